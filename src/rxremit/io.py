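"""Readers and writers: cohort tables (CSV + JSON sidecar), dosage CSV,
clinical CSV with typed metadata, and minimal VCF.

The on-disk cohort table is a directory of plain-text files that round-trips
bit-exactly: ``features.csv`` (pandas repr floats), ``meta.json`` (typed
per-feature metadata) and ``samples.csv`` (drug arm + outcome).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort

logger = logging.getLogger(__name__)


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.features.to_csv(path / "features.csv", index=False)
    pd.DataFrame(
        {"drug": cohort.drug, "outcome": cohort.outcome}
    ).to_csv(path / "samples.csv", index=False)
    meta = {
        name: {
            "kind": row["kind"],
            "vtype": row["vtype"],
            "maf": None if pd.isna(row["maf"]) else float(row["maf"]),
            "levels": None if row["levels"] is None or (
                isinstance(row["levels"], float) and np.isnan(row["levels"])
            ) else [float(v) for v in row["levels"]],
            "mean": None if pd.isna(row["mean"]) else float(row["mean"]),
            "sd": None if pd.isna(row["sd"]) else float(row["sd"]),
        }
        for name, row in cohort.feature_meta.iterrows()
    }
    with open(path / "meta.json", "w") as fh:
        json.dump({"outcome_kind": cohort.outcome_kind, "features": meta}, fh, indent=2)
        fh.write("\n")


def load_cohort(path: str | Path) -> Cohort:
    path = Path(path)
    features = pd.read_csv(path / "features.csv")
    samples = pd.read_csv(path / "samples.csv")
    with open(path / "meta.json") as fh:
        doc = json.load(fh)
    records = []
    for name, m in doc["features"].items():
        records.append(
            dict(
                name=name,
                kind=m["kind"],
                vtype=m["vtype"],
                maf=np.nan if m["maf"] is None else m["maf"],
                levels=None if m["levels"] is None else tuple(m["levels"]),
                mean=np.nan if m["mean"] is None else m["mean"],
                sd=np.nan if m["sd"] is None else m["sd"],
            )
        )
    meta = pd.DataFrame.from_records(records, index="name")
    return Cohort(
        features=features,
        feature_meta=meta,
        drug=samples["drug"].to_numpy(),
        outcome=samples["outcome"].to_numpy(),
        outcome_kind=doc.get("outcome_kind", "binary"),
    )


def read_dosage_csv(path: str | Path) -> pd.DataFrame:
    """Dosage matrix CSV: one row per participant, one column per variant."""
    return pd.read_csv(path)


def read_clinical_csv(path: str | Path, meta_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical CSV plus a sidecar metadata CSV (name, vtype, levels).

    ``levels`` in the sidecar is a ``|``-separated admissible value list for
    ordinal/binary columns, empty for continuous ones.
    """
    data = pd.read_csv(path)
    raw = pd.read_csv(meta_path)
    records = []
    for _, row in raw.iterrows():
        levels = row.get("levels")
        parsed = (
            tuple(float(v) for v in str(levels).split("|"))
            if isinstance(levels, str) and levels
            else None
        )
        records.append(
            dict(
                name=row["name"],
                kind="clinical",
                vtype=row["vtype"],
                maf=np.nan,
                levels=parsed,
                mean=np.nan,
                sd=np.nan,
            )
        )
    return data, pd.DataFrame.from_records(records, index="name")


_VCF_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(dosages: pd.DataFrame, path: str | Path) -> None:
    """Minimal VCF 4.2 with synthetic CHROM/POS and GT-only sample columns."""
    path = Path(path)
    samples = [f"S{i:05d}" for i in range(len(dosages))]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        values = dosages.to_numpy(dtype=float)
        for j, name in enumerate(dosages.columns):
            gts = [
                "./." if np.isnan(v) else _VCF_GT[float(v)] for v in values[:, j]
            ]
            fh.write(
                f"1\t{j + 1}\t{name}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Additive dosages from a VCF (GT field; missing GT -> NaN).

    Multi-allelic records are skipped with a warning. Requires cyvcf2.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    names, columns = [], []
    for variant in vcf:
        if len(variant.ALT) > 1:
            logger.warning("skipping multi-allelic record %s", variant.ID)
            continue
        col = np.empty(len(vcf.samples))
        for i, gt in enumerate(variant.genotypes):
            a = [x for x in gt[:-1]]
            col[i] = np.nan if any(x < 0 for x in a) else float(sum(x > 0 for x in a))
        names.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(col)
    vcf.close()
    return pd.DataFrame(np.column_stack(columns) if columns else np.empty((0, 0)), columns=names)


def write_simulation_outputs(cohort: Cohort, out_dir: str | Path, vcf: bool = False) -> None:
    """Writer used by the CLI: clinical+outcome CSV, dosage CSV (or VCF)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clin = cohort.features[cohort.clinical_columns].copy()
    clin.insert(0, "drug", cohort.drug)
    clin.insert(1, "outcome", cohort.outcome)
    clin.to_csv(out_dir / "clinical.csv", index=False)
    G = cohort.features[cohort.genetic_columns]
    if vcf:
        write_vcf(G, out_dir / "genotypes.vcf")
    else:
        G.to_csv(out_dir / "genotypes.csv", index=False)
    save_cohort(cohort, out_dir / "cohort")
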