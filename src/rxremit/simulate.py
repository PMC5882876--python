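"""Synthetic randomized two-arm pharmacogenetic cohorts with known ground truth.

Emulates the structure of a randomized antidepressant trial: a few hundred
participants allocated to one of two drugs, LD-blocked SNP dosages, ordinal /
continuous clinical variables, and a remission outcome generated from sparse
drug-specific logistic effects. Every stage of the downstream pipeline
(QC filters, imputation, selection, modelling, validation) is therefore
testable against a known generative truth.

Linkage disequilibrium is induced by thresholding latent AR(1) Gaussians at
Hardy-Weinberg quantiles: within a block, latent variables have correlation
``ld_rho`` between neighbours, and each is cut at the quantiles of
P(0) = (1-MAF)^2, P(1) = 2*MAF*(1-MAF), P(2) = MAF^2. The implied pairwise
dosage correlation is integrable, which gives an exact oracle for tests.

A single global seed drives a :class:`numpy.random.SeedSequence` that is
spawned, in fixed order, into independent child generators for genotypes,
clinical variables, drug allocation, outcomes and missingness.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .cohort import Cohort
from .exceptions import ConfigurationError

DRUG_LABELS = ("A", "B")

# fixed spawn order of the per-stage child generators
_STAGES = ("genotypes", "clinical", "drug", "outcome", "missing")


@dataclasses.dataclass
class SimulationConfig:
    """Ground-truth description of a simulated randomized cohort.

    ``effect_sizes`` are per-unit log-odds of remission (for SNPs: per minor
    allele). ``intercept_per_drug`` maps each arm to a log-odds intercept, or
    the string ``"center"`` to set the intercept to minus the expected genetic
    + clinical contribution so that simulated remission prevalence is ~50%.

    ``causal_maf_range``, when set, draws the MAFs of causal SNPs from this
    narrower range (e.g. restricting causal variants to common SNPs, where a
    given per-allele odds ratio carries appreciable outcome variance) while
    the remaining SNPs keep ``maf_range``.
    """

    n_participants: int = 430
    n_snps: int = 500
    ld_block_size: int = 10
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_clinical: int = 10
    causal_features_per_drug: Mapping[str, Sequence[str]] = dataclasses.field(
        default_factory=lambda: {"A": (), "B": ()}
    )
    effect_sizes: Mapping[str, float] = dataclasses.field(default_factory=dict)
    intercept_per_drug: Mapping[str, float] | str = dataclasses.field(
        default_factory=lambda: {"A": 0.0, "B": 0.0}
    )
    causal_maf_range: tuple[float, float] | None = None
    missing_rate: float = 0.05
    outcome_mode: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_snps < 0 or self.n_clinical < 0:
            raise ConfigurationError("cohort dimensions must be non-negative (n >= 1)")
        if self.n_snps and not (1 <= self.ld_block_size <= self.n_snps):
            raise ConfigurationError("require n_snps >= ld_block_size >= 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        for rng_pair in (self.maf_range, self.causal_maf_range):
            if rng_pair is None:
                continue
            lo, hi = rng_pair
            if not (0.0 < lo <= hi <= 0.5):
                raise ConfigurationError("MAF ranges must lie inside (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.outcome_mode not in ("binary", "hrsd_score"):
            raise ConfigurationError("outcome_mode must be 'binary' or 'hrsd_score'")
        for d in self.causal_features_per_drug:
            if d not in DRUG_LABELS:
                raise ConfigurationError(f"unknown drug label {d!r}")

    def rngs(self) -> dict[str, np.random.Generator]:
        """Per-stage generators spawned deterministically from the global seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {s: np.random.default_rng(c) for s, c in zip(_STAGES, children)}


def snp_names(n_snps: int) -> list[str]:
    return [f"snp_{i:05d}" for i in range(n_snps)]


def clinical_names(n_clinical: int) -> list[str]:
    return [f"clin_{i:03d}" for i in range(n_clinical)]


def hardy_weinberg_thresholds(maf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latent-Gaussian cut points giving Hardy-Weinberg genotype frequencies."""
    maf = np.asarray(maf, dtype=float)
    t0 = ndtri((1.0 - maf) ** 2)  # below: dosage 0
    t1 = ndtri(1.0 - maf**2)  # between: dosage 1; above: dosage 2
    return t0, t1


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw an ``n x n_snps`` dosage matrix and the per-SNP MAFs used.

    Blocks of ``ld_block_size`` adjacent SNPs share an AR(1) latent Gaussian
    with neighbour correlation ``ld_rho``; blocks are mutually independent.
    """
    if rng is None:
        rng = config.rngs()["genotypes"]
    n, p = config.n_participants, config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    if config.causal_maf_range is not None:
        causal = set()
        for feats in config.causal_features_per_drug.values():
            causal.update(feats)
        names = snp_names(p)
        idx = [j for j, nm in enumerate(names) if nm in causal]
        if idx:
            maf[idx] = rng.uniform(
                config.causal_maf_range[0], config.causal_maf_range[1], size=len(idx)
            )
    latent = np.empty((n, p))
    rho = config.ld_rho
    innov_sd = np.sqrt(1.0 - rho**2)
    for start in range(0, p, config.ld_block_size):
        width = min(config.ld_block_size, p - start)
        e = rng.standard_normal((n, width))
        z = np.empty((n, width))
        z[:, 0] = e[:, 0]
        for j in range(1, width):
            z[:, j] = rho * z[:, j - 1] + innov_sd * e[:, j]
        latent[:, start : start + width] = z
    t0, t1 = hardy_weinberg_thresholds(maf)
    dosage = (latent > t0).astype(np.int64) + (latent > t1)
    return dosage.astype(float), maf


# clinical column archetypes cycled over n_clinical; parameters drawn per column
_CLINICAL_CYCLE = ("ordinal", "continuous", "binary")


def simulate_clinical(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw clinical/demographic columns and their typed metadata.

    Ordinal columns mimic 0-4 scale items (binomial(4, p)); binary columns
    mimic yes/no history items; continuous columns mimic age/BMI-like
    measurements. Declared mean/sd are stored in the metadata so the sampling
    distribution is testable.
    """
    if rng is None:
        rng = config.rngs()["clinical"]
    n, m = config.n_participants, config.n_clinical
    names = clinical_names(m)
    X = np.empty((n, m))
    records = []
    for i, name in enumerate(names):
        vtype = _CLINICAL_CYCLE[i % len(_CLINICAL_CYCLE)]
        if vtype == "ordinal":
            pr = rng.uniform(0.2, 0.8)
            X[:, i] = rng.binomial(4, pr, size=n)
            rec = dict(
                name=name, vtype=vtype, levels=tuple(range(5)),
                mean=4 * pr, sd=float(np.sqrt(4 * pr * (1 - pr))),
            )
        elif vtype == "binary":
            pr = rng.uniform(0.2, 0.8)
            X[:, i] = rng.binomial(1, pr, size=n)
            rec = dict(
                name=name, vtype=vtype, levels=(0, 1),
                mean=pr, sd=float(np.sqrt(pr * (1 - pr))),
            )
        else:
            mu = rng.uniform(20.0, 50.0)
            sd = rng.uniform(5.0, 15.0)
            X[:, i] = rng.normal(mu, sd, size=n)
            rec = dict(name=name, vtype=vtype, levels=None, mean=mu, sd=sd)
        rec["kind"] = "clinical"
        rec["maf"] = np.nan
        records.append(rec)
    meta = pd.DataFrame.from_records(records, index="name") if records else pd.DataFrame(
        columns=["vtype", "levels", "mean", "sd", "kind", "maf"]
    )
    return X[:, : len(names)], meta


def linear_predictor(
    features: pd.DataFrame, drug: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """True per-participant log-odds of remission under the generating model."""
    n = len(features)
    eta = np.zeros(n)
    intercepts = _resolve_intercepts(features, config)
    for d, causal in config.causal_features_per_drug.items():
        mask = np.asarray(drug == d)
        if not mask.any():
            continue
        eta[mask] += intercepts[d]
        for k in causal:
            if k not in features.columns:
                raise ConfigurationError(f"causal feature {k!r} absent from features")
            eta[mask] += config.effect_sizes.get(k, 0.0) * features[k].to_numpy()[mask]
    return eta


def _resolve_intercepts(
    features: pd.DataFrame, config: SimulationConfig
) -> dict[str, float]:
    if config.intercept_per_drug == "center":
        out = {}
        for d, causal in config.causal_features_per_drug.items():
            for k in causal:
                if k not in features.columns:
                    raise ConfigurationError(f"causal feature {k!r} absent from features")
            out[d] = -sum(
                config.effect_sizes.get(k, 0.0) * float(features[k].mean())
                for k in causal
            )
        for d in DRUG_LABELS:
            out.setdefault(d, 0.0)
        return out
    return {d: config.intercept_per_drug.get(d, 0.0) for d in DRUG_LABELS}


def simulate_outcomes(
    features: pd.DataFrame,
    drug: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw outcomes from the drug-specific sparse logistic model.

    In ``binary`` mode, remission ~ Bernoulli(logistic(eta)). In
    ``hrsd_score`` mode an integer HRSD-17 total in [0, 52] is produced that
    is monotone non-increasing in eta for a fixed uniform draw and satisfies
    P(HRSD <= 7) = logistic(eta) by construction, so dichotomising at <= 7
    recovers the same remission model.
    """
    if rng is None:
        rng = config.rngs()["outcome"]
    eta = linear_predictor(features, drug, config)
    prob = expit(eta)
    u = rng.uniform(size=len(eta))
    if config.outcome_mode == "binary":
        return (u < prob).astype(np.int64)
    remit = u < prob
    score = np.empty(len(eta), dtype=np.int64)
    # remitters: spread u/prob over the 8 scores 0..7; others over 8..52
    with np.errstate(divide="ignore", invalid="ignore"):
        score[remit] = np.floor(u[remit] / prob[remit] * 8.0).astype(np.int64)
        score[~remit] = 8 + np.floor(
            (u[~remit] - prob[~remit]) / (1.0 - prob[~remit]) * 45.0
        ).astype(np.int64)
    return np.clip(score, 0, 52)


def inject_missingness(
    matrix: np.ndarray,
    rate: float,
    column_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Set eligible cells (columns flagged in ``column_mask``) missing MCAR."""
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError("missing rate must lie in [0, 1)")
    out = np.array(matrix, dtype=float, copy=True)
    if rate == 0.0 or not np.any(column_mask):
        return out
    cols = np.flatnonzero(column_mask)
    mask = rng.uniform(size=(out.shape[0], cols.size)) < rate
    sub = out[:, cols]
    sub[mask] = np.nan
    out[:, cols] = sub
    return out


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full cohort: genotypes, clinical variables, randomized drug
    allocation, outcomes, then MCAR missingness in clinical columns.

    Bit-identical for identical ``config`` (including seed).
    """
    rngs = config.rngs()
    geno, maf = simulate_genotypes(config, rngs["genotypes"])
    clin, clin_meta = simulate_clinical(config, rngs["clinical"])

    g_names = snp_names(config.n_snps)
    geno_meta = pd.DataFrame(
        {
            "kind": "genetic",
            "vtype": "dosage",
            "maf": maf,
            "levels": [(0, 1, 2)] * config.n_snps,
            "mean": 2.0 * maf,
            "sd": np.sqrt(2.0 * maf * (1.0 - maf)),
        },
        index=pd.Index(g_names, name="name"),
    )
    cols = ["kind", "vtype", "maf", "levels", "mean", "sd"]
    meta = (
        pd.concat([geno_meta, clin_meta])[cols]
        if len(clin_meta)
        else geno_meta[cols]
    )

    features = pd.DataFrame(
        np.hstack([geno, clin]) if clin.size else geno,
        columns=g_names + clinical_names(config.n_clinical),
    )

    # balanced randomized allocation, independent of all features
    n = config.n_participants
    drug = np.array([DRUG_LABELS[0]] * (n // 2) + [DRUG_LABELS[1]] * (n - n // 2))
    rngs["drug"].shuffle(drug)

    for d, causal in config.causal_features_per_drug.items():
        for k in causal:
            if k not in features.columns:
                raise ConfigurationError(f"causal feature {k!r} absent from features")

    outcome = simulate_outcomes(features, drug, config, rngs["outcome"])

    clinical_mask = np.array(
        [meta.loc[c, "kind"] == "clinical" for c in features.columns]
    )
    values = inject_missingness(
        features.to_numpy(), config.missing_rate, clinical_mask, rngs["missing"]
    )
    features = pd.DataFrame(values, columns=features.columns)

    return Cohort(
        features=features,
        feature_meta=meta,
        drug=drug,
        outcome=outcome,
        outcome_kind=config.outcome_mode,
        config=config,
    )
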