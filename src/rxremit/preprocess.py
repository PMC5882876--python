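"""Predictor preparation: genotype QC, imputation, outcome derivation, split.

The genotype filters mirror a standard pharmacogenetic QC chain: minor allele
frequency strictly above 0.01, per-variant completeness of at least 99%, and
greedy pruning of variants in linkage disequilibrium (squared Pearson
correlation of dosages) above 0.8. Missing clinical values are completed by a
bagged-tree nonparametric imputer with categorical rounding afterwards.
Remission is defined as an HRSD-17 total of 7 points or less, and the cohort
is split 65/35 into training and validation sets, stratified by
outcome x drug.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .cohort import Cohort
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class QcThresholds:
    """Variant-level quality-control thresholds.

    maf_min: retain MAF strictly greater than this (default 0.01).
    completeness_min: retain non-missing fraction >= this (default 0.99).
    ld_max: drop a variant whose squared dosage correlation with a retained
        variant in the scan window exceeds this (default 0.8).
    """

    maf_min: float = 0.01
    completeness_min: float = 0.99
    ld_max: float = 0.8
    ld_window: int = 50

    def __post_init__(self) -> None:
        for v in (self.maf_min, self.completeness_min, self.ld_max):
            if not 0.0 < v <= 1.0:
                raise ConfigurationError("QC thresholds must lie in (0, 1]")


@dataclasses.dataclass
class SplitSpec:
    """Train/validation split: fraction, seed, and stratification switch."""

    train_fraction: float = 0.65
    seed: int = 0
    stratify: bool = True  # by outcome x drug

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")


def empirical_maf(column: np.ndarray) -> float:
    """Minor allele frequency of a dosage column over non-missing entries,
    folded to <= 0.5. NaN when the column is entirely missing."""
    col = np.asarray(column, dtype=float)
    col = col[~np.isnan(col)]
    if col.size == 0:
        return float("nan")
    freq = col.mean() / 2.0
    return float(min(freq, 1.0 - freq))


def filter_maf(genotypes: pd.DataFrame, maf_min: float = 0.01) -> list[str]:
    """Columns whose empirical MAF is strictly greater than ``maf_min``."""
    retained = []
    for name in genotypes.columns:
        maf = empirical_maf(genotypes[name].to_numpy())
        if np.isnan(maf):
            logger.warning("MAF filter: column %s is entirely missing; dropped", name)
            continue
        if maf > maf_min:
            retained.append(name)
    return retained


def filter_completeness(
    genotypes: pd.DataFrame, completeness_min: float = 0.99
) -> list[str]:
    """Columns with non-missing fraction >= ``completeness_min``."""
    frac = 1.0 - genotypes.isna().mean(axis=0)
    return list(genotypes.columns[(frac >= completeness_min).to_numpy()])


def ld_prune(
    genotypes: pd.DataFrame, ld_max: float = 0.8, window: int = 50
) -> tuple[list[str], dict[str, str]]:
    """Greedy left-to-right LD pruning on squared Pearson dosage correlation.

    A column is dropped when its r^2 with any previously retained column at
    most ``window`` positions back (in input order, assumed to follow genomic
    position) exceeds ``ld_max``. Returns the retained names and, for each
    dropped column, the retained column that triggered the exclusion.
    Missing entries are mean-filled for the correlation computation.
    """
    cols = list(genotypes.columns)
    X = genotypes.to_numpy(dtype=float).copy()
    mean = np.nanmean(X, axis=0)
    isnan = np.isnan(X)
    X[isnan] = np.take(mean, np.nonzero(isnan)[1])
    X -= X.mean(axis=0)
    norms = np.sqrt((X**2).sum(axis=0))

    retained: list[int] = []
    dropped_by: dict[str, str] = {}
    for j, name in enumerate(cols):
        if norms[j] == 0.0:
            logger.warning("LD prune: column %s has zero variance; dropped", name)
            dropped_by[name] = ""
            continue
        culprit = None
        for i in reversed(retained):
            if j - i > window:
                break
            r = float(X[:, i] @ X[:, j] / (norms[i] * norms[j]))
            if r * r > ld_max:
                culprit = cols[i]
                break
        if culprit is None:
            retained.append(j)
        else:
            dropped_by[name] = culprit
    return [cols[j] for j in retained], dropped_by


def _fill_for_prediction(X: pd.DataFrame, categorical: set[str]) -> pd.DataFrame:
    """Mean-/mode-fill predictor columns so trees can be fit on them."""
    out = X.copy()
    for c in out.columns:
        col = out[c]
        if col.isna().any():
            if c in categorical:
                observed = col.dropna()
                fill = observed.mode().iloc[0] if len(observed) else 0.0
            else:
                fill = col.mean() if col.notna().any() else 0.0
            out[c] = col.fillna(fill)
    return out


def bagged_tree_impute(
    features: pd.DataFrame,
    feature_meta: pd.DataFrame,
    n_trees: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Complete missing entries with a bagged-tree nonparametric imputer.

    For each column with missing values, ``n_trees`` trees are fit on
    bootstrap resamples of the rows observed in that column, using all other
    columns (mean-/mode-filled) as predictors. Missing cells receive the
    ensemble mean (continuous) or plurality vote (ordinal/binary, ties toward
    the smaller value). Observed cells are never altered; deterministic given
    ``seed``.
    """
    out = features.copy()
    targets = [c for c in out.columns if out[c].isna().any()]
    if not targets:
        return out
    categorical = {
        c
        for c in out.columns
        if c in feature_meta.index
        and feature_meta.loc[c, "vtype"] in ("ordinal", "binary", "dosage")
    }
    ss = np.random.SeedSequence(seed).spawn(len(targets))
    for col, child in zip(targets, ss):
        obs = out[col].notna().to_numpy()
        if not obs.any():
            raise ValueError(f"column {col!r} has no observed values; cannot impute")
        predictors = [c for c in out.columns if c != col]
        Xpred = _fill_for_prediction(out[predictors], categorical).to_numpy()
        y = out[col].to_numpy()[obs]
        Xobs, Xmiss = Xpred[obs], Xpred[~obs]
        rng = np.random.default_rng(child)
        is_cat = col in categorical
        preds = np.empty((n_trees, Xmiss.shape[0]))
        for t in range(n_trees):
            idx = rng.integers(0, len(y), size=len(y))
            tree_seed = int(rng.integers(0, 2**31 - 1))
            if is_cat:
                tree = DecisionTreeClassifier(random_state=tree_seed)
                tree.fit(Xobs[idx], y[idx].astype(np.int64))
            else:
                tree = DecisionTreeRegressor(random_state=tree_seed)
                tree.fit(Xobs[idx], y[idx])
            preds[t] = tree.predict(Xmiss)
        if is_cat:
            imputed = np.empty(Xmiss.shape[0])
            for i in range(Xmiss.shape[0]):
                vals, counts = np.unique(preds[:, i], return_counts=True)
                imputed[i] = vals[counts == counts.max()].min()  # tie -> smaller
        else:
            imputed = preds.mean(axis=0)
        filled = out[col].to_numpy(dtype=float, copy=True)
        filled[~obs] = imputed
        out[col] = filled
    return out


def round_categorical(
    features: pd.DataFrame,
    feature_meta: pd.DataFrame,
    imputed_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Snap imputed values in ordinal/binary columns to the nearest admissible
    value (ties toward the smaller value). If ``imputed_mask`` is given, only
    flagged cells are rounded; observed cells are untouched either way."""
    out = features.copy()
    for col in out.columns:
        if col not in feature_meta.index:
            continue
        if feature_meta.loc[col, "vtype"] not in ("ordinal", "binary", "dosage"):
            continue
        levels = feature_meta.loc[col, "levels"]
        if levels is None or (isinstance(levels, float) and np.isnan(levels)):
            continue
        levels = np.sort(np.asarray(list(levels), dtype=float))
        if levels.size == 0:
            raise ConfigurationError(f"empty admissible value set for {col!r}")
        vals = out[col].to_numpy(dtype=float, copy=True)
        target = (
            imputed_mask[col].to_numpy() if imputed_mask is not None
            else np.ones(len(vals), dtype=bool)
        )
        target = target & ~np.isnan(vals)
        if not target.any():
            continue
        d = np.abs(vals[target, None] - levels[None, :])
        # argmin returns the first (smallest) level on ties
        vals[target] = levels[np.argmin(d, axis=1)]
        out[col] = vals
    return out


def derive_remission(hrsd_total: np.ndarray) -> np.ndarray:
    """Remission indicator: HRSD-17 total of 7 points or less."""
    scores = np.asarray(hrsd_total)
    if not np.all(np.isfinite(scores)):
        raise ValueError("HRSD totals must be finite")
    if np.any(scores != np.round(scores)) or scores.min() < 0 or scores.max() > 52:
        raise ValueError("HRSD totals must be integers in [0, 52]")
    return (scores <= 7).astype(np.int64)


def mode_fill_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Complete residual genotype missingness by per-column mode (dosages are
    essentially complete after the completeness filter)."""
    out = genotypes.copy()
    for c in out.columns:
        col = out[c]
        if col.isna().any():
            observed = col.dropna()
            fill = observed.mode().iloc[0] if len(observed) else 0.0
            out[c] = col.fillna(fill)
    return out


def split_train_validation(
    outcome: np.ndarray,
    drug: np.ndarray,
    spec: SplitSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation split.

    The training-set size is round-half-up of ``n * train_fraction`` (430 at
    65% gives exactly 280/150). Per-stratum training counts are the
    largest-remainder apportionment of that total, so stratum proportions in
    each partition differ from the whole cohort by at most one participant.
    Deterministic given ``spec.seed``.
    """
    n = len(outcome)
    if n == 0:
        raise ValueError("cannot split an empty cohort")
    n_train = int(np.floor(n * spec.train_fraction + 0.5))
    rng = np.random.default_rng(spec.seed)

    if spec.stratify:
        strata = pd.Series(
            [f"{o}|{d}" for o, d in zip(outcome, drug)], dtype="object"
        )
    else:
        strata = pd.Series(["all"] * n, dtype="object")

    groups: dict[str, np.ndarray] = {
        k: np.flatnonzero(strata.to_numpy() == k) for k in sorted(strata.unique())
    }
    train_idx: list[int] = []
    eligible: list[str] = []
    remaining = n_train
    for k, idx in groups.items():
        if len(idx) < 2:
            warnings.warn(
                f"stratum {k!r} has fewer than 2 members; assigned wholly to training"
            )
            train_idx.extend(idx.tolist())
            remaining -= len(idx)
        else:
            eligible.append(k)
    remaining = max(remaining, 0)
    sizes = {k: len(groups[k]) for k in eligible}
    total = sum(sizes.values())
    targets = {k: sizes[k] * remaining / total for k in eligible} if total else {}
    base = {k: int(np.floor(t)) for k, t in targets.items()}
    shortfall = remaining - sum(base.values())
    order = sorted(eligible, key=lambda k: (-(targets[k] - base[k]), k))
    for k in order[:shortfall]:
        base[k] += 1
    for k in eligible:
        idx = rng.permutation(groups[k])
        take = min(base[k], len(idx))
        train_idx.extend(idx[:take].tolist())
    train = np.sort(np.asarray(train_idx, dtype=np.int64))
    val = np.setdiff1d(np.arange(n), train)
    return train, val


def preprocess_cohort(
    cohort: Cohort,
    qc: QcThresholds | None = None,
    n_trees: int = 25,
    seed: int = 0,
) -> tuple[Cohort, dict]:
    """Full predictor preparation on a cohort.

    Applies MAF -> completeness -> LD filters to genetic columns, mode-fills
    residual genotype missingness, imputes clinical missingness with bagged
    trees, rounds imputed categorical values, and dichotomises HRSD totals
    into remission when needed. Returns the prepared cohort and a QC report.
    """
    qc = qc or QcThresholds()
    gcols = cohort.genetic_columns
    ccols = cohort.clinical_columns
    G = cohort.features[gcols]

    keep_maf = set(filter_maf(G, qc.maf_min))
    keep_complete = set(filter_completeness(G, qc.completeness_min))
    keep = [c for c in gcols if c in keep_maf and c in keep_complete]
    keep_ld, dropped_by = ld_prune(cohort.features[keep], qc.ld_max, qc.ld_window)

    G = mode_fill_genotypes(cohort.features[keep_ld])

    C = cohort.features[ccols]
    imputed_mask = C.isna()
    if imputed_mask.to_numpy().any():
        C = bagged_tree_impute(C, cohort.feature_meta, n_trees=n_trees, seed=seed)
        C = round_categorical(C, cohort.feature_meta, imputed_mask)

    features = pd.concat([G, C], axis=1)
    outcome = cohort.outcome
    if cohort.outcome_kind == "hrsd_score":
        outcome = derive_remission(outcome)

    prepared = Cohort(
        features=features,
        feature_meta=cohort.feature_meta.loc[list(features.columns)].copy(),
        drug=cohort.drug.copy(),
        outcome=outcome,
        outcome_kind="binary",
        config=cohort.config,
    )
    report = {
        "n_genetic_input": len(gcols),
        "n_after_maf": len(keep_maf & set(gcols)),
        "n_after_completeness": len(keep),
        "n_after_ld": len(keep_ld),
        "ld_dropped_by": dropped_by,
        "n_clinical": len(ccols),
        "n_clinical_cells_imputed": int(imputed_mask.to_numpy().sum()),
    }
    return prepared, report
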