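"""Study orchestration: one pooled split, per-drug derivation, external and
cross-drug validation.

The cohort is split once (65/35, stratified by outcome x drug); every
derivation step — stability selection, hyperparameter tuning, the final
elastic-net fit and the classification threshold — runs strictly inside the
training partition of one drug arm. Each frozen model is then evaluated on
the same-drug validation participants (external validation) and, without any
refitting, on the other drug's validation participants (cross-drug
specificity). All randomness flows from one master seed through a fixed
spawning order, so a study is bit-reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort
from .enet import (
    EnetHyperparams,
    FittedModel,
    export_model,
    fit_enet_logistic,
    fit_intercept_only,
    predict_probability,
    tune_hyperparameters,
)
from .evaluation import (
    EvaluationReport,
    choose_threshold,
    evaluate_predictions,
    roc_points,
)
from .preprocess import QcThresholds, SplitSpec, split_train_validation
from .selection import SelectionVotes, stability_select

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SelectionParams:
    repetitions: int = 20
    folds: int = 5
    lfdr_threshold: float = 0.8


@dataclasses.dataclass
class TuningParams:
    alphas: tuple[float, ...] = (0.1, 0.55, 1.0)
    n_lambda: int = 10
    folds: int = 5
    repetitions: int = 100


@dataclasses.dataclass
class StudyConfig:
    """Resolved configuration of a full two-drug study."""

    drugs: tuple[str, str] = ("A", "B")
    split: SplitSpec = dataclasses.field(default_factory=SplitSpec)
    qc: QcThresholds = dataclasses.field(default_factory=QcThresholds)
    selection: SelectionParams = dataclasses.field(default_factory=SelectionParams)
    tuning: TuningParams = dataclasses.field(default_factory=TuningParams)
    seed: int = 0
    out_dir: str | None = None


@dataclasses.dataclass
class DrugResult:
    votes: SelectionVotes
    model: FittedModel
    hyperparams: EnetHyperparams | None
    train_report: EvaluationReport
    validation_report: EvaluationReport


@dataclasses.dataclass
class StudyResult:
    per_drug: dict[str, DrugResult]
    cross_drug: dict[tuple[str, str], EvaluationReport]  # (model drug, eval drug)
    train_idx: np.ndarray
    validation_idx: np.ndarray
    manifest: dict


def _drug_seeds(config: StudyConfig) -> dict[str, dict[str, int]]:
    """Fixed spawning order: (selection, tuning) per drug in config order."""
    children = np.random.SeedSequence(config.seed).spawn(2 * len(config.drugs))
    out = {}
    for i, d in enumerate(config.drugs):
        out[d] = {
            "selection": int(children[2 * i].generate_state(1)[0] % (2**31 - 1)),
            "tuning": int(children[2 * i + 1].generate_state(1)[0] % (2**31 - 1)),
        }
    return out


def run_same_drug(
    cohort: Cohort,
    train_idx: np.ndarray,
    validation_idx: np.ndarray,
    drug: str,
    config: StudyConfig,
    seeds: dict[str, int] | None = None,
) -> DrugResult:
    """Derivation and external validation for one drug arm.

    Selection and tuning see only training-partition participants of the
    drug arm. An empty retained set degrades to an intercept-only model with
    a warning (chance-level reports rather than failure).
    """
    if seeds is None:
        seeds = _drug_seeds(config)[drug]
    arm = cohort.arm_mask(drug)
    tr = train_idx[arm[train_idx]]
    va = validation_idx[arm[validation_idx]]
    Xtr = cohort.features.iloc[tr]
    ytr = cohort.outcome[tr]

    votes = stability_select(
        Xtr.to_numpy(dtype=float),
        ytr,
        feature_names=list(Xtr.columns),
        repetitions=config.selection.repetitions,
        folds=config.selection.folds,
        lfdr_threshold=config.selection.lfdr_threshold,
        seed=seeds["selection"],
    )
    retained = votes.retained
    provenance = {
        "drug": drug,
        "n_train": int(len(tr)),
        "seed_selection": seeds["selection"],
        "seed_tuning": seeds["tuning"],
        "version": __version__,
    }
    if not retained:
        logger.warning("drug %s: empty retained set; fitting intercept-only model", drug)
        model = fit_intercept_only(ytr, train_drug=drug, provenance=provenance)
        hyper = None
    else:
        kinds = {
            n: cohort.feature_meta.loc[n, "kind"] for n in retained
        }
        hyper = tune_hyperparameters(
            Xtr[retained],
            ytr,
            alphas=config.tuning.alphas,
            n_lambda=config.tuning.n_lambda,
            folds=config.tuning.folds,
            repetitions=config.tuning.repetitions,
            seed=seeds["tuning"],
        )
        model = fit_enet_logistic(
            Xtr[retained],
            ytr,
            alpha=hyper.alpha,
            lam=hyper.lam,
            feature_kinds=kinds,
            train_drug=drug,
            provenance=provenance,
        )
    p_train = predict_probability(model, Xtr)
    model.threshold = choose_threshold(p_train, ytr)

    train_report = evaluate_predictions(
        p_train, ytr, model.threshold, context=f"{drug}|train|same-drug"
    )
    p_val = predict_probability(model, cohort.features.iloc[va])
    validation_report = evaluate_predictions(
        p_val,
        cohort.outcome[va],
        model.threshold,
        context=f"{drug}|validation|same-drug",
    )
    return DrugResult(
        votes=votes,
        model=model,
        hyperparams=hyper,
        train_report=train_report,
        validation_report=validation_report,
    )


def run_cross_drug(
    model: FittedModel,
    cohort: Cohort,
    eval_drug: str,
    validation_idx: np.ndarray,
) -> EvaluationReport:
    """Apply a frozen model (coefficients + threshold) to the other drug's
    validation participants. No refitting of any kind."""
    arm = cohort.arm_mask(eval_drug)
    va = validation_idx[arm[validation_idx]]
    if len(va) == 0:
        raise ValueError(f"no validation participants in drug arm {eval_drug!r}")
    p = predict_probability(model, cohort.features.iloc[va])
    thr = model.threshold if model.threshold is not None else 0.5
    return evaluate_predictions(
        p,
        cohort.outcome[va],
        thr,
        context=f"{model.train_drug}-on-{eval_drug}|validation|cross-drug",
    )


def _cohort_hash(cohort: Cohort) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(cohort.features.to_numpy(dtype=float)).tobytes())
    h.update(np.asarray(cohort.outcome, dtype=np.int64).tobytes())
    h.update("".join(map(str, cohort.drug)).encode())
    return h.hexdigest()


def build_manifest(cohort: Cohort, config: StudyConfig) -> dict:
    return {
        "version": __version__,
        "seed": config.seed,
        "n_participants": cohort.n,
        "n_features": cohort.features.shape[1],
        "drugs": list(config.drugs),
        "split": dataclasses.asdict(config.split),
        "qc": dataclasses.asdict(config.qc),
        "selection": dataclasses.asdict(config.selection),
        "tuning": dataclasses.asdict(config.tuning),
        "input_sha256": _cohort_hash(cohort),
    }


def run_full_study(cohort: Cohort, config: StudyConfig | None = None) -> StudyResult:
    """Split -> per-drug derivation + external validation -> both cross-drug
    analyses. Writes votes/model/report artifacts when ``config.out_dir`` is
    set. The cohort must already be preprocessed (binary outcome)."""
    config = config or StudyConfig()
    if cohort.outcome_kind != "binary":
        raise ValueError("run_full_study expects a preprocessed cohort (binary outcome)")
    manifest = build_manifest(cohort, config)
    train_idx, validation_idx = split_train_validation(
        cohort.outcome, cohort.drug, config.split
    )
    seeds = _drug_seeds(config)
    per_drug: dict[str, DrugResult] = {}
    for d in config.drugs:
        logger.info("deriving model for drug %s", d)
        per_drug[d] = run_same_drug(
            cohort, train_idx, validation_idx, d, config, seeds=seeds[d]
        )
    cross: dict[tuple[str, str], EvaluationReport] = {}
    d0, d1 = config.drugs
    cross[(d0, d1)] = run_cross_drug(per_drug[d0].model, cohort, d1, validation_idx)
    cross[(d1, d0)] = run_cross_drug(per_drug[d1].model, cohort, d0, validation_idx)

    result = StudyResult(
        per_drug=per_drug,
        cross_drug=cross,
        train_idx=train_idx,
        validation_idx=validation_idx,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_study_artifacts(result, cohort, Path(config.out_dir))
    return result


def write_study_artifacts(result: StudyResult, cohort: Cohort, out_dir: Path) -> None:
    """Write votes.csv / model.json / report.json / roc.csv per analysis cell
    plus the reproducibility manifest. Deterministic byte-for-byte."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for d, res in result.per_drug.items():
        pd.DataFrame(
            {
                "feature": res.votes.feature_names,
                "votes": res.votes.votes,
                "rounds": res.votes.rounds,
                "retained": res.votes.retained_mask,
            }
        ).to_csv(out_dir / f"votes_{d}.csv", index=False)
        with open(out_dir / f"model_{d}.json", "w") as fh:
            json.dump(export_model(res.model), fh, indent=2, sort_keys=True)
            fh.write("\n")
        for label, report in (
            (f"{d}_train", res.train_report),
            (f"{d}_validation", res.validation_report),
        ):
            with open(out_dir / f"report_{label}.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
    for (md, ed), report in result.cross_drug.items():
        with open(out_dir / f"report_{md}_on_{ed}.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        arm = cohort.arm_mask(ed)
        va = result.validation_idx[arm[result.validation_idx]]
        p = predict_probability(result.per_drug[md].model, cohort.features.iloc[va])
        pts = roc_points(p, cohort.outcome[va])
        pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(
            out_dir / f"roc_{md}_on_{ed}.csv", index=False
        )
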