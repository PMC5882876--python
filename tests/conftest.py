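import numpy as np
import pytest

import rxremit as rx


@pytest.fixture(scope="session")
def small_null_cohort():
    """Preprocessed cohort with no true effects (shared across tests)."""
    cfg = rx.SimulationConfig(
        n_participants=240,
        n_snps=100,
        n_clinical=6,
        missing_rate=0.05,
        seed=42,
    )
    prepared, _ = rx.preprocess_cohort(rx.generate_cohort(cfg), seed=0)
    return prepared


def make_signal_cohort(
    seed: int,
    n: int = 2000,
    n_snps: int = 500,
    n_causal: int = 10,
    log_or: float = float(np.log(1.8)),
    shared_causal: bool = False,
):
    """Two-arm cohort with drug-specific (or shared) causal SNPs planted in
    distinct LD blocks among common variants."""
    causal_a = [f"snp_{i * 10:05d}" for i in range(n_causal)]
    causal_b = (
        causal_a
        if shared_causal
        else [f"snp_{(i + n_causal) * 10:05d}" for i in range(n_causal)]
    )
    cfg = rx.SimulationConfig(
        n_participants=n,
        n_snps=n_snps,
        n_clinical=0,
        missing_rate=0.0,
        causal_features_per_drug={"A": causal_a, "B": causal_b},
        effect_sizes={k: log_or for k in set(causal_a) | set(causal_b)},
        causal_maf_range=(0.2, 0.5),
        intercept_per_drug="center",
        seed=seed,
    )
    return rx.generate_cohort(cfg), {"A": causal_a, "B": causal_b}
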