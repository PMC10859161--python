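import numpy as np
import pytest

from thrombomr import AssociationRecord, HarmonizedInstrument, harmonize, simulate_pair


def make_instruments(bx, sx, by, sy, ids=None):
    """Build kept HarmonizedInstrument objects from effect arrays."""
    bx, sx, by, sy = map(np.asarray, (bx, sx, by, sy))
    ids = ids or [f"rs{i + 1}" for i in range(bx.size)]
    return [
        HarmonizedInstrument(
            snp_id=ids[j], effect_allele="A", other_allele="G",
            beta_exp=float(bx[j]), se_exp=float(sx[j]),
            beta_out=float(by[j]), se_out=float(sy[j]),
        )
        for j in range(bx.size)
    ]


def record(snp, ea, oa, beta, se=0.01, pval=1e-10, eaf=None, n_cases=1000,
           n_controls=1000, trait="trait"):
    return AssociationRecord(snp, ea, oa, beta, se, pval, eaf, n_cases, n_controls, trait)


def kept_instruments(exposure, outcome, **kwargs):
    return [h for h in harmonize(exposure, outcome, **kwargs) if h.status == "kept"]


def kept_arrays(exposure, outcome, **kwargs):
    kept = kept_instruments(exposure, outcome, **kwargs)
    return (
        np.array([i.beta_exp for i in kept]),
        np.array([i.se_exp for i in kept]),
        np.array([i.beta_out for i in kept]),
        np.array([i.se_out for i in kept]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def synthetic_kept():
    """Kept instruments from a seeded synthetic pair with a real effect."""
    from thrombomr import SimulationConfig

    exposure, outcome, truth = simulate_pair(SimulationConfig(n_snp=40, theta=0.2, seed=7))
    return kept_instruments(exposure, outcome), truth
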