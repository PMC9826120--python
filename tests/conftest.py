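import numpy as np
import pytest

from tsdmeth.filtering import apply_filters
from tsdmeth.io import CpGLocus, MethylomeMatrix, SampleRecord
from tsdmeth.simulate import SimulationConfig, simulate_methylomes, treatment_groups


def make_samples(n=4, tissue="blood", temps=None, sexes=None, clutches=None):
    temps = temps or [30.0] * n
    sexes = sexes or ["F"] * n
    clutches = clutches or ["C1"] * n
    return [
        SampleRecord(f"S{i + 1:02d}", tissue, sexes[i], temps[i], clutches[i])
        for i in range(n)
    ]


def make_matrix(meth, cov, samples=None, scaffold="scaf1", start=100, step=50):
    meth = np.asarray(meth)
    cov = np.asarray(cov)
    loci = [CpGLocus(scaffold, start + step * i) for i in range(meth.shape[0])]
    samples = samples or make_samples(meth.shape[1])
    return MethylomeMatrix(loci, samples, meth, cov)


@pytest.fixture(scope="session")
def planted_study():
    """Seeded simulation at the study design with strong planted effects,
    already filtered; shared by recovery-style tests."""
    cfg = SimulationConfig(
        seed=11,
        n_loci=3000,
        sex_effect_logit=2.5,
        temp_slope_logit_per_degc=0.5,
        frac_sex_conditional=0.0,
    )
    study = simulate_methylomes(cfg)
    filtered, report = apply_filters(study.matrix, treatment_groups(study.metadata))
    return {"config": cfg, "study": study, "matrix": filtered, "report": report}


@pytest.fixture(scope="session")
def small_null_matrix():
    """All-null simulated matrix (no planted effects), unfiltered."""
    cfg = SimulationConfig(seed=3, n_loci=400, frac_sex_dmc=0.0, frac_temp_dmc=0.0)
    study = simulate_methylomes(cfg)
    return study
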