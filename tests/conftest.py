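import numpy as np
import pytest

from herbipk import ConcProfile, SimStudyConfig, profiles_from_table, simulate_pk_study


def make_profile(times, concs, blq=None, dose=100.0, lloq=1e-6,
                 subject="S1", analyte="A"):
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if blq is None:
        blq = concs < lloq
    return ConcProfile(
        subject_id=subject, analyte_id=analyte,
        times=times, concs=concs, blq_flags=np.asarray(blq, dtype=bool),
        dose=dose, lloq=lloq,
    )


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (fixed seed) plus its ground truth."""
    cfg = SimStudyConfig(seed=42)
    conc, truth = simulate_pk_study(cfg)
    lloqs = {a: k.lloq for a, k in cfg.analytes.items()}
    profiles = profiles_from_table(conc, cfg.dose, lloqs)
    return cfg, conc, truth, profiles


@pytest.fixture(scope="session")
def uncensored_study():
    """Same design but with negligible LLOQs: no censoring truncates supports."""
    from herbipk import DEFAULT_ANALYTES, AnalyteKinetics

    analytes = {
        a: AnalyteKinetics(ka=k.ka, ke=k.ke, scale=k.scale, lloq=1e-9)
        for a, k in DEFAULT_ANALYTES.items()
    }
    cfg = SimStudyConfig(analytes=analytes, error_add=0.0, seed=99)
    conc, truth = simulate_pk_study(cfg)
    lloqs = {a: k.lloq for a, k in cfg.analytes.items()}
    profiles = profiles_from_table(conc, cfg.dose, lloqs)
    return cfg, conc, truth, profiles
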