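import pytest

from aiflipid.lipids import LipidClass, enumerate_candidates
from aiflipid.simulate import (
    five_standard_config,
    plasma_like_config,
    simulate_run,
)

PLASMA_CLASSES = [LipidClass.PI, LipidClass.PE, LipidClass.PC, LipidClass.LPC]


def plasma_candidates():
    cands = []
    for cls in PLASMA_CLASSES:
        ions = ["[M-CH3]-"] if cls in (LipidClass.PC, LipidClass.LPC) else ["[M-H]-"]
        lo, hi = (14, 24) if cls is LipidClass.LPC else (28, 48)
        cands.extend(enumerate_candidates(cls, (lo, hi), (0, 12), ions))
    return cands


@pytest.fixture(scope="session")
def standard_run():
    """Five-standard negative-mode run (one species per class band)."""
    return simulate_run(five_standard_config(seed=11))


@pytest.fixture(scope="session")
def standard_run_clean():
    """Five-standard run with all noise sources off."""
    cfg = five_standard_config(seed=11)
    cfg.mz_jitter_ppm = 0.0
    cfg.intensity_cv = 0.0
    cfg.baseline_frac = 0.0
    return simulate_run(cfg)


@pytest.fixture(scope="session")
def plasma_run():
    """Plasma-like negative-mode run at default noise."""
    return simulate_run(plasma_like_config(seed=11))


@pytest.fixture(scope="session")
def plasma_run_clean():
    cfg = plasma_like_config(seed=11)
    cfg.mz_jitter_ppm = 0.0
    cfg.intensity_cv = 0.0
    cfg.baseline_frac = 0.0
    return simulate_run(cfg)


@pytest.fixture(scope="session")
def candidates():
    return plasma_candidates()
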