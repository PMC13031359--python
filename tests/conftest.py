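import numpy as np
import pytest

from fretsort import cytofret, simulate


@pytest.fixture
def photo_cfg() -> simulate.PhotophysicsConfig:
    """Default photophysics: realistic lognormal expression, 5% CV, background."""
    return simulate.PhotophysicsConfig()


@pytest.fixture
def noise_free_cfg(photo_cfg) -> simulate.PhotophysicsConfig:
    return photo_cfg.noise_free()


def summary(sample_id, m1, m2, m3, subtracted=True, n=100):
    """Shorthand for a ChannelSummary in tests."""
    return cytofret.ChannelSummary(
        sample_id=sample_id, m1=m1, m2=m2, m3=m3,
        n_events=n, background_subtracted=subtracted,
    )


def estimate_efficiency(cfg, e_true, n_events, rng):
    """Reference estimation pipeline: simulate one sample plus its controls,
    estimate S1/S2 from the controls, use the generator's true alpha."""
    fus = simulate.simulate_cytometry(cfg, e_true, n_events, "fusion", rng=rng)
    don = simulate.simulate_cytometry(cfg, 0.0, n_events, "donor_only", rng=rng)
    acc = simulate.simulate_cytometry(cfg, 0.0, n_events, "acceptor_only", rng=rng)
    bg = simulate.simulate_cytometry(cfg, 0.0, n_events, "background", rng=rng)
    bgs = cytofret.summarize_events(bg)
    d = cytofret.subtract_background(
        cytofret.summarize_events(don), bgs, require_positive=("m1", "m2")
    )
    a = cytofret.subtract_background(
        cytofret.summarize_events(acc), bgs, require_positive=("m2", "m3")
    )
    factors = cytofret.estimate_bleedthrough(d, a)
    calib = cytofret.SpectralCalibration.from_constants(
        factors.S1, factors.S2, cfg.alpha_true
    )
    s = cytofret.subtract_background(cytofret.summarize_events(fus), bgs)
    return cytofret.fret_efficiency(s, calib).E
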