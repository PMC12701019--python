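import pytest

from aslheight import PhantomConfig, render_scan, render_well


@pytest.fixture(scope="session")
def noiseless_scan():
    """A clean phantom (no noise, no tilt) with 7 µm ASL over a 15 µm cell layer."""
    cfg = PhantomConfig(noise_gaussian_sd=0.0, tilt=0.0, position_offset_sd=0.0,
                        asl_height=7.0)
    return render_scan(cfg, seed=0)


@pytest.fixture(scope="session")
def noisy_well():
    """A 15-position well at default noise and 1 µm tilt, truth 8.8 µm."""
    cfg = PhantomConfig(asl_height=8.8, tilt=1.0)
    return render_well(cfg, seed=42)
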