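import numpy as np
import pytest

import whiskerfit as wf


@pytest.fixture
def fit_config():
    """Deterministic fit configuration with alpha free around zero.

    Synthetic whiskers are generated in the standard frame, so the bounds
    envelope zero; multistarts are kept small for speed.
    """
    return wf.FitConfig(alpha_bounds=(-0.35, 0.35), seed=1, multistart_count=2)


def make_whisker(family, params, S=30.0, noise_dpi=None, seed=0, **kw):
    """Generate a synthetic whisker and preprocess it for fitting.

    Noise-free input skips the smoothing pass (nothing to denoise); noisy
    input gets the full smooth+resample pipeline.
    """
    spec = wf.SyntheticSpec(family, params, S=S, noise_dpi=noise_dpi, seed=seed, **kw)
    raw = wf.generate_whisker(spec)
    window = 4.0 if noise_dpi else None
    return wf.preprocess(raw, window_mm=window)


@pytest.fixture
def quadratic_trace():
    """Noise-free y = 0.02 x^2 whisker of 30 mm arc length, preprocessed."""
    return make_whisker("poly", {"orders": (2,), "coeffs": (0.02,)}).trace


def straight_trace(angle=0.0, length=10.0, n=201):
    """A perfectly straight resampled trace at a given angle."""
    t = np.linspace(0.0, length, n)
    pts = np.stack([t * np.cos(angle), t * np.sin(angle)], axis=-1)
    return wf.resample_trace(pts, spacing=0.25)
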