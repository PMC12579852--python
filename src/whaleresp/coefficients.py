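"""Published posterior-mean coefficients for the gray-whale recovery models.

These are the plug-in inputs to the daily FMR simulator: posterior means of
the recovery-design mixed models (headstand reference tactic, covariates
z-scored) for breath count (Poisson, log link), total inhalation duration,
and mean inter-breath interval (both Gaussian on the log scale).  The
z-scoring constants the original fits used are not published; the defaults
below span the simulated covariate grid (TL 9-12 m, BAI 22-32, dives
60-300 s) and are configurable.
"""

from __future__ import annotations

from .models import StandardizationConstants

__all__ = ["RECOVERY_POSTERIOR_MEANS", "default_standardization"]

RECOVERY_POSTERIOR_MEANS: dict[str, dict[str, float]] = {
    "breath_count": {
        "intercept": 0.83, "tl": 0.07, "bai": 0.11, "bubble": -0.02,
        "dive_duration": 0.16, "forward_swimming": -0.15,
        "subsurface_stationary": -0.39, "side_swim_stationary": -0.02,
        "surface_tactics": -0.44,
    },
    "total_inhalation": {
        "intercept": 1.01, "tl": 0.08, "bai": 0.08, "bubble": 0.02,
        "dive_duration": 0.16, "forward_swimming": -0.09,
        "subsurface_stationary": -0.38, "side_swim_stationary": -0.14,
        "surface_tactics": -0.51,
    },
    "mean_ibi": {
        "intercept": 2.64, "tl": 0.21, "bai": -0.07, "bubble": 0.09,
        "dive_duration": -0.13, "forward_swimming": 0.19,
        "subsurface_stationary": -0.12, "side_swim_stationary": -0.14,
        "surface_tactics": -0.09,
    },
}


def default_standardization() -> StandardizationConstants:
    """Default z-scoring constants for plug-in prediction (configurable)."""
    c = StandardizationConstants()
    c.set("tl", 10.5, 1.5)
    c.set("bai", 27.0, 5.0)
    c.set("dive_duration", 120.0, 120.0)
    return c
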