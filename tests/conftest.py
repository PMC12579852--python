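import numpy as np
import pytest

from whaleresp import (TruthParameters, generate_foraging_data,
                       generate_whales)
from whaleresp.metrics import sequence_table
from whaleresp.models import StandardizationConstants


@pytest.fixture(scope="session")
def default_params():
    return TruthParameters()


@pytest.fixture(scope="session")
def small_dataset(default_params):
    """Ten whales x six sequences with metrics table and manifest."""
    whales = generate_whales(10, default_params, seed=7)
    events, dives, manifest = generate_foraging_data(
        whales, default_params, 6, seed=8)
    metrics = sequence_table(events, dives)
    return {"whales": whales, "events": events, "dives": dives,
            "manifest": manifest, "metrics": metrics,
            "params": default_params}


def recovery_truth_params():
    """Generating parameters with effect sizes in the 0.1-0.3 band used by
    the parameter-recovery checks."""
    p = TruthParameters()
    for resp in ("breath_count", "total_inhalation", "mean_ibi"):
        p.coefficients[resp].update(
            tl=0.2, bai=0.15, dive_duration=0.12, bubble=-0.1,
            forward_swimming=-0.2, subsurface_stationary=-0.15,
            side_swim_stationary=0.1, surface_tactics=-0.3)
    return p


def population_constants(params):
    c = StandardizationConstants()
    c.set("tl", params.tl_mean_m, params.tl_sd_m)
    c.set("bai", params.bai_mean, params.bai_sd)
    return c
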