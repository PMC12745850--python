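import numpy as np
import pytest

from nyctinast import build_phase, cell_means
from nyctinast.synthdata import SimParams, simulate_motion

#: Coarse capture cadence used by simulation-heavy tests.  Cell means are
#: plain frame averages, so the cadence changes only the per-cell frame
#: count, not the estimand.
COARSE_DT = 120.0


@pytest.fixture(scope="session")
def phase1_schedule():
    """The 23-cycle, 24-h-day schedule of the main experiment."""
    return build_phase(1, 23)


@pytest.fixture(scope="session")
def phase2_schedule():
    """The 6-cycle, 20-h-day schedule."""
    return build_phase(2, 6)


def simulate_cells(schedule, capture_interval_s=COARSE_DT, **params):
    """Simulate a series and bin it, returning (cells, ground_truth)."""
    p = SimParams(**params)
    series, truth = simulate_motion(p, schedule, capture_interval_s)
    return cell_means(series, schedule), truth
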