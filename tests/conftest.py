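import numpy as np
import pytest

import ribotrace as rt
from ribotrace.calibration import detect_peaks, fit_ladder


@pytest.fixture(scope="session")
def migration():
    return rt.MigrationModel()


@pytest.fixture(scope="session")
def ladder():
    return rt.LadderSpec()


@pytest.fixture(scope="session")
def calibration(ladder):
    """Size calibration fitted from a noiseless synthetic ladder trace."""
    trace = rt.generate_ladder_trace(ladder)
    baseline = rt.estimate_baseline(trace)
    peaks = detect_peaks(trace, baseline)
    return fit_ladder(peaks, ladder)


def analyze_trace(trace, cal, construct_size=2000.0):
    """Shared helper: baseline + region integration for one trace."""
    baseline = rt.estimate_baseline(trace)
    return rt.integrate_regions(trace, baseline, cal, construct_size)


def riemann_region_areas(scenario, boundaries, model=None, oversample=10):
    """Independent oracle: midpoint Riemann sums of the analytic noiseless
    signal on a grid ``oversample``x finer than the instrument's, split at
    the boundaries reported by the integrator."""
    from ribotrace.synthetic import analytic_signal

    model = model or rt.MigrationModel()
    rate = model.sample_rate * oversample
    n = int(round(model.run_length * rate))
    t = (np.arange(n) + 0.5) / rate
    sig = analytic_signal(t, scenario, model, None)
    dt = 1.0 / rate

    def area(lo, hi):
        m = (t >= lo) & (t < hi)
        return float(sig[m].sum() * dt)

    b = boundaries
    return {
        "fragments": area(b["fragment_start"], b["dropped_line"]),
        "main": area(b["dropped_line"], b["upper_cut"]),
        "hmw": area(b["upper_cut"], model.run_length),
    }
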