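"""Synthetic microchip-CE electropherograms with known ground truth.

The generator emulates the signal structure of a short (~70 s) microchip
gel-electrophoresis separation of an mRNA-LNP sample after detergent
solubilisation and formamide denaturation:

* a lower-marker internal standard common to every injection,
* an 8-transcript RNA size ladder spanning 200-6000 nt,
* a Gaussian main peak for the intact construct (~2000 nt, ~49 s),
* a broad unresolved fragment smear earlier in the run,
* an optional high-molecular-weight (HMW) species at ~2x the construct
  size that appears only when the sample is incompletely denatured
  (low formamide, no heating),
* total non-marker area proportional to mRNA concentration and damped by
  detergent (Brij) concentration while the purity percentages are unchanged,
* additive polynomial baseline drift plus white Gaussian noise,
* first-order loss of the intact fraction with Arrhenius temperature
  dependence for whole stability studies, with total analyte area conserved
  (what the main peak loses, the fragment smear gains).

Migration time is log-linear in RNA size: ``t = t_ref + slope * log10(size /
s_ref)``. The defaults place a 2000 nt construct at 49 s, a 4000 nt HMW
species at ~56 s, and the fragment smear at ~31-45 s.

Everything is deterministic under a seed; the noiseless analytic signal is
exposed so tests can integrate it on arbitrarily fine grids.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import RibotraceError
from .traceio import Trace, TraceMeta

#: Universal gas constant, J/(mol K).
GAS_CONSTANT = 8.314

#: Supported RNA size range of the separation, nt.
SIZE_MIN, SIZE_MAX = 50.0, 6000.0

#: Non-marker peak area per unit mRNA concentration at the reference Brij
#: concentration, signal*s per (ug/mL).
AREA_PER_UG_ML = 100.0

#: Fixed lower-marker area, signal*s (internal standard, concentration-independent).
MARKER_AREA = 30.0

#: Gaussian widths in seconds: narrow for marker/ladder/main, broad for HMW
#: and for each component of the fragment smear.
SIGMA_NARROW = 0.4
SIGMA_HMW = 1.2
SIGMA_FRAGMENT = 0.8

#: Fragment envelope: number of Gaussian components and size range. The lower
#: bound keeps the smallest fragments clear of the lower-marker window.
N_FRAGMENT_COMPONENTS = 15
FRAGMENT_MIN_NT = 150.0
FRAGMENT_MAX_FACTOR = 0.7

#: HMW species is modelled at twice the construct size (incomplete denaturation
#: of paired structure).
HMW_SIZE_FACTOR = 2.0

#: Formamide threshold below which (without heating) the HMW species survives
#: sample preparation, % v/v.
FORMAMIDE_DENATURING_PCT = 40.0


@dataclass(frozen=True)
class MigrationModel:
    """Log-linear migration-time model ``t = t_ref + slope*log10(size/s_ref)``.

    Defaults anchor a 2000 nt construct at 49 s with 23.3 s per decade of
    size, which also places 4000 nt at ~56 s and 200 nt at ~25.7 s.
    """

    t_ref: float = 49.0
    s_ref: float = 2000.0
    slope: float = 23.3
    run_length: float = 70.0
    sample_rate: float = 20.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive (larger species migrate later)")
        if self.run_length <= 0 or self.sample_rate <= 0:
            raise ValueError("run_length and sample_rate must be positive")


@dataclass(frozen=True)
class LadderSpec:
    """An RNA size ladder plus the lower-marker internal standard."""

    transcript_sizes: tuple = (200.0, 500.0, 1000.0, 1500.0, 2000.0, 3000.0, 4000.0, 6000.0)
    lower_marker_time: float = 19.0
    relative_abundances: tuple | None = None

    def __post_init__(self) -> None:
        sizes = np.asarray(self.transcript_sizes, float)
        if sizes.size < 2 or np.any(np.diff(sizes) <= 0):
            raise ValueError("transcript sizes must be strictly increasing")
        if sizes.min() < SIZE_MIN or sizes.max() > SIZE_MAX:
            raise ValueError(f"transcript sizes must lie in [{SIZE_MIN}, {SIZE_MAX}] nt")
        if self.relative_abundances is not None:
            w = np.asarray(self.relative_abundances, float)
            if w.size != sizes.size or np.any(w <= 0):
                raise ValueError("relative abundances must be positive, one per transcript")

    @property
    def weights(self) -> np.ndarray:
        if self.relative_abundances is None:
            return np.ones(len(self.transcript_sizes))
        return np.asarray(self.relative_abundances, float)


@dataclass(frozen=True)
class SampleScenario:
    """Ground-truth composition of one injected sample.

    ``intact_fraction`` and ``hmw_fraction`` partition the analyte signal;
    the remainder is the fragment smear. ``brij_pct`` damps the total area
    (detergent effect) without changing the percentages.
    """

    concentration: float = 10.0
    intact_fraction: float = 0.8
    hmw_fraction: float = 0.0
    construct_size: float = 2000.0
    brij_pct: float = 10.0
    formamide_pct: float = 85.0
    heated: bool = True

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if not (0.0 <= self.intact_fraction <= 1.0 and 0.0 <= self.hmw_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.intact_fraction + self.hmw_fraction > 1.0 + 1e-12:
            raise ValueError("intact_fraction + hmw_fraction must not exceed 1")
        if not (SIZE_MIN <= self.construct_size <= SIZE_MAX):
            raise ValueError(f"construct_size must lie in [{SIZE_MIN}, {SIZE_MAX}] nt")


@dataclass(frozen=True)
class KineticTruth:
    """First-order Arrhenius degradation parameters of the simulated product.

    ``Ea`` in kJ/mol, ``lnA`` is the natural log of the pre-exponential in
    1/day. The default lnA anchors the rate at refrigerated temperature to a
    ~10-point integrity loss (from 80%) over 90 days.
    """

    Ea: float = 74.8
    lnA: float = 25.712
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.Ea < 0:
            raise ValueError("activation energy must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Additive detector noise: polynomial baseline drift + white Gaussian noise."""

    white_sd: float = 1.0
    drift_amplitude: float = 2.0
    drift_order: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd < 0:
            raise ValueError("white_sd must be non-negative")
        if self.drift_order < 0:
            raise ValueError("drift_order must be non-negative")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(white_sd=0.0, drift_amplitude=0.0, drift_order=0, seed=0)

    def with_seed(self, seed: int) -> "NoiseModel":
        return replace(self, seed=int(seed))


def size_to_time(model: MigrationModel, size: float) -> float:
    """Predicted apex time (s) of a species of the given length (nt)."""
    size_arr = np.asarray(size, dtype=float)
    if np.any(size_arr < SIZE_MIN) or np.any(size_arr > SIZE_MAX):
        raise ValueError(f"size {size} nt outside supported range [{SIZE_MIN}, {SIZE_MAX}]")
    t = model.t_ref + model.slope * np.log10(size_arr / model.s_ref)
    return float(t) if np.isscalar(size) or size_arr.ndim == 0 else t


def arrhenius_rate(truth: KineticTruth, temperature_K: float) -> float:
    """First-order degradation rate k(T) = exp(lnA - Ea/(R*T)), per day."""
    T = np.asarray(temperature_K, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    k = np.exp(truth.lnA - truth.Ea * 1000.0 / (truth.gas_constant * T))
    return float(k) if T.ndim == 0 else k


def brij_area_factor(brij_pct: float) -> float:
    """Relative total-area response vs Brij concentration (1.0 at 10% w/v).

    Modelled as a linear decrease of 0.04 per Brij percentage point, which
    passes through 1.35 at 1.25%, 1.0 at 10% and 0.8 at 15%. Purity
    percentages are unaffected, only the overall signal scale.
    """
    factor = 1.0 - 0.04 * (brij_pct - 10.0)
    return float(max(factor, 0.05))


def scenario_component_areas(scenario: SampleScenario) -> dict:
    """Intended (noiseless) region areas implied by a scenario, signal*s.

    The HMW portion is reported under ``hmw`` only when the preparation
    leaves the species intact (formamide below the denaturing threshold and
    no heating); otherwise it is folded into ``main``.
    """
    total = AREA_PER_UG_ML * scenario.concentration * brij_area_factor(scenario.brij_pct)
    hmw_visible = (
        scenario.formamide_pct < FORMAMIDE_DENATURING_PCT and not scenario.heated
    )
    hmw = scenario.hmw_fraction if hmw_visible else 0.0
    main = scenario.intact_fraction + (0.0 if hmw_visible else scenario.hmw_fraction)
    fragments = 1.0 - scenario.intact_fraction - scenario.hmw_fraction
    return {
        "main": total * main,
        "fragments": total * fragments,
        "hmw": total * hmw,
        "total": total,
    }


def _gaussian(t: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    amp = area / (sigma * np.sqrt(2.0 * np.pi))
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def fragment_component_sizes(construct_size: float) -> np.ndarray:
    """Centres (nt) of the Gaussian mixture forming the fragment smear."""
    upper = FRAGMENT_MAX_FACTOR * construct_size
    return np.geomspace(FRAGMENT_MIN_NT, upper, N_FRAGMENT_COMPONENTS)


def analytic_signal(
    t: np.ndarray,
    scenario: SampleScenario | None,
    model: MigrationModel,
    ladder: LadderSpec | None,
    marker_time: float | None = None,
) -> np.ndarray:
    """Noiseless analytic signal on an arbitrary time grid.

    If ``ladder`` is given the trace is a ladder injection (marker + one
    narrow peak per transcript); otherwise it is a sample/blank injection
    described by ``scenario``.
    """
    t = np.asarray(t, float)
    if marker_time is None:
        marker_time = ladder.lower_marker_time if ladder is not None else 19.0
    sig = _gaussian(t, marker_time, SIGMA_NARROW, MARKER_AREA)

    if ladder is not None:
        weights = ladder.weights
        per_area = 5.0 * AREA_PER_UG_ML * weights / weights.sum()
        for size, area in zip(ladder.transcript_sizes, per_area):
            sig += _gaussian(t, size_to_time(model, size), SIGMA_NARROW, area)
        return sig

    if scenario is None:
        raise ValueError("either a scenario or a ladder must be provided")
    areas = scenario_component_areas(scenario)
    if areas["total"] <= 0:
        return sig
    if areas["main"] > 0:
        sig += _gaussian(
            t, size_to_time(model, scenario.construct_size), SIGMA_NARROW, areas["main"]
        )
    if areas["hmw"] > 0:
        hmw_size = min(HMW_SIZE_FACTOR * scenario.construct_size, SIZE_MAX)
        sig += _gaussian(t, size_to_time(model, hmw_size), SIGMA_HMW, areas["hmw"])
    if areas["fragments"] > 0:
        sizes = fragment_component_sizes(scenario.construct_size)
        per = areas["fragments"] / sizes.size
        for size in sizes:
            sig += _gaussian(t, size_to_time(model, size), SIGMA_FRAGMENT, per)
    return sig


def _time_grid(model: MigrationModel) -> np.ndarray:
    n = int(round(model.run_length * model.sample_rate))
    if n < 500:
        raise ValueError("run_length * sample_rate must give at least 500 points")
    return np.arange(n) / model.sample_rate


def _noise_terms(t: np.ndarray, model: MigrationModel, noise: NoiseModel) -> np.ndarray:
    drift = noise.drift_amplitude * (t / model.run_length) ** noise.drift_order \
        if noise.drift_amplitude else 0.0
    rng = np.random.default_rng(noise.seed)
    white = rng.normal(0.0, noise.white_sd, t.size) if noise.white_sd > 0 else 0.0
    return drift + white


def generate_trace(
    scenario: SampleScenario | None,
    model: MigrationModel | None = None,
    ladder: LadderSpec | None = None,
    noise: NoiseModel | None = None,
    meta: TraceMeta | None = None,
) -> Trace:
    """Generate one electropherogram trace.

    Pass a ``scenario`` for a sample/blank injection, or a ``ladder`` for a
    ladder injection. Identical arguments (including the noise seed) produce
    bit-identical traces.
    """
    model = model or MigrationModel()
    noise = noise or NoiseModel.off()
    t = _time_grid(model)
    sig = analytic_signal(t, scenario, model, ladder)
    sig = sig + _noise_terms(t, model, noise)
    if meta is None:
        role = "ladder" if ladder is not None else (
            "blank" if scenario is not None and scenario.concentration == 0 else "sample"
        )
        meta = TraceMeta(sample_id=role, role=role,
                         conc_ug_ml=None if scenario is None else scenario.concentration)
    return Trace(t, sig, meta)


def child_seed(base_seed: int, sample_id: str) -> int:
    """Deterministic per-trace seed: mixing the global seed with the sample id
    means adding a sample never reshuffles the noise of the others."""
    mix = zlib.crc32(sample_id.encode("utf-8"))
    return int((int(base_seed) * 1000003 + mix) % (2**31 - 1))


@dataclass
class StabilityStudy:
    """Output of :func:`simulate_stability_study`: traces plus ground truth."""

    traces: list
    truth: pd.DataFrame  # temp_C, time_days, k_per_day, intact_fraction, integrity_pct
    kinetic_truth: KineticTruth
    start_integrity: float


def simulate_stability_study(
    truth: KineticTruth,
    start_integrity: float = 80.0,
    temperatures: Sequence[float] = (-20.0, 4.0, 25.0, 37.0, 45.0, 60.0),
    timepoints: Sequence[float] = (0.0, 4.0, 7.0, 14.0, 30.0, 60.0, 90.0),
    scenario: SampleScenario | None = None,
    noise: NoiseModel | None = None,
    model: MigrationModel | None = None,
    seed: int = 0,
) -> StabilityStudy:
    """Simulate a heat-stress stability study.

    At storage temperature T (deg C) and time t (days) the intact fraction is
    ``(start_integrity/100) * exp(-k(T) * t)`` with k from the Arrhenius
    truth; the fragment smear gains exactly the area the main peak loses, so
    the non-marker total area is conserved across all conditions.
    """
    temperatures = list(temperatures)
    timepoints = list(timepoints)
    if not temperatures or not timepoints:
        raise RibotraceError("temperature and timepoint lists must be non-empty")
    if min(timepoints) < 0:
        raise RibotraceError("timepoints must be non-negative")
    if 0.0 not in timepoints:
        raise RibotraceError("timepoints must include 0")
    if not (0.0 < start_integrity <= 100.0):
        raise ValueError("start_integrity must be in (0, 100]")
    base = scenario or SampleScenario()
    model = model or MigrationModel()
    noise = noise or NoiseModel.off()

    traces: list[Trace] = []
    rows = []
    for T in temperatures:
        k = arrhenius_rate(truth, T + 273.15)
        for t_days in timepoints:
            intact = (start_integrity / 100.0) * float(np.exp(-k * t_days))
            sid = f"T{T:g}C_d{t_days:g}"
            scen = replace(base, intact_fraction=intact, hmw_fraction=0.0)
            tr = generate_trace(
                scen,
                model=model,
                noise=noise.with_seed(child_seed(seed, sid)),
                meta=TraceMeta(sample_id=sid, role="sample",
                               conc_ug_ml=base.concentration,
                               temp_C=T, time_days=t_days),
            )
            traces.append(tr)
            rows.append(
                {"temp_C": T, "time_days": t_days, "k_per_day": k,
                 "intact_fraction": intact, "integrity_pct": 100.0 * intact}
            )
    return StabilityStudy(
        traces=traces,
        truth=pd.DataFrame(rows),
        kinetic_truth=truth,
        start_integrity=start_integrity,
    )


def generate_ladder_trace(
    ladder: LadderSpec | None = None,
    model: MigrationModel | None = None,
    noise: NoiseModel | None = None,
    meta: TraceMeta | None = None,
) -> Trace:
    """Convenience wrapper: a ladder injection with the default ladder."""
    return generate_trace(None, model=model, ladder=ladder or LadderSpec(),
                          noise=noise, meta=meta)
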