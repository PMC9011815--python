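"""Assay-qualification statistics: specificity, recovery, precision,
linearity and S/N-based detection/quantitation limits.

These follow the standard analytical-method conventions: percent recovery
against the theoretical purity of a designed mixture, relative standard
deviation (%CV) with the sample (n-1) standard deviation, ordinary
least-squares linearity of total peak area on concentration, and LOD/LOQ as
the lowest concentrations reaching S/N 3 and 10 respectively, interpolated
in log-concentration because dilution series are geometric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RibotraceError
from .integration import IntegrityResult

LOD_SNR = 3.0
LOQ_SNR = 10.0
PURITY_LOQ_SNR = 10.0


def recovery(
    observed_purity: float,
    purity_high: float,
    purity_low: float,
    mix_fraction: float = 0.5,
    concentration_high: float | None = None,
    concentration_low: float | None = None,
) -> tuple[float, float]:
    """Percent recovery of a designed high/low-purity mixture.

    ``theoretical = mix_fraction*purity_high + (1-mix_fraction)*purity_low``
    (the purity of a 1:1 mix is theoretically the average of the two
    components, assuming equal mRNA concentration); ``recovery = observed /
    theoretical * 100``. When component concentrations are supplied the
    theoretical purity is concentration-weighted instead.

    Returns ``(theoretical_purity, recovery_pct)``.
    """
    for name, val in (("observed", observed_purity), ("high", purity_high),
                      ("low", purity_low)):
        if not (0.0 <= val <= 100.0):
            raise ValueError(f"{name} purity {val} outside [0, 100]%")
    if not (0.0 <= mix_fraction <= 1.0):
        raise ValueError("mix_fraction must lie in [0, 1]")
    if concentration_high is not None and concentration_low is not None:
        wh = mix_fraction * concentration_high
        wl = (1.0 - mix_fraction) * concentration_low
        theoretical = (wh * purity_high + wl * purity_low) / (wh + wl)
    else:
        theoretical = mix_fraction * purity_high + (1.0 - mix_fraction) * purity_low
    if theoretical == 0:
        raise RibotraceError("theoretical purity is zero; recovery undefined")
    return float(theoretical), float(observed_purity / theoretical * 100.0)


def precision_rsd(values: Sequence[float]) -> float:
    """Relative standard deviation (%CV): sample SD / mean x 100."""
    arr = np.asarray(values, float)
    if arr.size < 2:
        raise ValueError("precision requires at least two replicates")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("mean of replicates is zero; RSD undefined")
    return float(arr.std(ddof=1) / mean * 100.0)


def linearity(
    concs: Sequence[float], total_areas: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of total peak area on concentration: (slope, intercept, R^2).

    R^2 is the squared Pearson correlation (0 for a flat response).
    """
    x = np.asarray(concs, float)
    y = np.asarray(total_areas, float)
    if np.unique(x).size < 3:
        raise ValueError("linearity requires at least three distinct concentrations")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return float(res.slope), float(res.intercept), r2


@dataclass
class LimitEstimate:
    """A detection/quantitation limit with an out-of-range flag.

    ``flag`` is ``None`` for an in-range estimate, ``"<min"`` when even the
    lowest tested concentration exceeds the S/N threshold, and ``">max"``
    when the threshold is never reached.
    """

    conc_ug_ml: float
    flag: str | None = None


def _limit_at(series: list[tuple[float, float]], threshold: float) -> LimitEstimate:
    concs = np.array([c for c, _ in series])
    snrs = np.array([s for _, s in series])
    above = snrs >= threshold
    if above[0]:
        return LimitEstimate(float(concs[0]), flag="<min")
    if not above.any():
        return LimitEstimate(float(concs[-1]), flag=">max")
    i = int(np.argmax(above))  # first crossing
    c0, c1 = np.log10(concs[i - 1]), np.log10(concs[i])
    s0, s1 = snrs[i - 1], snrs[i]
    frac = 1.0 if s1 == s0 else (threshold - s0) / (s1 - s0)
    return LimitEstimate(float(10.0 ** (c0 + frac * (c1 - c0))))


def lod_loq(
    dilution_series: Iterable[tuple[float, float]],
    lod_snr: float = LOD_SNR,
    loq_snr: float = LOQ_SNR,
) -> tuple[LimitEstimate, LimitEstimate]:
    """LOD and LOQ from a (concentration, S/N) dilution series.

    The limit is the lowest concentration whose S/N reaches the threshold,
    with log-linear interpolation between the bracketing points. The series
    must be sorted by concentration.
    """
    series = [(float(c), float(s)) for c, s in dilution_series]
    if len(series) < 2:
        raise ValueError("dilution series needs at least two points")
    concs = [c for c, _ in series]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("dilution series must be sorted by increasing concentration")
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be positive for log interpolation")
    return _limit_at(series, lod_snr), _limit_at(series, loq_snr)


def specificity_check(blank_results: Sequence[IntegrityResult]) -> bool:
    """Pass iff every analysed blank shows no analyte signal.

    A blank passes when its result carries the ``no-signal`` flag, i.e. no
    non-marker feature reached S/N 3 during integration.
    """
    blanks = list(blank_results)
    if not blanks:
        raise ValueError("no blank results supplied")
    return all(r.no_signal for r in blanks)


def purity_loq(
    results_with_conc: Sequence[tuple[float, IntegrityResult]],
    snr_threshold: float = PURITY_LOQ_SNR,
) -> LimitEstimate:
    """Lowest concentration at which the *purity percentage* is quantifiable.

    Below the peak-level LOQ the main peak may still be measurable while the
    fragment smear is lost in the baseline, making the percentage unreliable.
    A concentration qualifies when the trace has signal and the fragment
    region's *integrated* S/N (region area over the noise contribution to
    that area) reaches the threshold -- the height-based S/N of a broad,
    unresolved smear would understate how quantifiable its area is.
    """
    items = sorted(results_with_conc, key=lambda cr: cr[0])
    if not items:
        raise ValueError("no results supplied")
    for conc, res in items:
        if not res.no_signal and res.frag_area_snr >= snr_threshold:
            return LimitEstimate(float(conc))
    return LimitEstimate(float(items[-1][0]), flag=">max")


def system_suitability_summary(result_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and %CV of % fragments, % main peak and total area across runs.

    Mirrors the layout of a system-suitability control chart summary: one
    column per metric, rows ``Mean`` and ``% CV``.
    """
    cols = {"% Fragments": "pct_fragments", "% Main peak": "pct_main",
            "Total peak area": "total_area"}
    data = {}
    for label, col in cols.items():
        vals = pd.to_numeric(result_table[col], errors="coerce").dropna().to_numpy()
        if vals.size < 2:
            raise ValueError(f"need >= 2 results for {label}")
        data[label] = [vals.mean(), precision_rsd(vals)]
    return pd.DataFrame(data, index=["Mean", "% CV"])


@dataclass
class QualificationReport:
    """Aggregate qualification readout; numbers only, thresholds live in config."""

    specificity_pass: bool | None = None
    theoretical_purity: float | None = None
    observed_purity: float | None = None
    recovery_pct: float | None = None
    intra_rsd: dict = field(default_factory=dict)
    inter_rsd: dict = field(default_factory=dict)
    linearity_slope: float | None = None
    linearity_intercept: float | None = None
    r_squared: float | None = None
    lod: LimitEstimate | None = None
    loq: LimitEstimate | None = None
    purity_loq: LimitEstimate | None = None

    def __post_init__(self) -> None:
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")
        if self.lod is not None and self.loq is not None:
            if self.lod.flag is None and self.loq.flag is None \
                    and self.lod.conc_ug_ml > self.loq.conc_ug_ml + 1e-12:
                raise ValueError("LOD must not exceed LOQ")

    def to_dict(self) -> dict:
        def _lim(est: LimitEstimate | None):
            if est is None:
                return None
            return {"conc_ug_ml": est.conc_ug_ml, "flag": est.flag}

        return {
            "specificity_pass": self.specificity_pass,
            "theoretical_purity": self.theoretical_purity,
            "observed_purity": self.observed_purity,
            "recovery_pct": self.recovery_pct,
            "intra_rsd": self.intra_rsd,
            "inter_rsd": self.inter_rsd,
            "linearity_slope": self.linearity_slope,
            "linearity_intercept": self.linearity_intercept,
            "r_squared": self.r_squared,
            "lod": _lim(self.lod),
            "loq": _lim(self.loq),
            "purity_loq": _lim(self.purity_loq),
        }
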