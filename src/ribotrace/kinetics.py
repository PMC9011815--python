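"""Degradation kinetics: first-order rate constants and Arrhenius analysis.

mRNA chain scission is dominated by first-order bond breaking, so the
intact fraction decays as ``I(t) = I(0) * exp(-k t)`` and ``ln(I(t)/I(0))``
is linear in time with slope ``-k``. Across storage temperatures the rate
constants follow the Arrhenius relation ``ln k = ln A - Ea/(R T)``; the
slope of ln k against 1/T gives the activation energy Ea.

The module exposes the functional core (:func:`fit_first_order`,
:func:`fit_arrhenius`, :func:`predict_time_to_loss`) plus a model/results
pair (:class:`DegradationStudy` / :class:`KineticResults`) for fitting a
whole stability study from a tidy table in one call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FitError

#: Universal gas constant, J/(mol K).
GAS_CONSTANT = 8.314

#: Number of earliest positive timepoints used by the initial-rate fit.
INITIAL_RATE_POINTS = 3


def celsius_to_kelvin(temp_C: float) -> float:
    return float(temp_C) + 273.15


@dataclass
class StabilitySeries:
    """% integrity over time at a single storage temperature."""

    temperature_C: float
    timepoints: np.ndarray
    integrity: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, float)
        self.integrity = np.asarray(self.integrity, float)
        if self.timepoints.size != self.integrity.size:
            raise ValueError("timepoints and integrity must have equal length")
        if np.any(self.timepoints < 0) or np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be non-negative and strictly increasing")
        if np.any(self.integrity < -1e-9) or np.any(self.integrity > 100 + 1e-9):
            raise ValueError("integrity must lie in [0, 100]%")


@dataclass
class FirstOrderFit:
    """A per-temperature first-order rate constant with its uncertainty."""

    temperature_C: float
    k_per_day: float
    se: float
    mode: str
    n_used: int
    n_excluded: int
    r_squared: float


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS fit y = a + b x; returns (slope, intercept, slope_se, r_squared)."""
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        raise FitError("degenerate design: all x identical")
    slope = float(((x - xbar) * (y - ybar)).sum() / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - (intercept + slope * x)
    sst = float(((y - ybar) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - float((resid**2).sum()) / sst
    dof = n - 2
    se = math.sqrt(float((resid**2).sum()) / dof / sxx) if dof > 0 else float("nan")
    return slope, intercept, se, r2


def fit_first_order(
    series: StabilitySeries,
    mode: str = "initial-rate",
    n_initial: int = INITIAL_RATE_POINTS,
) -> FirstOrderFit:
    """Fit ``ln(I(t)/I(0))`` against time; the rate constant is minus the slope.

    ``mode="full-curve"`` regresses over every timepoint with positive
    integrity (>= 3 required); ``mode="initial-rate"`` restricts to the
    earliest ``n_initial`` positive points (>= 2 required), estimating the
    initial rate constant before depletion effects. Points at or below 0%
    integrity are excluded (their log is undefined) and counted in
    ``n_excluded`` so saturated series remain visibly censored.
    """
    if mode not in ("initial-rate", "full-curve"):
        raise ValueError(f"unknown fit mode {mode!r}")
    t = series.timepoints
    y = series.integrity
    pos = y > 0
    n_excluded = int((~pos).sum())
    t_pos, y_pos = t[pos], y[pos]
    if t_pos.size == 0 or y_pos[0] <= 0:
        raise FitError("no positive-integrity points to fit")
    required = 3 if mode == "full-curve" else 2
    if mode == "initial-rate":
        t_pos = t_pos[:n_initial]
        y_pos = y_pos[:n_initial]
    if t_pos.size < required:
        raise FitError(
            f"{mode} fit needs >= {required} positive points, have {t_pos.size}"
        )
    logratio = np.log(y_pos / y_pos[0])
    slope, _, se, r2 = _ols_line(t_pos, logratio)
    k = -slope
    if k < 0:
        warnings.warn(
            f"negative fitted rate at {series.temperature_C:g} C clamped to 0",
            stacklevel=2,
        )
        k = 0.0
    return FirstOrderFit(
        temperature_C=series.temperature_C, k_per_day=float(k), se=float(se),
        mode=mode, n_used=int(t_pos.size), n_excluded=n_excluded, r_squared=r2,
    )


@dataclass
class ArrheniusFit:
    """Arrhenius parameters from regression of ln k on 1/T."""

    Ea_kJ_mol: float
    Ea_se: float
    lnA: float
    lnA_se: float
    r_squared: float
    n_used: int
    excluded_temperatures: list = field(default_factory=list)
    weighted: bool = False

    def rate_at(self, temp_C: float) -> float:
        """Extrapolated rate constant (per day) at a temperature in deg C."""
        T = celsius_to_kelvin(temp_C)
        return float(np.exp(self.lnA - self.Ea_kJ_mol * 1000.0 / (GAS_CONSTANT * T)))


def fit_arrhenius(
    fits: Sequence[tuple[float, float]],
    k_se: Sequence[float] | None = None,
) -> ArrheniusFit:
    """Regress ln k on 1/T over (temperature_C, k_per_day) pairs.

    ``Ea = -slope * R / 1000`` in kJ/mol. Temperatures with k <= 0 are
    excluded (and listed); at least two positive rates are required. When
    per-temperature standard errors of k are supplied, the fit is weighted
    least squares with known variances ``se(ln k) = se(k)/k`` and parameter
    covariance ``(X' W X)^-1`` -- appropriate when the scatter about the
    Arrhenius line is the propagated uncertainty of the rate-constant fits.
    R^2 is reported on the unweighted (1/T, ln k) points.
    """
    pairs = [(float(T), float(k)) for T, k in fits]
    excluded = [T for T, k in pairs if k <= 0]
    kept = [(T, k) for T, k in pairs if k > 0]
    if not kept:
        raise FitError("no measurable degradation: all rate constants are zero")
    if len(kept) < 2:
        raise FitError("Arrhenius fit requires >= 2 temperatures with k > 0")
    if k_se is not None and len(k_se) != len(pairs):
        raise ValueError("k_se must match fits in length")

    x = np.array([1.0 / celsius_to_kelvin(T) for T, _ in kept])
    y = np.array([math.log(k) for _, k in kept])

    if k_se is not None:
        se_lnk = np.array(
            [float(se) / k for (T, k), se in zip(pairs, k_se) if k > 0]
        )
        if np.any(~np.isfinite(se_lnk)) or np.any(se_lnk <= 0):
            raise ValueError("k_se must be finite and positive for kept temperatures")
        w = 1.0 / se_lnk**2
        X = np.column_stack([np.ones_like(x), x])
        XtWX = X.T @ (w[:, None] * X)
        cov = np.linalg.inv(XtWX)
        beta = cov @ (X.T @ (w * y))
        intercept, slope = float(beta[0]), float(beta[1])
        intercept_se, slope_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        weighted = True
    else:
        slope, intercept, slope_se, _ = _ols_line(x, y)
        n = x.size
        sxx = float(((x - x.mean()) ** 2).sum())
        resid = y - (intercept + slope * x)
        dof = n - 2
        s2 = float((resid**2).sum()) / dof if dof > 0 else float("nan")
        intercept_se = (
            math.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx)) if dof > 0 else float("nan")
        )
        weighted = False

    sst = float(((y - y.mean()) ** 2).sum())
    resid = y - (intercept + slope * x)
    r2 = 1.0 if sst == 0 else 1.0 - float((resid**2).sum()) / sst

    return ArrheniusFit(
        Ea_kJ_mol=float(-slope * GAS_CONSTANT / 1000.0),
        Ea_se=float(slope_se * GAS_CONSTANT / 1000.0) if np.isfinite(slope_se) else float("nan"),
        lnA=float(intercept),
        lnA_se=float(intercept_se),
        r_squared=r2,
        n_used=int(x.size),
        excluded_temperatures=excluded,
        weighted=weighted,
    )


def predict_time_to_loss(
    loss_fraction: float,
    model: str = "first-order",
    k_per_day: float | None = None,
    rate_points_per_day: float | None = None,
    start_integrity: float | None = None,
    arrhenius: ArrheniusFit | None = None,
    temp_C: float | None = None,
) -> float:
    """Days until the product loses ``loss_fraction`` of its starting mRNA.

    ``model="first-order"``: exponential decay of the intact fraction,
    ``t = -ln(1 - loss_fraction) / k``; supply ``k_per_day`` directly or an
    :class:`ArrheniusFit` plus a temperature.

    ``model="zero-order"``: linear loss of percentage points,
    ``t = loss_fraction * start_integrity / rate_points_per_day`` -- the
    extrapolation a constant observed points-per-day decline implies.

    The two models genuinely disagree away from small losses; they are
    reported separately, never mixed.
    """
    if not (0.0 < loss_fraction < 1.0):
        raise ValueError("loss_fraction must lie strictly between 0 and 1")
    if model == "first-order":
        k = k_per_day
        if k is None:
            if arrhenius is None or temp_C is None:
                raise ValueError("supply k_per_day or (arrhenius, temp_C)")
            k = arrhenius.rate_at(temp_C)
        if k < 0:
            raise ValueError("rate constant must be non-negative")
        if k == 0:
            warnings.warn("zero rate constant: time to loss is infinite", stacklevel=2)
            return float("inf")
        return float(-math.log(1.0 - loss_fraction) / k)
    if model == "zero-order":
        if rate_points_per_day is None or start_integrity is None:
            raise ValueError("zero-order model needs rate_points_per_day and start_integrity")
        if rate_points_per_day < 0:
            raise ValueError("rate must be non-negative")
        if rate_points_per_day == 0:
            warnings.warn("zero rate: time to loss is infinite", stacklevel=2)
            return float("inf")
        return float(loss_fraction * start_integrity / rate_points_per_day)
    raise ValueError(f"unknown kinetic model {model!r}")


class DegradationStudy:
    """Statsmodels-style model for a multi-temperature stability study.

    Built from a tidy table with columns ``temp_C``, ``time_days`` and
    ``integrity`` (% main peak); :meth:`fit` estimates one first-order rate
    constant per temperature and the Arrhenius line across temperatures.
    """

    REQUIRED = ("temp_C", "time_days", "integrity")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"missing required column(s) {missing}")
        self.data = (
            data.loc[:, list(self.REQUIRED)]
            .dropna()
            .sort_values(["temp_C", "time_days"])
            .reset_index(drop=True)
        )
        if self.data.empty:
            raise ValueError("no usable rows in stability table")

    @classmethod
    def from_result_table(
        cls, results: pd.DataFrame, sheet: pd.DataFrame
    ) -> "DegradationStudy":
        """Join an integration result table with its sample sheet."""
        merged = results.merge(
            sheet[["sample_id", "temp_C", "time_days"]], on="sample_id", how="inner"
        )
        merged = merged.rename(columns={"pct_main": "integrity"})
        return cls(merged[["temp_C", "time_days", "integrity"]])

    def series(self) -> list[StabilitySeries]:
        out = []
        for T, grp in self.data.groupby("temp_C", sort=True):
            out.append(
                StabilitySeries(
                    temperature_C=float(T),
                    timepoints=grp["time_days"].to_numpy(),
                    integrity=grp["integrity"].to_numpy(),
                )
            )
        return out

    def fit(self, mode: str = "initial-rate",
            weighted_arrhenius: bool = True) -> "KineticResults":
        fits: list[FirstOrderFit] = []
        for ser in self.series():
            try:
                fits.append(fit_first_order(ser, mode=mode))
            except FitError as exc:
                warnings.warn(
                    f"temperature {ser.temperature_C:g} C skipped: {exc}", stacklevel=2
                )
        if not fits:
            raise FitError("no temperature could be fitted")
        pairs = [(f.temperature_C, f.k_per_day) for f in fits]
        ses = [f.se for f in fits]
        use_w = weighted_arrhenius and all(np.isfinite(s) and s > 0 for s in ses)
        arr = fit_arrhenius(pairs, k_se=ses if use_w else None)
        return KineticResults(model=self, rate_fits=fits, arrhenius=arr, mode=mode)


class KineticResults:
    """Results of :meth:`DegradationStudy.fit`."""

    def __init__(self, model: DegradationStudy, rate_fits: list[FirstOrderFit],
                 arrhenius: ArrheniusFit, mode: str):
        self.model = model
        self.rate_fits = rate_fits
        self.arrhenius = arrhenius
        self.mode = mode

    @property
    def rate_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "temp_C": f.temperature_C,
                    "k_per_day": f.k_per_day,
                    "k_se": f.se,
                    "mode": f.mode,
                    "n_used": f.n_used,
                    "n_excluded": f.n_excluded,
                    "r_squared": f.r_squared,
                }
                for f in self.rate_fits
            ]
        )

    def arrhenius_table(self) -> pd.DataFrame:
        """(1/T_K, ln k) pairs for plotting the Arrhenius line."""
        rows = [
            {
                "temp_C": f.temperature_C,
                "inv_T_K": 1.0 / celsius_to_kelvin(f.temperature_C),
                "ln_k": math.log(f.k_per_day) if f.k_per_day > 0 else float("nan"),
            }
            for f in self.rate_fits
        ]
        return pd.DataFrame(rows)

    def predict_time_to_loss(self, loss_fraction: float, temp_C: float,
                             model: str = "first-order",
                             start_integrity: float | None = None) -> float:
        if model == "first-order":
            return predict_time_to_loss(
                loss_fraction, model="first-order",
                arrhenius=self.arrhenius, temp_C=temp_C,
            )
        # zero-order extrapolation from the observed early decline at temp_C
        fits = {f.temperature_C: f for f in self.rate_fits}
        if temp_C not in fits:
            raise ValueError(f"no fitted series at {temp_C:g} C")
        grp = self.model.data[self.model.data["temp_C"] == temp_C]
        start = start_integrity if start_integrity is not None \
            else float(grp["integrity"].iloc[0])
        k = fits[temp_C].k_per_day
        rate_pts = start * (1.0 - math.exp(-k)) if k > 0 else 0.0  # points/day initially
        return predict_time_to_loss(
            loss_fraction, model="zero-order",
            rate_points_per_day=rate_pts, start_integrity=start,
        )

    def summary(self) -> str:
        lines = [
            "Degradation kinetics (first-order / Arrhenius)",
            "=" * 54,
            f"fit mode: {self.mode}",
            "",
            f"{'T (C)':>8} {'k (1/day)':>14} {'SE':>12} {'n':>4} {'excl':>5}",
        ]
        for f in self.rate_fits:
            lines.append(
                f"{f.temperature_C:8.1f} {f.k_per_day:14.5e} "
                f"{f.se:12.3e} {f.n_used:4d} {f.n_excluded:5d}"
            )
        a = self.arrhenius
        lines += [
            "",
            f"Ea  = {a.Ea_kJ_mol:8.2f} +/- {a.Ea_se:.2f} kJ/mol",
            f"lnA = {a.lnA:8.3f} +/- {a.lnA_se:.3f} (A in 1/day)",
            f"R^2 (ln k vs 1/T) = {a.r_squared:.6f}",
        ]
        if a.excluded_temperatures:
            lines.append(
                f"excluded (k <= 0): {', '.join(f'{T:g} C' for T in a.excluded_temperatures)}"
            )
        return "\n".join(lines)

    def plot_arrhenius(self, ax=None):
        """Arrhenius plot: ln k against 1/T with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.arrhenius_table().dropna()
        ax.plot(tab["inv_T_K"], tab["ln_k"], "o", label="fitted rate constants")
        xs = np.linspace(tab["inv_T_K"].min(), tab["inv_T_K"].max(), 50)
        a = self.arrhenius
        ax.plot(xs, a.lnA - a.Ea_kJ_mol * 1000.0 / GAS_CONSTANT * xs, "-",
                label=f"Ea = {a.Ea_kJ_mol:.1f} kJ/mol")
        ax.set_xlabel("1/T (1/K)")
        ax.set_ylabel("ln k (k in 1/day)")
        ax.legend()
        return ax
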