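"""Two-state thermal melting analysis of variable-temperature chemical shifts.

The observable chemical shift of a proton exchanging fast between a folded
and an unfolded state follows

    delta(T) = delta_U + (delta_F - delta_U) / (1 + exp(-dH_m/R (1/T - 1/T_m)))

where ``delta_U`` / ``delta_F`` are the terminal shifts of the fully
unfolded / folded states, ``T_m`` the melting temperature (folded fraction
0.5) and ``dH_m`` the enthalpy change upon unfolding at ``T_m``.  With this
sign convention ``delta -> delta_U`` as ``T -> inf`` and ``dH_m > 0`` for a
cooperative unfolding transition.

The module provides per-proton fits (:class:`TwoStateMelt`), the pooled
normalised global fit (:class:`GlobalMelt`), folding free energies by two
routes, a van't Hoff entropy cross-check, amide temperature coefficients
with their hydrogen-bonding classification, and the relative-stability
(slope) analysis comparing two compounds without reference to absolute
terminal populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .constants import R_GAS

__all__ = [
    "ShiftMeltSeries",
    "TwoStateMelt",
    "GlobalMelt",
    "MeltFitError",
    "RelativeStability",
    "fit_two_state",
    "folded_fraction",
    "global_melt_fit",
    "delta_g",
    "van_t_hoff_entropy",
    "relative_folding",
    "temperature_coefficients",
    "read_vt_table",
]


class MeltFitError(RuntimeError):
    """Raised when a melting-curve fit cannot be carried out."""

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass
class ShiftMeltSeries:
    """Chemical shift of one proton across a strictly increasing T grid."""

    proton_label: str
    temperatures: np.ndarray  # K
    shifts: np.ndarray  # ppm

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, float)
        self.shifts = np.asarray(self.shifts, float)
        if self.temperatures.shape != self.shifts.shape:
            raise ValueError("temperature and shift arrays differ in length")
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be positive (kelvin)")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temperatures)


def two_state_shift(T, delta_u, delta_f, tm, dhm):
    """Evaluate the two-state shift model (ppm)."""
    T = np.asarray(T, float)
    frac = 1.0 / (1.0 + np.exp(-dhm / R_GAS * (1.0 / T - 1.0 / tm)))
    return delta_u + (delta_f - delta_u) * frac


class TwoStateMelt(BaseEstimator):
    """Nonlinear least-squares fit of a single proton's melting curve.

    Parameters
    ----------
    init : tuple, optional
        Optional (delta_u, delta_f, tm, dhm) starting guess; when given it
        replaces the default multi-start grid.
    shift_floor : float
        Minimum shift change (ppm) across the series below which the data is
        rejected as showing no transition.

    Attributes (after ``fit``)
    --------------------------
    delta_u_, delta_f_ : float  -- terminal shifts, ppm
    tm_ : float                 -- melting temperature, K
    dhm_ : float                -- unfolding enthalpy at T_m, J/mol
    cov_ : (4, 4) ndarray       -- parameter covariance
    residuals_ : ndarray        -- per-point residuals, ppm
    sse_ : float
    """

    def __init__(self, init=None, shift_floor=0.01, max_nfev=5000):
        self.init = init
        self.shift_floor = shift_floor
        self.max_nfev = max_nfev

    # -- helpers -----------------------------------------------------------

    def _starts(self, T, d):
        if self.init is not None:
            return [tuple(self.init)]
        n = len(T)
        k = max(1, n // 10)
        cold = float(np.mean(d[:k]))
        hot = float(np.mean(d[-k:]))
        span = T[-1] - T[0]
        return [
            (hot, cold, T[0] + f * span, 25_000.0) for f in (1 / 6, 1 / 2, 5 / 6)
        ]

    def fit(self, T, shifts=None):
        """Fit the model.  ``T`` may be a :class:`ShiftMeltSeries`."""
        if isinstance(T, ShiftMeltSeries):
            series = T
        else:
            series = ShiftMeltSeries("proton", np.asarray(T, float),
                                     np.asarray(shifts, float))
        if len(series) < 5:
            raise MeltFitError(
                f"{series.proton_label}: need >= 5 temperature points, "
                f"got {len(series)}"
            )
        T_arr, d = series.temperatures, series.shifts
        if np.ptp(d) < self.shift_floor:
            raise MeltFitError(
                f"{series.proton_label}: no transition detected (shift change "
                f"{np.ptp(d):.4f} ppm below floor {self.shift_floor})"
            )

        def resid(theta):
            return two_state_shift(T_arr, *theta) - d

        best = None
        lo = [-np.inf, -np.inf, T_arr[0] - 50.0, 1.0]
        hi = [np.inf, np.inf, T_arr[-1] + 50.0, np.inf]
        for theta0 in self._starts(T_arr, d):
            theta0 = np.clip(theta0, lo, hi)
            try:
                sol = least_squares(resid, theta0, bounds=(lo, hi),
                                    max_nfev=self.max_nfev)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise MeltFitError(f"{series.proton_label}: all fit starts failed")
        if not best.success:
            raise MeltFitError(
                f"{series.proton_label}: melt fit did not converge", partial=best
            )

        self.proton_label_ = series.proton_label
        self.delta_u_, self.delta_f_, self.tm_, self.dhm_ = map(float, best.x)
        self.residuals_ = resid(best.x)
        self.sse_ = float(np.sum(self.residuals_**2))
        dof = max(len(T_arr) - 4, 1)
        s2 = self.sse_ / dof
        jtj = best.jac.T @ best.jac
        try:
            self.cov_ = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            self.cov_ = np.full((4, 4), np.nan)
        self.series_ = series
        return self

    def predict(self, T):
        """Back-calculate delta(T) in ppm from the fitted parameters."""
        return two_state_shift(T, self.delta_u_, self.delta_f_, self.tm_,
                               self.dhm_)

    @property
    def params_(self):
        return {
            "delta_u": self.delta_u_, "delta_f": self.delta_f_,
            "tm": self.tm_, "dhm": self.dhm_,
        }


def fit_two_state(series: ShiftMeltSeries, init=None) -> TwoStateMelt:
    """Functional wrapper over :class:`TwoStateMelt`."""
    return TwoStateMelt(init=init).fit(series)


def folded_fraction(fit, T) -> float | np.ndarray:
    """Molar fraction of the folded state at temperature T (kelvin).

    ``fit`` may be a fitted :class:`TwoStateMelt` / :class:`GlobalMelt` or a
    (tm, dhm) tuple.
    """
    tm, dhm = (fit.tm_, fit.dhm_) if hasattr(fit, "tm_") else fit
    T = np.asarray(T, float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    f = 1.0 / (1.0 + np.exp(-dhm / R_GAS * (1.0 / T - 1.0 / tm)))
    return float(f) if f.ndim == 0 else f


class GlobalMelt(BaseEstimator):
    """Pooled two-state fit across many protons.

    Stage 1 fits each proton individually; stage 2 rescales each series to
    fraction folded using its own fitted terminals (normalisation to the
    maximum shift change); stage 3 fits the shared (T_m, dH_m) to the pooled
    normalised points with terminals pinned at 0 and 1.  Protons whose
    individual fit fails are excluded with a warning.
    """

    def __init__(self, shift_floor=0.01):
        self.shift_floor = shift_floor

    def fit(self, series_set):
        series_set = list(series_set)
        if len(series_set) < 2:
            raise MeltFitError("global fit needs at least 2 series")
        fits: dict[str, TwoStateMelt] = {}
        excluded: list[str] = []
        for s in series_set:
            try:
                fits[s.proton_label] = TwoStateMelt(
                    shift_floor=self.shift_floor).fit(s)
            except MeltFitError as exc:
                warnings.warn(
                    f"excluding proton {s.proton_label!r} from global melt "
                    f"fit: {exc}"
                )
                excluded.append(s.proton_label)
        if len(fits) < 2:
            raise MeltFitError(
                f"fewer than 2 protons survived individual fitting "
                f"({len(fits)} of {len(series_set)})"
            )
        T_all, f_all = [], []
        for s in series_set:
            if s.proton_label not in fits:
                continue
            pf = fits[s.proton_label]
            frac = (s.shifts - pf.delta_u_) / (pf.delta_f_ - pf.delta_u_)
            T_all.append(s.temperatures)
            f_all.append(frac)
        T_arr = np.concatenate(T_all)
        f_arr = np.concatenate(f_all)

        def resid(theta):
            tm, dhm = theta
            return 1.0 / (1.0 + np.exp(-dhm / R_GAS *
                                       (1.0 / T_arr - 1.0 / tm))) - f_arr

        tm0 = float(np.median([pf.tm_ for pf in fits.values()]))
        dhm0 = float(np.median([pf.dhm_ for pf in fits.values()]))
        sol = least_squares(resid, (tm0, dhm0),
                            bounds=([T_arr.min() - 50.0, 1.0],
                                    [T_arr.max() + 50.0, np.inf]))
        if not sol.success:
            raise MeltFitError("global melt fit did not converge", partial=sol)
        self.tm_, self.dhm_ = map(float, sol.x)
        self.delta_u_, self.delta_f_ = 0.0, 1.0
        self.residuals_ = resid(sol.x)
        self.sse_ = float(np.sum(self.residuals_**2))
        dof = max(len(T_arr) - 2, 1)
        jtj = sol.jac.T @ sol.jac
        try:
            self.cov_ = self.sse_ / dof * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            self.cov_ = np.full((2, 2), np.nan)
        self.per_proton_ = fits
        self.excluded_ = excluded
        return self

    def predict(self, T):
        """Pooled normalised melting curve, i.e. folded fraction at T."""
        return folded_fraction(self, T)


def global_melt_fit(series_set) -> GlobalMelt:
    """Functional wrapper over :class:`GlobalMelt`."""
    return GlobalMelt().fit(series_set)


def delta_g(fit=None, T=298.0, *, dhm=None, dsm=None, shift=None):
    """Standard folding free energy at T, J/mol, plus the folding constant.

    Two routes are exposed:

    (a) from a fit (and optionally an observed shift at T):
        ``k_F = (delta_U - delta(T)) / (delta(T) - delta_F)``, which for
        exact two-state data equals ``exp(dH_m/R (1/T - 1/T_m))``;
        ``dG = -R T ln k_F``.
    (b) from tabulated (dH_m, dS_m): ``dG = dH_m - T dS_m`` (k_F follows
        from dG), assuming dH constant in temperature.

    Returns
    -------
    (dg, k_f) : tuple of float
    """
    if T <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if dhm is not None and dsm is not None:
        dg = dhm - T * dsm
        return float(dg), float(np.exp(-dg / (R_GAS * T)))
    if fit is None:
        raise ValueError("either a fit or (dhm, dsm) must be supplied")
    if shift is not None:
        lo, hi = sorted((fit.delta_u_, fit.delta_f_))
        if not (lo < shift < hi):
            raise ValueError(
                f"shift {shift} ppm outside the fitted terminals "
                f"({lo:.3f}, {hi:.3f}): folded fraction outside [0, 1]"
            )
        k_f = (fit.delta_u_ - shift) / (shift - fit.delta_f_)
    else:
        k_f = float(np.exp(fit.dhm_ / R_GAS * (1.0 / T - 1.0 / fit.tm_)))
    return float(-R_GAS * T * np.log(k_f)), float(k_f)


def van_t_hoff_entropy(fit: TwoStateMelt, f_bounds=(0.02, 0.98)):
    """Entropy/enthalpy from the van't Hoff line of the fitted series.

    ln k_F computed from the observed shifts and the fitted terminals is
    regressed on 1/T over points whose folded fraction lies strictly inside
    ``f_bounds``.  For exact two-state data the slope reproduces dH_m/R and
    the intercept -dH_m/(R T_m), i.e. dS = dH_m/T_m.

    Returns a dict with unfolding-convention ``ds`` (J/(K mol)), ``dh``
    (J/mol) and the intercept standard error.
    """
    s = fit.series_
    frac = (s.shifts - fit.delta_u_) / (fit.delta_f_ - fit.delta_u_)
    mask = (frac > f_bounds[0]) & (frac < f_bounds[1])
    if mask.sum() < 4:
        raise MeltFitError(
            f"van't Hoff regression needs >= 4 points with folded fraction in "
            f"{f_bounds}, got {int(mask.sum())}"
        )
    k_f = frac[mask] / (1.0 - frac[mask])
    x = 1.0 / s.temperatures[mask]
    y = np.log(k_f)
    coeffs, cov = np.polyfit(x, y, 1, cov=True)
    slope, intercept = coeffs
    # folding convention: ln k_F = (dH_m/R)(1/T) - dH_m/(R T_m)
    dh = float(R_GAS * slope)           # unfolding enthalpy
    ds = float(-R_GAS * intercept)      # unfolding entropy
    return {
        "ds": ds,
        "dh": dh,
        "ds_stderr": float(R_GAS * np.sqrt(cov[1, 1])),
        "n_points": int(mask.sum()),
    }


@dataclass
class RelativeStability:
    """Ratio of folding constants of two compounds and the derived ddG."""

    k_ratio: float
    ddg: float  # J/mol, = -R T_m2 ln K
    slope_stderr: float
    points: pd.DataFrame = field(repr=False)


def relative_folding(series1: ShiftMeltSeries, series2: ShiftMeltSeries,
                     terminals1: tuple[float, float],
                     terminals2: tuple[float, float],
                     tm2: float) -> RelativeStability:
    """Relative folding constant K = k_F1/k_F2 from matched-temperature shifts.

    For each common temperature t the bilinear products

        y_t = (dU1 - d1_t) (d2_t - dF2),   x_t = (d1_t - dF1) (dU2 - d2_t)

    satisfy y = K x exactly when k_F1 = K k_F2; K is the slope of the
    zero-intercept least-squares line through the (x, y) points.  Points
    whose shift falls outside its own terminals (folded fraction outside
    [0, 1]) are dropped with a warning.  ddG = -R T_m2 ln K with T_m2 the
    reference compound's melting temperature.
    """
    if not np.allclose(series1.temperatures, series2.temperatures):
        raise ValueError("the two compounds must be observed at matched "
                         "temperatures")
    du1, df1 = terminals1
    du2, df2 = terminals2
    rows = []
    for t, d1, d2 in zip(series1.temperatures, series1.shifts, series2.shifts):
        in1 = min(du1, df1) <= d1 <= max(du1, df1)
        in2 = min(du2, df2) <= d2 <= max(du2, df2)
        if not (in1 and in2):
            warnings.warn(
                f"dropping T={t:.1f} K: shift outside terminal window"
            )
            continue
        rows.append(
            {"T": t, "x": (d1 - df1) * (du2 - d2), "y": (du1 - d1) * (d2 - df2)}
        )
    if not rows:
        raise MeltFitError("no usable temperature points for the relative "
                           "folding regression")
    pts = pd.DataFrame(rows)
    x, y = pts["x"].to_numpy(), pts["y"].to_numpy()
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise MeltFitError("degenerate regression: all x products are zero")
    k = float(np.dot(x, y) / sxx)
    resid = y - k * x
    dof = max(len(x) - 1, 1)
    stderr = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    ddg = float(-R_GAS * tm2 * np.log(k))
    return RelativeStability(k_ratio=k, ddg=ddg, slope_stderr=stderr, points=pts)


# temperature-coefficient bands, ppb/K; exact 3 and 5 fall in the middle band
TEMPCO_CLASSES = (
    (3.0, "intramolecular H-bond"),
    (5.0, "dynamic equilibrium"),
    (np.inf, "solvent exposed"),
)


def temperature_coefficients(series_set) -> pd.DataFrame:
    """Amide temperature coefficients |d delta/dT| in ppb/K with classes.

    Magnitudes below 3 ppb/K indicate an intramolecular hydrogen bond, 3-5
    (inclusive) a dynamic equilibrium between bonded and exposed states, and
    above 5 a solvent-exposed proton.
    """
    rows = []
    for s in series_set:
        if len(s) < 3:
            raise ValueError(
                f"{s.proton_label}: temperature coefficient needs >= 3 points"
            )
        slope = np.polyfit(s.temperatures, s.shifts, 1)[0]
        coeff = abs(float(slope)) * 1000.0  # ppm/K -> ppb/K
        if coeff < TEMPCO_CLASSES[0][0]:
            cls = TEMPCO_CLASSES[0][1]
        elif coeff <= TEMPCO_CLASSES[1][0]:
            cls = TEMPCO_CLASSES[1][1]
        else:
            cls = TEMPCO_CLASSES[2][1]
        rows.append({"proton": s.proton_label, "coeff_ppb_per_K": coeff,
                     "class": cls})
    return pd.DataFrame(rows).set_index("proton")


def read_vt_table(path) -> list[ShiftMeltSeries]:
    """Read a variable-temperature shift table.

    Delimited text; first column the temperature in kelvin, one column per
    proton in ppm.  Missing cells are allowed and dropped per proton.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    tcol = df.columns[0]
    out = []
    for col in df.columns[1:]:
        sub = df[[tcol, col]].dropna().sort_values(tcol)
        out.append(
            ShiftMeltSeries(str(col), sub[tcol].to_numpy(float),
                            sub[col].to_numpy(float))
        )
    return out
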