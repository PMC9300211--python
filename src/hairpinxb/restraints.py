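"""Spectroscopic tables to population-averaged restraints.

NOESY build-up curves are reduced to cross-relaxation rates by the initial
rate approximation (zero-intercept regression over the linear regime), then
calibrated to interproton distances against a fixed-distance reference pair
through the r^-6 dependence.  Three-bond couplings relate to backbone phi
dihedrals through a Karplus curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .constants import KARPLUS_HN_HA

__all__ = [
    "BuildUp",
    "DistanceRestraint",
    "JRestraint",
    "InitialRateFit",
    "fit_initial_rate",
    "calibrate_distances",
    "karplus_j",
    "read_buildup_table",
    "read_restraint_table",
]

#: default fixed-distance calibration reference: a geminal methylene pair
GEMINAL_R_REF = 1.78


@dataclass
class BuildUp:
    """NOESY cross-peak intensity versus mixing time for one proton pair."""

    proton_pair: tuple[str, str]
    tau: np.ndarray  # mixing times, s
    intensity: np.ndarray  # arbitrary units
    reference: bool = False

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, float)
        self.intensity = np.asarray(self.intensity, float)
        if len(self.tau) < 3:
            raise ValueError(f"{self.proton_pair}: need >= 3 mixing times")
        if np.any(self.tau <= 0) or np.any(np.diff(self.tau) <= 0):
            raise ValueError(
                f"{self.proton_pair}: mixing times must be positive and "
                "strictly increasing"
            )


@dataclass(frozen=True)
class DistanceRestraint:
    proton_pair: tuple[str, str]
    r: float  # angstrom
    tolerance: float  # angstrom

    def __post_init__(self):
        if self.r <= 0 or self.tolerance <= 0:
            raise ValueError("distance and tolerance must be positive")


@dataclass(frozen=True)
class JRestraint:
    dihedral_label: str  # the residue's phi
    j: float  # Hz
    tolerance: float = 0.5  # Hz


class InitialRateFit(BaseEstimator):
    """Initial-rate (zero-intercept) regression of a NOE build-up.

    The cross-relaxation rate sigma is the slope of intensity on mixing time
    through the origin.  When no window is supplied, the largest prefix of
    the build-up whose regression keeps every relative residual below
    ``linearity_tol`` is used; at least three points are required.
    """

    def __init__(self, linear_window=None, linearity_tol=0.10):
        self.linear_window = linear_window
        self.linearity_tol = linearity_tol

    def fit(self, tau, intensity=None):
        if isinstance(tau, BuildUp):
            b, tau, intensity = tau, tau.tau, tau.intensity
        else:
            b = None
            tau = np.asarray(tau, float)
            intensity = np.asarray(intensity, float)
        if len(tau) < 3:
            raise ValueError("need >= 3 mixing times")
        if self.linear_window is not None:
            mask = tau <= self.linear_window
            if mask.sum() < 3:
                raise ValueError(
                    "fewer than 3 mixing times inside the linear window"
                )
            used, used_i = tau[mask], intensity[mask]
            sigma = self._slope(used, used_i)
        else:
            used = used_i = sigma = None
            for n in range(len(tau), 2, -1):
                s = self._slope(tau[:n], intensity[:n])
                pred = s * tau[:n]
                with np.errstate(divide="ignore", invalid="ignore"):
                    rel = np.abs(intensity[:n] - pred) / np.abs(pred)
                if np.all(rel[np.isfinite(rel)] < self.linearity_tol):
                    used, used_i, sigma = tau[:n], intensity[:n], s
                    break
            if used is None:
                raise ValueError("no linear regime: no prefix of >= 3 points "
                                 "passes the linearity test")
        resid = used_i - sigma * used
        # HC3 leverage-adjusted robust standard error: build-up noise is
        # typically multiplicative, so homoskedastic formulas undercover
        lev = used**2 / np.sum(used**2)
        self.sigma_ = float(sigma)
        self.stderr_ = float(
            np.sqrt(np.sum(used**2 * (resid / (1.0 - lev)) ** 2))
            / np.sum(used**2)
        )
        self.n_points_ = len(used)
        self.window_max_tau_ = float(used[-1])
        self.pair_ = b.proton_pair if b is not None else None
        return self

    @staticmethod
    def _slope(t, i):
        return float(np.dot(t, i) / np.dot(t, t))


def fit_initial_rate(buildup: BuildUp, linear_window=None) -> InitialRateFit:
    """Functional wrapper over :class:`InitialRateFit`."""
    return InitialRateFit(linear_window=linear_window).fit(buildup)


def calibrate_distances(rates, reference, tol_frac=0.10,
                        tol_floor=0.2) -> list[DistanceRestraint]:
    """Convert cross-relaxation rates to distances against a reference pair.

    r_ij = r_ref (sigma_ref / sigma_ij)^(1/6).  The calibration is invariant
    to the global intensity scale.  Restraint tolerances are
    ``max(tol_frac * r, tol_floor)`` angstrom.  Pairs with non-positive
    rates are skipped with a warning.

    Parameters
    ----------
    rates : mapping proton_pair -> sigma (intensity/s)
    reference : (proton_pair, r_ref angstrom)
    """
    ref_pair, r_ref = reference
    if ref_pair not in rates:
        raise KeyError(f"reference pair {ref_pair} missing from rates")
    sigma_ref = rates[ref_pair]
    if sigma_ref <= 0:
        raise ValueError("reference cross-relaxation rate must be positive")
    out = []
    for pair, sigma in rates.items():
        if sigma <= 0:
            warnings.warn(f"skipping pair {pair}: non-positive rate {sigma}")
            continue
        r = r_ref * (sigma_ref / sigma) ** (1.0 / 6.0)
        out.append(DistanceRestraint(pair, r, max(tol_frac * r, tol_floor)))
    return out


def karplus_j(phi, coeffs=KARPLUS_HN_HA):
    """Karplus curve for 3J(HN, HA): J = A cos^2(phi-60) + B cos(phi-60) + C.

    ``phi`` in degrees (scalar or array), J in Hz.  Total and 360-periodic.
    """
    a, b, c = coeffs
    th = np.radians(np.asarray(phi, float) - 60.0)
    j = a * np.cos(th) ** 2 + b * np.cos(th) + c
    return float(j) if j.ndim == 0 else j


# --------------------------------------------------------------------------
# table I/O
# --------------------------------------------------------------------------


def _parse_pair(text: str) -> tuple[str, str]:
    for sep in ("/", "-", ":"):
        if sep in text:
            a, b = text.split(sep, 1)
            return (a.strip(), b.strip())
    raise ValueError(f"cannot parse proton pair {text!r}")


def read_buildup_table(path) -> list[BuildUp]:
    """Delimited build-up table: first column tau_m (s), one column per
    proton pair named like ``HA2/HN3``."""
    df = pd.read_csv(path, sep=None, engine="python")
    tcol = df.columns[0]
    out = []
    for col in df.columns[1:]:
        sub = df[[tcol, col]].dropna().sort_values(tcol)
        out.append(BuildUp(_parse_pair(str(col)), sub[tcol].to_numpy(float),
                           sub[col].to_numpy(float)))
    return out


def read_restraint_table(path, kind="distance"):
    """Delimited restraint table: label, value, tolerance columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    out = []
    for _, row in df.iterrows():
        label, value, tol = row.iloc[0], float(row.iloc[1]), float(row.iloc[2])
        if kind == "distance":
            out.append(DistanceRestraint(_parse_pair(str(label)), value, tol))
        elif kind == "j":
            out.append(JRestraint(str(label), value, tol))
        else:
            raise ValueError(f"unknown restraint kind {kind!r}")
    return out
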