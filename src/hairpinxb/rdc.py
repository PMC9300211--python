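"""Residual dipolar coupling analysis: extraction, Saupe tensor SVD, ensembles.

One-bond C-H RDCs are extracted as the difference between the total
coupling measured under weak alignment and the isotropic scalar coupling,
scaled by the number of equivalent protons.  For a rigid structure the RDC
of a bond with direction cosines (c_x, c_y, c_z) is linear in the five
independent elements of the traceless symmetric Saupe order matrix, so the
tensor follows from a (weighted) singular value decomposition of the design
matrix.  Fit quality is summarised by the Cornilescu Q factor and the
condition number of the design matrix.  For flexible molecules a shared
tensor and conformer populations are fit jointly by alternating linear
solves, and sub-ensembles of increasing size are compared through a
chi-squared + penalty score to guard against overfitting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .constants import DMAX_CH

__all__ = [
    "RdcObservation",
    "AlignmentTensor",
    "RdcFitReport",
    "rdc_from_couplings",
    "build_design_row",
    "SaupeTensorFit",
    "svd_fit",
    "RdcEnsembleFit",
    "ensemble_rdc_fit",
    "RdcModelSelector",
    "model_select",
    "read_rdc_table",
]

_MULTIPLICITY = {"CH": 1, "CH2": 2, "CH3": 3}


@dataclass(frozen=True)
class RdcObservation:
    """One measured coupling pair for a C-H vector (or CHn group)."""

    vector_label: str
    n_h: int
    j: float  # 1J(CH), Hz
    t: float  # 1T(CH) under alignment, Hz
    sigma_j: float = 0.0
    sigma_t: float = 0.0

    def __post_init__(self):
        if self.n_h not in (1, 2, 3):
            raise ValueError(f"{self.vector_label}: multiplicity must be "
                             f"1, 2 or 3, got {self.n_h}")
        if self.sigma_j < 0 or self.sigma_t < 0:
            raise ValueError("uncertainties must be non-negative")

    @property
    def d(self) -> float:
        return rdc_from_couplings(self.j, self.t, self.n_h)[0]

    @property
    def sigma_d(self) -> float:
        return rdc_from_couplings(self.j, self.t, self.n_h,
                                  self.sigma_j, self.sigma_t)[1]


def rdc_from_couplings(j, t, n_h, sigma_j=0.0, sigma_t=0.0):
    """RDC from total and scalar couplings: D = (T - J)/n_H.

    The per-proton uncertainty propagates as sqrt(s_T^2 + s_J^2)/n_H.
    Returns (D, sigma_D) in Hz.
    """
    if n_h not in (1, 2, 3):
        raise ValueError(f"multiplicity must be 1, 2 or 3, got {n_h}")
    d = (t - j) / n_h
    return float(d), float(np.hypot(sigma_t, sigma_j) / n_h)


def build_design_row(v) -> np.ndarray:
    """Direction-cosine design row for the Saupe 5-vector.

    For a unit vector (c_x, c_y, c_z) the row is
    ``(c_y^2 - c_x^2, c_z^2 - c_x^2, 2 c_x c_y, 2 c_x c_z, 2 c_y c_z)``
    (Losonczi parametrisation) so that ``D = D_max * row . s`` with
    ``s = (S_yy, S_zz, S_xy, S_xz, S_yz)``.  Even in v -> -v.
    """
    v = np.asarray(v, float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-9:
        raise ValueError("design rows require a unit vector")
    cx, cy, cz = v
    return np.array([cy**2 - cx**2, cz**2 - cx**2,
                     2 * cx * cy, 2 * cx * cz, 2 * cy * cz])


def design_rows_for_pool(pool, vectors) -> np.ndarray:
    """Design rows per conformer for a list of C-H vector definitions.

    ``vectors`` holds (label, heavy_atom, proton_labels, n_h) tuples; for a
    CHn group the row is the mean of the individual bond rows (RDCs are
    linear in the design row, so group-averaged couplings average the
    rows).  Returns an (n_conformers, n_vectors, 5) array.
    """
    from .geometry import unit_vector  # local import avoids a cycle

    out = []
    for conf in pool:
        conf_rows = []
        for _label, heavy, protons, _n_h in vectors:
            rows = [
                build_design_row(unit_vector(conf.xyz(heavy), conf.xyz(p)))
                for p in protons
            ]
            conf_rows.append(np.mean(rows, axis=0))
        out.append(conf_rows)
    return np.asarray(out, float)


def saupe_matrix(s) -> np.ndarray:
    """Traceless symmetric 3x3 Saupe matrix from the 5-vector."""
    syy, szz, sxy, sxz, syz = np.asarray(s, float)
    sxx = -syy - szz
    return np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]])


@dataclass
class AlignmentTensor:
    """Saupe order matrix with eigen-decomposition and derived anisotropy."""

    s: np.ndarray  # 5-vector (S_yy, S_zz, S_xy, S_xz, S_yz)
    dmax: float = DMAX_CH

    def __post_init__(self):
        self.s = np.asarray(self.s, float)
        self.matrix = saupe_matrix(self.s)
        w, v = np.linalg.eigh(self.matrix)
        order = np.argsort(np.abs(w))  # |A_xx| <= |A_yy| <= |A_zz|
        self.eigenvalues = w[order]
        self.principal_axes = v[:, order]

    @property
    def a_zz(self) -> float:
        return float(self.eigenvalues[2])

    @property
    def d_a(self) -> float:
        """Axial component in Hz: D_max * A_zz / 2."""
        return float(self.dmax * self.a_zz / 2.0)

    @property
    def rhombicity(self) -> float:
        """R = (2/3)(A_xx - A_yy)/A_zz, bounded by |R| <= 2/3."""
        axx, ayy, azz = self.eigenvalues
        return float(2.0 / 3.0 * (axx - ayy) / azz)

    def predict(self, rows) -> np.ndarray:
        return self.dmax * np.asarray(rows, float) @ self.s


@dataclass
class RdcFitReport:
    table: pd.DataFrame = field(repr=False)  # per-vector obs/calc/residual
    q: float = np.nan
    condition_number: float = np.nan
    chi2: float = np.nan
    populations: pd.Series | None = None


def _quality(d_obs, d_calc, sigma=None):
    resid = d_obs - d_calc
    q = float(np.sqrt(np.mean(resid**2)) / np.sqrt(np.mean(d_obs**2)))
    if sigma is None or np.all(sigma == 0):
        chi2 = float(np.sum(resid**2))
    else:
        sig = np.where(sigma > 0, sigma, 1.0)
        chi2 = float(np.sum((resid / sig) ** 2))
    return q, chi2


class SaupeTensorFit(BaseEstimator):
    """Weighted SVD fit of one alignment tensor to observed RDCs.

    ``fit(rows, d, sigma=None)`` takes per-observation design rows (built
    from unit bond vectors), observed RDCs in Hz and optional 1-sigma
    uncertainties used as inverse weights.  Requires at least five
    observations of full rank; otherwise the degenerate combination is named
    in the error.
    """

    def __init__(self, dmax=DMAX_CH):
        self.dmax = dmax

    def fit(self, rows, d, sigma=None, labels=None):
        rows = np.atleast_2d(np.asarray(rows, float))
        d = np.asarray(d, float)
        n = len(d)
        if rows.shape != (n, 5):
            raise ValueError("design rows must be an (n, 5) array matching d")
        if n < 5:
            raise ValueError(f"need >= 5 RDCs to determine the tensor, got {n}")
        if sigma is not None:
            sigma = np.asarray(sigma, float)
            w = np.where(sigma > 0, 1.0 / sigma, 1.0)
        else:
            w = np.ones(n)
        m = rows * w[:, None]
        u, sv, vt = np.linalg.svd(m, full_matrices=False)
        if sv[-1] < 1e-10 * sv[0]:
            null = vt[-1]
            raise ValueError(
                "degenerate vector geometry: design matrix rank < 5 "
                f"(null direction {np.round(null, 4)})"
            )
        s_vec = vt.T @ np.diag(1.0 / sv) @ u.T @ (w * d) / self.dmax
        self.tensor_ = AlignmentTensor(s_vec, dmax=self.dmax)
        d_calc = self.tensor_.predict(rows)
        q, chi2 = _quality(d, d_calc, sigma)
        self.condition_number_ = float(sv[0] / sv[-1])
        self.q_ = q
        self.chi2_ = chi2
        self.d_calc_ = d_calc
        self.singular_values_ = sv
        self._d = d
        self._labels = labels
        return self

    @property
    def report_(self) -> RdcFitReport:
        d, d_calc = self._d, self.d_calc_
        labels = self._labels if self._labels is not None \
            else np.arange(len(d))
        return RdcFitReport(
            table=pd.DataFrame({"label": labels, "d_obs": d,
                                "d_calc": d_calc, "residual": d - d_calc}),
            q=self.q_, condition_number=self.condition_number_,
            chi2=self.chi2_,
        )

    def predict(self, rows):
        return self.tensor_.predict(rows)


def svd_fit(d, rows, sigma=None, labels=None, dmax=DMAX_CH):
    """Functional wrapper: returns (AlignmentTensor, RdcFitReport)."""
    model = SaupeTensorFit(dmax=dmax).fit(rows, d, sigma, labels)
    return model.tensor_, model.report_


def _simplex_nnls(a, b, anchor=1e3):
    """min ||a p - b|| s.t. p >= 0, sum p = 1 via an anchored NNLS."""
    scale = max(np.abs(a).max(), 1.0)
    mu = anchor * scale
    a_aug = np.vstack([a, mu * np.ones((1, a.shape[1]))])
    b_aug = np.concatenate([b, [mu]])
    p, _ = nnls(a_aug, b_aug)
    total = p.sum()
    if total <= 0:
        raise RuntimeError("population solve collapsed to the zero vector")
    return p / total


class RdcEnsembleFit(BaseEstimator):
    """Joint fit of conformer populations and one shared alignment tensor.

    The model for observation k is ``D_k = D_max sum_i p_i row_k(i) . s``
    with a single tensor for the whole ensemble (one weak-alignment medium).
    Alternating linear solves: with p fixed the tensor is the SVD solution
    on population-averaged rows; with the tensor fixed the populations solve
    a non-negative least squares on the simplex.  Iterated to a chi-squared
    change below ``tol`` from ``n_restarts`` seeded Dirichlet starts; the
    best chi-squared wins.
    """

    def __init__(self, dmax=DMAX_CH, n_restarts=10, seed=1234, tol=1e-8,
                 max_iter=500, pop_floor=1e-6):
        self.dmax = dmax
        self.n_restarts = n_restarts
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter
        self.pop_floor = pop_floor

    def fit(self, rows_by_conformer, d, sigma=None, labels=None):
        """``rows_by_conformer``: (n_conf, n_obs, 5) design rows per conformer."""
        rows = np.asarray(rows_by_conformer, float)
        if rows.ndim == 2:
            rows = rows[None]
        n_conf, n_obs, _ = rows.shape
        d = np.asarray(d, float)
        if sigma is not None:
            sigma = np.asarray(sigma, float)
            sig = np.where(sigma > 0, sigma, 1.0)
        else:
            sig = np.ones(n_obs)

        if n_conf == 1:
            sub = SaupeTensorFit(dmax=self.dmax).fit(rows[0], d, sigma, labels)
            self.populations_ = np.array([1.0])
            self.tensor_ = sub.tensor_
            self.chi2_ = sub.chi2_
            self.q_ = sub.q_
            self.n_iter_ = 1
            self._d, self._sigma, self._labels = d, sigma, labels
            self._d_calc = sub.d_calc_
            self._cond = sub.condition_number_
            return self

        rng = np.random.default_rng(self.seed)
        starts = [np.full(n_conf, 1.0 / n_conf)]
        starts += [rng.dirichlet(np.ones(n_conf))
                   for _ in range(self.n_restarts)]
        w = 1.0 / sig
        wd = w * d
        best = None
        for p in starts:
            p = np.clip(p, self.pop_floor, None)
            p /= p.sum()
            chi2_prev = np.inf
            s_vec = None
            for it in range(self.max_iter):
                # fixed p -> tensor: weighted least squares on averaged rows
                avg_rows = np.tensordot(p, rows, axes=(0, 0))
                s_vec, *_ = np.linalg.lstsq(avg_rows * w[:, None] * self.dmax,
                                            wd, rcond=None)
                # fixed tensor -> populations: D = sum_i p_i d_i(k)
                d_per_conf = self.dmax * rows @ s_vec  # (n_conf, n_obs)
                p_new = _simplex_nnls((d_per_conf * w).T, wd)
                p_new = np.clip(p_new, self.pop_floor, None)
                p_new /= p_new.sum()
                resid = (d - p_new @ d_per_conf) * w
                chi2 = float(resid @ resid)
                p = p_new
                if abs(chi2_prev - chi2) < self.tol:
                    break
                chi2_prev = chi2
            else:
                continue  # non-converged start
            if best is None or chi2 < best[0]:
                best = (chi2, p, s_vec, it + 1)
        if best is None:
            raise RuntimeError(
                f"ensemble RDC fit failed to converge within "
                f"{self.max_iter} iterations on all starts"
            )
        chi2, p, s_vec, n_iter = best
        tensor = AlignmentTensor(s_vec, dmax=self.dmax)
        avg_rows = np.tensordot(p, rows, axes=(0, 0))
        d_calc = tensor.predict(avg_rows)
        q, chi2 = _quality(d, d_calc, sigma)
        self.populations_ = p
        self.tensor_ = tensor
        self.chi2_ = chi2
        self.q_ = q
        self.n_iter_ = n_iter
        self._d, self._sigma, self._labels = d, sigma, labels
        self._d_calc = d_calc
        wsv = np.linalg.svd(avg_rows * (1.0 / sig)[:, None],
                            compute_uv=False)
        self._cond = float(wsv[0] / wsv[-1]) if wsv[-1] > 0 else np.inf
        return self

    @property
    def report_(self) -> RdcFitReport:
        d, d_calc = self._d, self._d_calc
        labels = self._labels if self._labels is not None \
            else np.arange(len(d))
        return RdcFitReport(
            table=pd.DataFrame({"label": labels, "d_obs": d,
                                "d_calc": d_calc, "residual": d - d_calc}),
            q=self.q_, condition_number=self._cond, chi2=self.chi2_,
            populations=pd.Series(self.populations_),
        )


def ensemble_rdc_fit(rows_by_conformer, d, sigma=None, labels=None, **opts):
    """Functional wrapper over :class:`RdcEnsembleFit`."""
    model = RdcEnsembleFit(**opts).fit(rows_by_conformer, d, sigma, labels)
    return model.populations_, model.tensor_, model.report_


class RdcModelSelector(BaseEstimator):
    """Sub-ensemble size selection by a chi-squared penalty score.

    For every size m up to ``max_size`` the best-fitting m-conformer
    sub-ensemble is found (exhaustively for small pools, greedy forward
    selection beyond ``exhaustive_pool_max`` conformers or
    ``exhaustive_m_max`` members) and scored as ``chi2 + lambda * k`` with
    ``k = 5 + (m - 1)`` free parameters.

    The default penalty ``'ric'`` (risk inflation criterion) uses
    ``lambda = 2 ln(pool size)``: because each added conformer is chosen as
    the best of the combinatorially many candidate subsets, the expected
    spurious chi-squared gain scales with the log of the number of
    candidates, and the AIC value 2 systematically overfits.
    ``penalty='aic'`` uses lambda = 2, ``'bic'`` lambda = ln(n_obs), or
    pass a number.
    """

    def __init__(self, max_size=3, penalty="ric", dmax=DMAX_CH,
                 exhaustive_pool_max=15, exhaustive_m_max=4, n_restarts=4,
                 seed=1234):
        self.max_size = max_size
        self.penalty = penalty
        self.dmax = dmax
        self.exhaustive_pool_max = exhaustive_pool_max
        self.exhaustive_m_max = exhaustive_m_max
        self.n_restarts = n_restarts
        self.seed = seed

    def _lambda(self, n_obs, n_pool):
        if self.penalty == "ric":
            return float(2.0 * np.log(max(n_pool, 2)))
        if self.penalty == "aic":
            return 2.0
        if self.penalty == "bic":
            return float(np.log(n_obs))
        return float(self.penalty)

    def _fit_subset(self, rows, d, sigma, subset):
        model = RdcEnsembleFit(dmax=self.dmax, n_restarts=self.n_restarts,
                               seed=self.seed)
        model.fit(rows[list(subset)], d, sigma)
        return model

    def fit(self, rows_by_conformer, d, sigma=None, conformer_ids=None):
        rows = np.asarray(rows_by_conformer, float)
        n_conf = rows.shape[0]
        if n_conf == 0:
            raise ValueError("empty conformer pool")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        d = np.asarray(d, float)
        ids = list(conformer_ids) if conformer_ids is not None \
            else list(range(n_conf))
        lam = self._lambda(len(d), n_conf)
        per_size = []
        best_models = {}
        prev_best_subset = ()
        for m in range(1, min(self.max_size, n_conf) + 1):
            exhaustive = (n_conf <= self.exhaustive_pool_max
                          and m <= self.exhaustive_m_max)
            if exhaustive:
                candidates = itertools.combinations(range(n_conf), m)
            else:
                remaining = [i for i in range(n_conf)
                             if i not in prev_best_subset]
                candidates = (tuple(sorted(prev_best_subset + (i,)))
                              for i in remaining)
            best = None
            for subset in candidates:
                model = self._fit_subset(rows, d, sigma, subset)
                if best is None or model.chi2_ < best[0]:
                    best = (model.chi2_, subset, model)
            chi2, subset, model = best
            score = chi2 + lam * (5 + (m - 1))
            per_size.append({"m": m, "chi2": chi2, "score": score,
                             "conformer_ids": [ids[i] for i in subset]})
            best_models[m] = (subset, model)
            prev_best_subset = subset
        table = pd.DataFrame(per_size)
        winner = int(table.loc[table["score"].idxmin(), "m"])
        subset, model = best_models[winner]
        self.size_ = winner
        self.subset_ids_ = [ids[i] for i in subset]
        self.subset_index_ = list(subset)
        self.model_ = model
        self.populations_ = pd.Series(model.populations_,
                                      index=self.subset_ids_)
        self.table_ = table
        return self


def model_select(rows_by_conformer, d, sigma=None, max_size=3,
                 conformer_ids=None, **opts) -> RdcModelSelector:
    """Functional wrapper over :class:`RdcModelSelector`."""
    return RdcModelSelector(max_size=max_size, **opts).fit(
        rows_by_conformer, d, sigma, conformer_ids=conformer_ids)


def read_rdc_table(path) -> list[RdcObservation]:
    """Delimited RDC table: label, multiplicity (CH/CH2/CH3 or 1/2/3),
    1J, sigma_J, 1T, sigma_T (Hz)."""
    df = pd.read_csv(path, sep=None, engine="python")
    out = []
    for _, row in df.iterrows():
        mult = row.iloc[1]
        n_h = int(_MULTIPLICITY.get(str(mult).strip().upper(), 0) or mult)
        out.append(RdcObservation(
            vector_label=str(row.iloc[0]), n_h=n_h,
            j=float(row.iloc[2]), sigma_j=float(row.iloc[3]),
            t=float(row.iloc[4]), sigma_t=float(row.iloc[5]),
        ))
    return out
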