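"""Spatial weights, Moran's I, and SAR spatial-error regression.

The regression model is the simultaneous autoregressive (SAR) error
model

    y = X beta + u,    u = lambda W u + eps,    eps ~ N(0, sigma^2 I),

with W a row-standardized neighbor matrix.  Estimation is by maximum
likelihood: for a trial lambda the betas are obtained by least squares on
the spatially filtered variables (I - lambda W) y and (I - lambda W) X,
and the concentrated log-likelihood

    l(lambda) = -(n/2)(ln 2 pi + 1) - (n/2) ln sigma^2(lambda) + ln|I - lambda W|

is maximized by bounded scalar search, with the log-determinant computed
from the eigenvalues of W.  Model adequacy follows the usual diagnostics:
a likelihood-ratio test of lambda, and a permutation test of global
Moran's I on the spatially filtered residuals.  Model comparison uses
BIC (counting lambda and sigma^2 as free parameters) and the Nagelkerke
pseudo-R^2 against an intercept-only null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

log = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# spatial weights
# ---------------------------------------------------------------------------

class SpatialWeights:
    """Symmetric neighbor structure with optional row standardization.

    Stores an ordered list of unit ids and a binary adjacency; the dense
    weight matrix is materialized on demand.  Units without neighbors
    (islands) are retained and flagged; diagnostics and SAR fits exclude
    them explicitly at the caller level.
    """

    def __init__(self, ids, neighbors: dict, style: str = "row_standardized"):
        if style not in ("row_standardized", "binary"):
            raise ValueError("style must be 'row_standardized' or 'binary'")
        self.ids = [str(i) for i in ids]
        self._pos = {u: k for k, u in enumerate(self.ids)}
        nb = {str(i): sorted({str(j) for j in neighbors.get(str(i), neighbors.get(i, []))})
              for i in self.ids}
        for i, js in nb.items():
            for j in js:
                if j not in self._pos:
                    raise ValueError(f"neighbor {j} of {i} not in id list")
                if i not in nb[j]:  # enforce symmetry by union
                    nb[j] = sorted(set(nb[j]) | {i})
        self.neighbors = nb
        self.style = style

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def islands(self) -> list[str]:
        return [i for i in self.ids if not self.neighbors[i]]

    def cardinality(self, unit) -> int:
        return len(self.neighbors[str(unit)])

    # -- constructors -------------------------------------------------------

    @classmethod
    def grid(cls, n_rows: int, n_cols: int, scheme: str = "queen",
             style: str = "row_standardized", ids=None) -> "SpatialWeights":
        """Contiguity weights on a regular grid (row-major unit order)."""
        if scheme not in ("queen", "rook"):
            raise ValueError("grid scheme must be 'queen' or 'rook'")
        if ids is None:
            ids = [f"g{r}_{c}" for r in range(n_rows) for c in range(n_cols)]
        ids = [str(i) for i in ids]
        if len(ids) != n_rows * n_cols:
            raise ValueError("ids length must equal n_rows * n_cols")
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        nb = {}
        for r in range(n_rows):
            for c in range(n_cols):
                cur = ids[r * n_cols + c]
                lst = []
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_rows and 0 <= cc < n_cols:
                        lst.append(ids[rr * n_cols + cc])
                nb[cur] = lst
        return cls(ids, nb, style=style)

    @classmethod
    def from_adjacency(cls, neighbors: dict, style: str = "row_standardized"):
        return cls(list(neighbors.keys()), neighbors, style=style)

    @classmethod
    def knn(cls, coords: dict, k: int = 6, style: str = "row_standardized"):
        """k-nearest-neighbor weights symmetrized by union."""
        ids = [str(i) for i in coords]
        pts = np.array([coords[i] for i in coords], dtype=float)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        nb = {}
        for a, i in enumerate(ids):
            order = np.argsort(d2[a], kind="stable")[:k]
            nb[i] = [ids[b] for b in order]
        return cls(ids, nb, style=style)

    @classmethod
    def from_polygons(cls, polygons: dict, scheme: str = "queen",
                      style: str = "row_standardized"):
        """Contiguity from shapely polygons: queen = any boundary contact,
        rook = shared edge (1-d intersection)."""
        from shapely.geometry import shape

        ids = [str(i) for i in polygons]
        geoms = {}
        for i in ids:
            g = polygons[i] if hasattr(polygons[i], "intersection") else shape(polygons[i])
            geoms[i] = g
        nb = {i: [] for i in ids}
        for a, i in enumerate(ids):
            for j in ids[a + 1:]:
                gi, gj = geoms[i], geoms[j]
                if not gi.intersects(gj):
                    continue
                inter = gi.intersection(gj)
                if inter.is_empty:
                    continue
                if scheme == "queen" or inter.length > 0:
                    nb[i].append(j)
                    nb[j].append(i)
        w = cls(ids, nb, style=style)
        if w.islands:
            log.warning("contiguity produced %d island(s): %s",
                        len(w.islands), w.islands[:5])
        return w

    @classmethod
    def read_gal(cls, path, style: str = "row_standardized") -> "SpatialWeights":
        """Read GAL adjacency text (header line: n; then id/degree + neighbor lines)."""
        with open(path) as fh:
            tokens = fh.read().split("\n")
        lines = [ln.strip() for ln in tokens if ln.strip()]
        header = lines[0].split()
        n = int(header[0]) if len(header) == 1 else int(header[1])
        ids, nb = [], {}
        k = 1
        while len(ids) < n:
            uid, deg = lines[k].split()[:2]
            deg = int(deg)
            neigh = lines[k + 1].split() if deg > 0 else []
            if deg > 0:
                k += 2
            else:
                # degree-0 unit may or may not have an (empty) neighbor line
                k += 1
            ids.append(uid)
            nb[uid] = neigh[:deg]
        return cls(ids, nb, style=style)

    def write_gal(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i in self.ids:
                js = self.neighbors[i]
                fh.write(f"{i} {len(js)}\n")
                if js:
                    fh.write(" ".join(js) + "\n")

    # -- matrices -----------------------------------------------------------

    def binary_dense(self) -> np.ndarray:
        mat = np.zeros((self.n, self.n))
        for i, js in self.neighbors.items():
            a = self._pos[i]
            for j in js:
                mat[a, self._pos[j]] = 1.0
        return mat

    def dense(self) -> np.ndarray:
        """Weight matrix in the chosen style (islands keep zero rows).

        Cached: the neighbor structure is treated as immutable once built.
        """
        if getattr(self, "_dense_cache", None) is None:
            mat = self.binary_dense()
            if self.style == "row_standardized":
                deg = mat.sum(axis=1)
                deg[deg == 0] = 1.0
                mat = mat / deg[:, None]
            self._dense_cache = mat
        return self._dense_cache

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of the weight matrix (cached).

        A row-standardized matrix derived from a symmetric binary
        adjacency is similar to the symmetric D^{-1/2} B D^{-1/2}, so its
        spectrum is real and computed via a symmetric eigensolve.
        """
        if getattr(self, "_eig_cache", None) is None:
            b = self.binary_dense()
            if self.style == "binary":
                self._eig_cache = scipy.linalg.eigvalsh(b)
            else:
                deg = b.sum(axis=1)
                deg[deg == 0] = 1.0
                dinv = 1.0 / np.sqrt(deg)
                sym = b * dinv[:, None] * dinv[None, :]
                self._eig_cache = scipy.linalg.eigvalsh(sym)
        return self._eig_cache

    def subset(self, keep_ids) -> "SpatialWeights":
        keep = [str(i) for i in keep_ids]
        keep_set = set(keep)
        nb = {i: [j for j in self.neighbors[i] if j in keep_set] for i in keep}
        return SpatialWeights(keep, nb, style=self.style)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    I: float
    p_value: float
    expected: float
    n_perm: int
    lagged: np.ndarray = field(repr=False, default=None)
    permuted: np.ndarray = field(repr=False, default=None)


def morans_i(values, weights: SpatialWeights, n_perm: int = 999,
             seed: int | None = None) -> MoranResult:
    """Global Moran's I with a two-sided permutation test.

    I = (n / S0) z'Wz / z'z with z the centered values and S0 the sum of
    weights.  The permutation p-value is (#{|I_perm - E[I]| >= |I - E[I]|} + 1)
    / (n_perm + 1); E[I] = -1/(n-1).  Island units must be removed first.
    """
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("morans_i: missing values present")
    if np.unique(arr).size < 2:
        raise ValueError("morans_i: constant values")
    if weights.islands:
        raise ValueError(
            f"morans_i: weights contain islands {weights.islands[:5]}; "
            "subset them out first"
        )
    w = weights.dense()
    n = len(arr)
    if n != weights.n:
        raise ValueError("values length does not match weights")
    z = arr - arr.mean()
    s0 = w.sum()
    denom = float(z @ z)
    lag = w @ z
    stat = float(n / s0 * (z @ lag) / denom)
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for b in range(n_perm):
        zp = rng.permutation(z)
        perms[b] = n / s0 * (zp @ (w @ zp)) / denom
    extreme = np.abs(perms - expected) >= np.abs(stat - expected) - 1e-14
    p = (extreme.sum() + 1) / (n_perm + 1)
    return MoranResult(I=stat, p_value=float(p), expected=expected,
                       n_perm=n_perm, lagged=lag + arr.mean(), permuted=perms)


# ---------------------------------------------------------------------------
# SAR error model
# ---------------------------------------------------------------------------

def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if X is None:
        return np.empty((0, 0)), []
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def gaussian_loglik(resid: np.ndarray) -> float:
    """Maximized iid-Gaussian log-likelihood given residuals (ML sigma^2)."""
    n = len(resid)
    s2 = float(resid @ resid) / n
    return -0.5 * n * (LOG2PI + 1.0 + np.log(s2))


class SpatialErrorModel(RegressorMixin, BaseEstimator):
    """Maximum-likelihood SAR spatial-error regression.

    Parameters
    ----------
    weights : :class:`SpatialWeights` over the observation units, in row
        order of the design matrix.  Must contain no islands.
    fit_intercept : include an intercept column (default False — in this
        analysis predictors are standardized and the intercept is itself
        a selectable model term).
    lambda_tol : absolute tolerance of the bounded lambda search.

    Fitted attributes (per scikit-learn convention)
    ----------------
    coef_, stderr_, zvalues_, pvalues_ : coefficient table arrays.
    lambda_, lambda_se_ : spatial dependence parameter and profile SE.
    sigma2_ : ML innovation variance.  loglik_, bic_, n_, k_.
    ols_loglik_ : maximized likelihood of the lambda = 0 model (same X).
    lr_lambda_p_ : likelihood-ratio p-value for lambda.
    nagelkerke_r2_ : pseudo-R^2 against the intercept-only null.
    """

    def __init__(self, weights: SpatialWeights | None = None,
                 fit_intercept: bool = False, lambda_tol: float = 1e-8):
        self.weights = weights
        self.fit_intercept = fit_intercept
        self.lambda_tol = lambda_tol

    # concentrated log-likelihood machinery ---------------------------------

    @staticmethod
    def _profile(lam, wmat, eigs, y, x):
        n = len(y)
        a_y = y - lam * (wmat @ y)
        if x.shape[1]:
            a_x = x - lam * (wmat @ x)
            beta, *_ = np.linalg.lstsq(a_x, a_y, rcond=None)
            resid = a_y - a_x @ beta
        else:
            beta = np.empty(0)
            resid = a_y
        s2 = float(resid @ resid) / n
        logdet = float(np.sum(np.log1p(-lam * eigs)))
        ll = -0.5 * n * (LOG2PI + 1.0 + np.log(s2)) + logdet
        return ll, beta, s2

    def fit(self, X, y) -> "SpatialErrorModel":
        if self.weights is None:
            raise ValueError("SpatialErrorModel requires weights")
        islands = self.weights.islands
        if islands and len(islands) < self.weights.n:
            raise ValueError("weights contain islands; subset them out first")
        # a fully empty adjacency is allowed: the model degenerates to the
        # ordinary Gaussian regression (lambda has no effect)
        y = np.asarray(y, dtype=float).ravel()
        x, names = _as_matrix(X)
        if x.size == 0:
            x = np.empty((len(y), 0))
        if self.fit_intercept:
            x = np.column_stack([np.ones(len(y)), x])
            names = ["intercept"] + names
        n, p = x.shape
        if np.isnan(y).any() or (x.size and np.isnan(x).any()):
            raise ValueError("missing values in y or X")
        if n != self.weights.n:
            raise ValueError("design rows do not match weights")
        if n <= p + 2:
            raise ValueError("need n > number of parameters")
        if p and np.linalg.matrix_rank(x) < p:
            raise ValueError("singular design matrix")

        wmat = self.weights.dense()
        eigs = self.weights.eigenvalues()
        emin, emax = float(eigs.min()), float(eigs.max())
        lo = (1.0 / emin + 1e-6) if emin < 0 else -0.999999
        hi = (1.0 / emax - 1e-6) if emax > 0 else 0.999999

        res = minimize_scalar(
            lambda lam: -self._profile(lam, wmat, eigs, y, x)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": self.lambda_tol},
        )
        lam = float(res.x)
        if min(lam - lo, hi - lam) < 1e-5:
            log.warning("lambda estimate %.6f is at the search boundary", lam)
        ll, beta, s2 = self._profile(lam, wmat, eigs, y, x)

        # beta covariance: information matrix is block-diagonal between beta
        # and (lambda, sigma2), so cov(beta) = sigma2 * (X'A'AX)^{-1}.
        if p:
            a_x = x - lam * (wmat @ x)
            xtx = a_x.T @ a_x
            cov = s2 * np.linalg.inv(xtx)
            se = np.sqrt(np.diag(cov))
            zval = beta / se
            pval = 2.0 * scipy.stats.norm.sf(np.abs(zval))
        else:
            cov = np.empty((0, 0))
            se = np.empty(0)
            zval = np.empty(0)
            pval = np.empty(0)

        # profile SE of lambda from the numerical curvature of l(lambda)
        h = max(1e-5, 1e-4 * (hi - lo))
        lam_m = np.clip(lam - h, lo, hi)
        lam_p = np.clip(lam + h, lo, hi)
        l0 = ll
        lm = self._profile(lam_m, wmat, eigs, y, x)[0]
        lp = self._profile(lam_p, wmat, eigs, y, x)[0]
        d2 = (lp - 2 * l0 + lm) / ((lam_p - lam) * (lam - lam_m) + 1e-300)
        self.lambda_se_ = float(np.sqrt(-1.0 / d2)) if d2 < 0 else float("nan")

        k = p + 2  # betas + lambda + sigma2
        self.names_ = names
        self.coef_ = beta
        self.cov_ = cov
        self.stderr_ = se
        self.zvalues_ = zval
        self.pvalues_ = pval
        self.lambda_ = lam
        self.sigma2_ = s2
        self.loglik_ = float(ll)
        self.n_ = n
        self.k_ = k
        self.bic_ = float(-2.0 * ll + k * np.log(n))

        # lambda = 0 benchmark on the same design (ordinary Gaussian fit)
        if p:
            beta0, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid0 = y - x @ beta0
        else:
            resid0 = y
        self.ols_loglik_ = gaussian_loglik(resid0)
        self.lr_lambda_p_ = lr_test_lambda(self.loglik_, self.ols_loglik_)

        # intercept-only non-spatial null for the pseudo-R^2
        null_ll = gaussian_loglik(y - y.mean())
        self.null_loglik_ = null_ll
        # a model without intercept does not nest the intercept-only null and
        # can fall below it; such a model explains nothing beyond the null
        self.nagelkerke_r2_ = nagelkerke_r2(max(self.loglik_, null_ll), null_ll, n)

        self._x = x
        self._y = y
        self._wmat = wmat
        return self

    # -----------------------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        x, _ = _as_matrix(X)
        if self.fit_intercept:
            x = np.column_stack([np.ones(len(x)), x])
        return x @ self.coef_

    def filtered_residuals(self) -> np.ndarray:
        """Innovation estimates (I - lambda W)(y - X beta)."""
        u = self._y - (self._x @ self.coef_ if self._x.shape[1] else 0.0)
        return u - self.lambda_ * (self._wmat @ u)

    def residual_moran(self, n_perm: int = 999, seed: int | None = None) -> MoranResult:
        """Permutation Moran test on the spatially filtered residuals."""
        return morans_i(self.filtered_residuals(), self.weights,
                        n_perm=n_perm, seed=seed)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef_, "se": self.stderr_,
             "z": self.zvalues_, "p": self.pvalues_},
            index=self.names_,
        )


def sar_error_fit(y, X, weights: SpatialWeights, **kwargs) -> SpatialErrorModel:
    """Functional wrapper over :class:`SpatialErrorModel`."""
    return SpatialErrorModel(weights=weights, **kwargs).fit(X, y)


def lr_test_lambda(sar_loglik: float, ols_loglik: float) -> float:
    """Likelihood-ratio p-value for lambda (chi-square, 1 df)."""
    stat = 2.0 * (sar_loglik - ols_loglik)
    if stat < -1e-6:
        raise ValueError(f"negative LR statistic {stat}: optimization failure")
    stat = max(stat, 0.0)
    return float(scipy.stats.chi2.sf(stat, df=1))


def nagelkerke_r2(loglik: float, null_loglik: float, n: int) -> float:
    """Nagelkerke pseudo-R^2: Cox-Snell rescaled so the maximum is 1."""
    if loglik < null_loglik - 1e-8:
        raise ValueError("fitted log-likelihood below the null log-likelihood")
    r2_cs = 1.0 - np.exp(2.0 / n * (null_loglik - loglik))
    denom = 1.0 - np.exp(2.0 / n * null_loglik)
    if denom <= 0:
        # null density above 1 per observation (tiny response variance):
        # the rescaling is undefined; report Cox-Snell, capped at 1.
        log.warning("Nagelkerke denominator nonpositive; reporting Cox-Snell R^2")
        return float(min(max(r2_cs, 0.0), 1.0))
    return float(min(max(r2_cs / denom, 0.0), 1.0))


# ---------------------------------------------------------------------------
# BIC / p-value model selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    model: SpatialErrorModel
    terms: list[str]
    trace: list[dict]
    r2_ablation: dict[str, float]

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)


def select_model(
    y,
    candidates: pd.DataFrame,
    weights: SpatialWeights,
    alpha: float = 0.05,
    delta_bic: float = 2.0,
    include_intercept: bool = True,
) -> SelectionResult:
    """Greedy forward/backward term selection for the SAR error model.

    A term is kept only if its coefficient is significant (p < alpha)
    AND removing it raises BIC by at least ``delta_bic``.  The trace
    records the BIC change and p-value of every candidate at every step;
    the ablation table reports the pseudo-R^2 of the selected model with
    each retained term removed.  If nothing survives, the null
    (empty-design) spatial model is returned with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    cols = list(candidates.columns)
    if include_intercept and "intercept" not in cols:
        candidates = candidates.copy()
        candidates["intercept"] = 1.0
        cols.append("intercept")

    def fit_terms(terms):
        x = candidates[terms] if terms else None
        return sar_error_fit(y, x, weights)

    current: list[str] = []
    current_fit = fit_terms(current)
    trace: list[dict] = []
    step = 0
    improved = True
    while improved:
        improved = False
        # forward sweep
        best = None
        for term in [c for c in cols if c not in current]:
            trial = fit_terms(current + [term])
            idx = trial.names_.index(term)
            rec = {"step": step, "action": "add", "term": term,
                   "bic": trial.bic_, "delta_bic": current_fit.bic_ - trial.bic_,
                   "p": float(trial.pvalues_[idx])}
            trace.append(rec)
            if rec["delta_bic"] >= delta_bic and rec["p"] < alpha:
                if best is None or trial.bic_ < best[1].bic_:
                    best = (term, trial)
        if best is not None:
            current.append(best[0])
            current_fit = best[1]
            improved = True
        # backward sweep: drop terms that no longer earn their keep
        dropped = True
        while dropped and current:
            dropped = False
            for term in list(current):
                reduced = fit_terms([t for t in current if t != term])
                idx = current_fit.names_.index(term)
                p_term = float(current_fit.pvalues_[idx])
                gain = reduced.bic_ - current_fit.bic_  # BIC increase if dropped
                trace.append({"step": step, "action": "drop-check", "term": term,
                              "bic": reduced.bic_, "delta_bic": gain, "p": p_term})
                if p_term >= alpha or gain < delta_bic:
                    current.remove(term)
                    current_fit = reduced
                    dropped = True
                    improved = True
                    break
        step += 1

    if not current:
        log.warning("no term survived selection; returning null spatial model")

    ablation = {}
    for term in current:
        reduced = fit_terms([t for t in current if t != term])
        ablation[term] = reduced.nagelkerke_r2_
    return SelectionResult(model=current_fit, terms=list(current),
                           trace=trace, r2_ablation=ablation)
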