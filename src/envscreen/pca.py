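"""Iterative PCA imputation and correlation-matrix PCA.

Missing indicator cells are filled by a regularized iterative PCA scheme:
standardize, reconstruct with the leading ``ncp`` components (singular
values optionally shrunk by the mean residual variance), refill the
missing cells, and repeat until the filled values stabilize.  PCA itself
is performed on the correlation matrix — columns are standardized and the
standardized data are eigendecomposed — so eigenvalues sum to the number
of variables and variance-explained fractions are eigenvalue / p.

Component signs are fixed deterministically by forcing an anchor
variable's loading positive (poverty for subsets that include it, diesel
PM otherwise), so "higher score = more burdened" reads consistently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin


class PCAImputer(TransformerMixin, BaseEstimator):
    """Fill missing cells by iterative low-rank reconstruction.

    Parameters
    ----------
    ncp : rank of the reconstruction (number of components), default 2.
    tol : convergence threshold on the max absolute change of filled
        cells (on the raw scale), default 1e-6.
    max_iter : iteration cap; non-convergence sets ``converged_ = False``
        and warns rather than raising.
    regularized : if True, shrink each retained singular direction by
        (eigenvalue - residual variance) / eigenvalue; if False, plain
        hard truncation.

    Observed cells are never altered.  Initialization is by column means,
    so the procedure is deterministic.
    """

    def __init__(self, ncp: int = 2, tol: float = 1e-6, max_iter: int = 1000,
                 regularized: bool = True):
        self.ncp = ncp
        self.tol = tol
        self.max_iter = max_iter
        self.regularized = regularized

    def fit(self, X: pd.DataFrame, y=None) -> "PCAImputer":
        self.fit_transform(X)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        is_frame = isinstance(X, pd.DataFrame)
        arr = (X.to_numpy(dtype=float) if is_frame else np.asarray(X, dtype=float)).copy()
        n, p = arr.shape
        if self.ncp >= p:
            raise ValueError("ncp must be smaller than the number of variables")
        miss = np.isnan(arr)
        if (np.sum(~miss, axis=0) < 2).any():
            raise ValueError("every variable needs at least 2 observed values")

        if not miss.any():
            self.n_iter_ = 0
            self.converged_ = True
            self.filled_mask_ = miss
            return X.copy() if is_frame else arr

        col_mean = np.nanmean(arr, axis=0)
        arr[miss] = np.take(col_mean, np.where(miss)[1])

        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            m = arr.mean(axis=0)
            s = arr.std(axis=0, ddof=1)
            if np.any(s == 0):
                raise ValueError("constant column during imputation")
            z = (arr - m) / s
            u, d, vt = np.linalg.svd(z, full_matrices=False)
            eig = d**2 / (n - 1)
            if self.regularized and p > self.ncp:
                sigma2 = eig[self.ncp:].mean()
                shrink = np.maximum(eig[: self.ncp] - sigma2, 0.0) / eig[: self.ncp]
            else:
                shrink = np.ones(self.ncp)
            zhat = (u[:, : self.ncp] * (d[: self.ncp] * shrink)) @ vt[: self.ncp]
            new_vals = (zhat * s + m)[miss]
            delta = np.max(np.abs(new_vals - arr[miss]))
            arr[miss] = new_vals
            if delta < self.tol:
                converged = True
                break
        if not converged:
            import warnings

            warnings.warn(
                f"PCA imputation did not converge in {self.max_iter} iterations "
                f"(last change {delta:.3g})"
            )
        self.n_iter_ = it
        self.converged_ = converged
        self.filled_mask_ = miss
        if is_frame:
            return pd.DataFrame(arr, index=X.index, columns=X.columns)
        return arr

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        # Imputation is a fit-time operation; transform refits on new data.
        return self.fit_transform(X)


class CorrelationPCA(TransformerMixin, BaseEstimator):
    """PCA on the correlation matrix with a deterministic sign convention.

    Fitted attributes
    -----------------
    loadings_ : DataFrame (variables x components), orthonormal columns
        (eigenvectors of the correlation matrix).
    eigenvalues_ : component variances of the standardized data; they sum
        to the number of variables.
    var_explained_ : eigenvalue / n_variables, non-increasing.
    mean_, scale_ : per-variable centering/scaling (sample SD).
    sign_anchor_ : per-component variable whose loading was forced positive.
    """

    #: anchor preference order used when ``sign_anchor`` is None
    _DEFAULT_ANCHORS = ("poverty", "diesel_pm")

    def __init__(self, n_components: int | None = None,
                 sign_anchor: str | None = None):
        self.n_components = n_components
        self.sign_anchor = sign_anchor

    def fit(self, X: pd.DataFrame, y=None) -> "CorrelationPCA":
        is_frame = isinstance(X, pd.DataFrame)
        cols = list(X.columns) if is_frame else [f"v{i}" for i in range(np.shape(X)[1])]
        arr = X.to_numpy(dtype=float) if is_frame else np.asarray(X, dtype=float)
        if np.isnan(arr).any():
            raise ValueError("CorrelationPCA requires a complete table; impute first")
        n, p = arr.shape
        sd = arr.std(axis=0, ddof=1)
        constant = [cols[j] for j in np.where(sd == 0)[0]]
        if constant:
            raise ValueError(f"constant column(s): {constant}")
        self.mean_ = arr.mean(axis=0)
        self.scale_ = sd
        z = (arr - self.mean_) / sd
        _, d, vt = np.linalg.svd(z, full_matrices=False)
        eig = d**2 / (n - 1)
        k = self.n_components or min(n, p)
        k = min(k, p)
        load = vt[:k].T  # p x k eigenvectors

        anchor = self.sign_anchor
        anchors = []
        for j in range(k):
            if anchor is not None and anchor in cols:
                a = cols.index(anchor)
            else:
                preferred = [c for c in self._DEFAULT_ANCHORS if c in cols]
                a = cols.index(preferred[0]) if preferred else int(np.argmax(np.abs(load[:, j])))
            if load[a, j] == 0:
                a = int(np.argmax(np.abs(load[:, j])))
            if load[a, j] < 0:
                load[:, j] = -load[:, j]
            anchors.append(cols[a])

        comp_names = [f"PC{i + 1}" for i in range(k)]
        self.variables_ = cols
        self.loadings_ = pd.DataFrame(load, index=cols, columns=comp_names)
        self.eigenvalues_ = eig[:k]
        self.all_eigenvalues_ = eig
        self.var_explained_ = eig[:k] / p
        self.sign_anchor_ = anchors
        self.n_samples_ = n
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "loadings_"):
            raise ValueError("CorrelationPCA is not fitted")
        is_frame = isinstance(X, pd.DataFrame)
        arr = X[self.variables_].to_numpy(dtype=float) if is_frame else np.asarray(X, dtype=float)
        z = (arr - self.mean_) / self.scale_
        scores = z @ self.loadings_.to_numpy()
        idx = X.index if is_frame else pd.RangeIndex(len(scores))
        return pd.DataFrame(scores, index=idx, columns=self.loadings_.columns)


def impute_iterative(table, ncp: int = 2, tol: float = 1e-6,
                     max_iter: int = 1000, regularized: bool = True):
    """Functional wrapper over :class:`PCAImputer`; returns (table, imputer)."""
    imputer = PCAImputer(ncp=ncp, tol=tol, max_iter=max_iter, regularized=regularized)
    completed = imputer.fit_transform(table)
    return completed, imputer


def fit_pca(table: pd.DataFrame, variable_subset=None,
            sign_anchor: str | None = None) -> CorrelationPCA:
    """Fit :class:`CorrelationPCA` on a complete table (optionally a subset)."""
    cols = list(variable_subset) if variable_subset is not None else list(table.columns)
    return CorrelationPCA(sign_anchor=sign_anchor).fit(table[cols])


def spearman(x, y):
    """Spearman rank correlation over pairwise non-missing values.

    Returns NaN (with a warning) for constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("spearman needs at least 3 paired observations")
    xs, ys = x[ok], y[ok]
    if np.unique(xs).size < 2 or np.unique(ys).size < 2:
        import warnings

        warnings.warn("spearman: constant vector, correlation undefined")
        return float("nan")
    rho = scipy.stats.spearmanr(xs, ys).statistic
    return float(rho)
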