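"""Phylogenetically corrected multivariate statistics.

Under Brownian motion on a phylogeny, trait values at the tips are
multivariate normal with covariance ``R (x) C`` — the Kronecker product
of an evolutionary rate matrix R (traits) and the phylogenetic matrix C
(species).  Everything in this module is generalized least squares with
C as the error structure:

* GLS trait means at the root, ``a = (1' C^-1 1)^-1 1' C^-1 X``;
* the evolutionary rate matrix ``R = (X - 1a')' C^-1 (X - 1a') / (n-1)``
  and its correlation scaling (phylogenetic Pearson correlations);
* PGLS regression of one trait on another;
* phylogenetic signal: Blomberg's K (permutation test) and Pagel's
  lambda (profile maximum likelihood);
* phylogenetic PCA of the rate matrix.

The estimator classes follow scikit-learn conventions (``fit`` plus
fitted attributes with trailing underscores); module-level functions are
thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .tree import PhyloVCV
from .traits import TraitTable

__all__ = [
    "TraitCorrelations",
    "SignalResult",
    "PPCAResult",
    "PGLSResult",
    "PhylogeneticCovariance",
    "PGLSRegression",
    "PhylogeneticPCA",
    "phylo_mean",
    "evolutionary_rate_matrix",
    "phylo_correlations",
    "pgls_fit",
    "blomberg_k",
    "pagel_lambda",
    "phylo_pca",
]

#: condition-number threshold beyond which a ridge is added to C
_COND_MAX = 1e12
_RIDGE = 1e-10


# ---------------------------------------------------------------------
# linear-algebra plumbing


def _as_cov(C) -> np.ndarray:
    if isinstance(C, PhyloVCV):
        return C.matrix
    return np.asarray(C, dtype=float)


def _regularized(C: np.ndarray) -> np.ndarray:
    """Add a small ridge when C is numerically singular."""
    if np.linalg.cond(C) > _COND_MAX:
        warnings.warn("phylogenetic covariance matrix is ill-conditioned; "
                      "adding ridge 1e-10 * mean(diag C)", UserWarning,
                      stacklevel=3)
        C = C + _RIDGE * np.mean(np.diag(C)) * np.eye(C.shape[0])
    return C

def _chol(C: np.ndarray):
    C = _regularized(C)
    try:
        return linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "phylogenetic covariance matrix is singular even after ridging"
        ) from exc


def _gls_mean_and_weights(C: np.ndarray):
    """Return (weights w with a = w'X, cho factor)."""
    cf = _chol(C)
    ones = np.ones(C.shape[0])
    ci1 = linalg.cho_solve(cf, ones)
    return ci1 / (ones @ ci1), cf


# ---------------------------------------------------------------------
# result containers


@dataclass
class TraitCorrelations:
    """Evolutionary rate matrix with its correlation scaling.

    ``significant`` optionally carries externally supplied significance
    flags (e.g. from a published table); when present it takes priority
    over ``pvalues`` in network construction.
    """

    names: tuple
    mean: np.ndarray = field(repr=False)          # GLS root means, length p
    rate: np.ndarray = field(repr=False)          # R, p x p
    corr: np.ndarray = field(repr=False)          # r, p x p, unit diagonal
    tvalues: np.ndarray | None = field(default=None, repr=False)
    pvalues: np.ndarray | None = field(default=None, repr=False)
    n: int | None = None
    significant: np.ndarray | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return len(self.names)

    def drop(self, trait: str) -> "TraitCorrelations":
        """Remove one trait's row/column everywhere; no re-estimation."""
        if trait not in self.names:
            raise KeyError(f"unknown trait {trait!r}")
        keep = [i for i, t in enumerate(self.names) if t != trait]
        ix = np.ix_(keep, keep)
        sub = lambda m: None if m is None else m[ix]
        return TraitCorrelations(
            names=tuple(t for t in self.names if t != trait),
            mean=self.mean[keep] if self.mean is not None else None,
            rate=sub(self.rate), corr=sub(self.corr),
            tvalues=sub(self.tvalues), pvalues=sub(self.pvalues),
            n=self.n, significant=sub(self.significant))

    def corr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.corr, index=self.names, columns=self.names)

    def pvalue_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pvalues, index=self.names, columns=self.names)


@dataclass
class SignalResult:
    """Phylogenetic signal of a single trait."""

    trait: str
    k: float | None = None
    p_k: float | None = None
    n_perm: int | None = None
    lam: float | None = None
    loglik: float | None = None
    loglik0: float | None = None
    p_lambda: float | None = None


@dataclass
class PPCAResult:
    """Phylogenetic principal component analysis output."""

    eigenvalues: np.ndarray
    sdev: np.ndarray
    proportion: np.ndarray
    cumulative: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    mode: str


@dataclass
class PGLSResult:
    """Single-predictor phylogenetic GLS regression."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    t_intercept: float
    t_slope: float
    p_intercept: float
    p_slope: float
    sigma2: float
    n: int
    lam: float | None = None

    @property
    def df_resid(self) -> int:
        return self.n - 2


# ---------------------------------------------------------------------
# GLS means / rate matrix / correlations


class PhylogeneticCovariance(BaseEstimator):
    """GLS estimator of the evolutionary rate and correlation matrices.

    Parameters
    ----------
    vcv : PhyloVCV or (n, n) array
        Brownian-motion covariance of the species, aligned to the rows
        of the data passed to :meth:`fit`.

    Attributes
    ----------
    location_ : ndarray of shape (p,)
        GLS trait means at the root.
    covariance_ : ndarray of shape (p, p)
        Evolutionary rate matrix R (n-1 denominator).
    correlation_ : ndarray of shape (p, p)
        Phylogenetic Pearson correlation matrix.
    tvalues_, pvalues_ : ndarray of shape (p, p)
        Per-pair t statistics (df = n-2) and two-sided p-values.
    """

    def __init__(self, vcv=None):
        self.vcv = vcv

    def fit(self, X, y=None):
        X, names = _table_to_array(X)
        C = _as_cov(self.vcv)
        n, p = X.shape
        if C.shape[0] != n:
            raise ValueError(f"vcv is {C.shape[0]}x{C.shape[0]} but data has {n} rows")
        if n <= p:
            warnings.warn(f"fewer species ({n}) than traits ({p}) + 1; "
                          "rate matrix is rank-deficient", UserWarning)
        w, cf = _gls_mean_and_weights(C)
        a = w @ X
        D = X - a
        R = D.T @ linalg.cho_solve(cf, D) / (n - 1)
        R = (R + R.T) / 2.0
        sd = np.sqrt(np.diag(R))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = R / np.outer(sd, sd)
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        self.feature_names_in_ = names
        self.n_samples_ = n
        self.location_ = a
        self.covariance_ = R
        self.correlation_ = r
        self.tvalues_, self.pvalues_ = _corr_significance(r, n)
        return self

    def results(self) -> TraitCorrelations:
        return TraitCorrelations(
            names=tuple(self.feature_names_in_), mean=self.location_,
            rate=self.covariance_, corr=self.correlation_,
            tvalues=self.tvalues_, pvalues=self.pvalues_, n=self.n_samples_)


def _table_to_array(X):
    if isinstance(X, TraitTable):
        return X.values, tuple(X.trait_names)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, tuple(f"x{i}" for i in range(X.shape[1]))


def _corr_significance(r: np.ndarray, n: int):
    """t = r sqrt((n-2)/(1-r^2)) with df = n-2; |r| = 1 maps to p = 0."""
    if n < 4:
        raise ValueError("need at least 4 species for correlation tests")
    p = r.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    pv = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pv[np.isclose(np.abs(r), 1.0)] = 0.0
    t[np.isinf(t) & (r > 0)] = np.inf
    np.fill_diagonal(pv, 1.0)
    np.fill_diagonal(t, np.inf)
    ut = np.triu_indices(p, 1)
    pv[(ut[1], ut[0])] = pv[ut]  # enforce exact symmetry
    return t, pv


def phylo_mean(X, C) -> np.ndarray:
    """GLS trait means at the root, ``(1'C^-1 1)^-1 1'C^-1 X``."""
    Xa, _ = _table_to_array(X)
    w, _ = _gls_mean_and_weights(_as_cov(C))
    return w @ Xa


def evolutionary_rate_matrix(X, C) -> TraitCorrelations:
    """Evolutionary rate matrix R and GLS means (correlations included)."""
    return PhylogeneticCovariance(vcv=C).fit(X).results()


def phylo_correlations(rates: TraitCorrelations, n: int | None = None) -> TraitCorrelations:
    """Scale a rate matrix to correlations and attach t/p significance."""
    n = rates.n if n is None else n
    if n is None:
        raise ValueError("sample size n is required for significance")
    sd = np.sqrt(np.diag(rates.rate))
    r = rates.rate / np.outer(sd, sd)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    t, pv = _corr_significance(r, n)
    return TraitCorrelations(names=rates.names, mean=rates.mean,
                             rate=rates.rate, corr=r, tvalues=t, pvalues=pv,
                             n=n, significant=rates.significant)


# ---------------------------------------------------------------------
# PGLS


class PGLSRegression(RegressorMixin, BaseEstimator):
    """Phylogenetic generalized least squares, single predictor.

    ``beta = (Z' C^-1 Z)^-1 Z' C^-1 y`` with ``Z = [1, x]`` and C the
    Brownian covariance of the species (optionally lambda-transformed).
    With ``C = I`` this is ordinary least squares.

    Parameters
    ----------
    vcv : PhyloVCV or array
        Species covariance aligned to the fit data.
    lam : float or "ml", default 1.0
        Pagel's lambda applied to the off-diagonal of C.  ``"ml"``
        profiles lambda by maximum likelihood jointly with the
        regression.

    Attributes
    ----------
    coef_, intercept_ : slope and intercept estimates.
    bse_, tvalues_, pvalues_ : standard errors (sigma^2 (Z'C^-1 Z)^-1
        with sigma^2 = GLS RSS / (n - 2)), t statistics and two-sided
        p-values with df = n - 2.
    scale_ : residual variance sigma^2.
    lambda_ : the lambda actually used.
    """

    def __init__(self, vcv=None, lam=1.0):
        self.vcv = vcv
        self.lam = lam

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        n = x.size
        if np.ptp(x) == 0:
            raise ValueError("degenerate predictor: x is constant")
        base = self.vcv if isinstance(self.vcv, PhyloVCV) else \
            PhyloVCV(tuple(map(str, range(n))), _as_cov(self.vcv))
        if self.lam == "ml":
            lam = _profile_lambda_regression(x, y, base)
        else:
            lam = float(self.lam)
        C = _regularized(base.transform(lam).matrix)
        Z = sm.add_constant(x)
        res = sm.GLS(y, Z, sigma=C).fit()
        self.lambda_ = lam
        self.n_samples_ = n
        self.intercept_ = float(res.params[0])
        self.coef_ = np.array([res.params[1]])
        self.bse_ = np.asarray(res.bse)
        self.tvalues_ = np.asarray(res.tvalues)
        self.pvalues_ = np.asarray(res.pvalues)
        self.scale_ = float(res.scale)
        self.df_resid_ = int(res.df_resid)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.coef_[0] * x

    def results(self) -> PGLSResult:
        return PGLSResult(
            intercept=self.intercept_, slope=float(self.coef_[0]),
            se_intercept=float(self.bse_[0]), se_slope=float(self.bse_[1]),
            t_intercept=float(self.tvalues_[0]), t_slope=float(self.tvalues_[1]),
            p_intercept=float(self.pvalues_[0]), p_slope=float(self.pvalues_[1]),
            sigma2=self.scale_, n=self.n_samples_, lam=self.lambda_)


def pgls_fit(y, x, C, lam=1.0) -> PGLSResult:
    """Fit ``y ~ x`` by phylogenetic GLS; see :class:`PGLSRegression`."""
    vcv = C if isinstance(C, PhyloVCV) else PhyloVCV(
        tuple(map(str, range(len(np.asarray(y).reshape(-1))))), _as_cov(C))
    return PGLSRegression(vcv=vcv, lam=lam).fit(x, y).results()


def _gauss_loglik(resid, C):
    """Profile log-likelihood: sigma^2 maximized out analytically (ML, /n)."""
    n = resid.size
    cf = _chol(C)
    quad = resid @ linalg.cho_solve(cf, resid)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    sigma2 = quad / n
    if sigma2 <= 0:
        return np.inf, 0.0
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n), sigma2


def _profile_lambda_regression(x, y, vcv: PhyloVCV) -> float:
    Z = sm.add_constant(x)

    def nll(lam):
        C = vcv.transform(lam).matrix
        cf = _chol(C)
        Ci_Z = linalg.cho_solve(cf, Z)
        beta = np.linalg.solve(Z.T @ Ci_Z, Ci_Z.T @ y)
        ll, _ = _gauss_loglik(y - Z @ beta, C)
        return -ll

    hi = min(vcv.lambda_max(), 10.0)
    res = optimize.minimize_scalar(nll, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-8})
    cands = [(nll(0.0), 0.0), (res.fun, float(res.x))]
    if hi >= 1.0:
        cands.append((nll(1.0), 1.0))
    return min(cands)[1]


# ---------------------------------------------------------------------
# phylogenetic signal


def blomberg_k(x, C, n_perm: int = 999, seed: int | None = None,
               trait: str = "") -> SignalResult:
    """Blomberg's K with a permutation test.

    K compares the observed ratio of non-phylogenetic to phylogenetic
    mean squared error, MSE0/MSE, to its Brownian-motion expectation
    ``(tr C - n / (1'C^-1 1)) / (n - 1)``; K = 1 under Brownian motion,
    and K = 1 identically on a star tree.  The permutation test shuffles
    the tip-to-value assignment and counts permutations whose
    phylogenetic MSE is at most the observed one:
    ``p = (1 + #{MSE_perm <= MSE_obs}) / (1 + n_perm)``.
    ``n_perm = 0`` skips the test (p_k is None); otherwise at least 99
    permutations are required for a meaningful p-value.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 species")
    if n_perm != 0 and n_perm < 99:
        raise ValueError("n_perm must be 0 (no test) or at least 99")
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    Cm = _regularized(_as_cov(C))
    cf = _chol(Cm)
    ones = np.ones(n)
    ci1 = linalg.cho_solve(cf, ones)
    denom1 = ones @ ci1
    w = ci1 / denom1
    Cinv = linalg.cho_solve(cf, np.eye(n))

    def mse_phylo(vec):
        d = vec - w @ vec
        return (d @ Cinv @ d) / (n - 1)

    a = w @ x
    mse0 = np.sum((x - a) ** 2) / (n - 1)
    mse = mse_phylo(x)
    expected = (np.trace(Cm) - n / denom1) / (n - 1)
    k = (mse0 / mse) / expected

    if n_perm == 0:
        return SignalResult(trait=trait, k=float(k), p_k=None, n_perm=0)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    ap = perms @ w
    dev = perms - ap[:, None]
    mse_perm = np.einsum("ij,jk,ik->i", dev, Cinv, dev) / (n - 1)
    p = (1 + int(np.sum(mse_perm <= mse + 1e-15))) / (1 + n_perm)
    return SignalResult(trait=trait, k=float(k), p_k=float(p), n_perm=n_perm)


def pagel_lambda(x, C, trait: str = "") -> SignalResult:
    """Maximum-likelihood Pagel's lambda with a boundary LR test vs 0.

    The profile log-likelihood over lambda in [0, lambda_max] is
    maximized by bounded scalar optimization (tolerance 1e-8); sigma^2
    and the GLS mean are profiled out analytically.  Because lambda = 0
    sits on the boundary of the parameter space, the likelihood-ratio
    p-value uses the 1/2 chi2_0 + 1/2 chi2_1 mixture.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 species")
    vcv = C if isinstance(C, PhyloVCV) else PhyloVCV(tuple(map(str, range(n))),
                                                     _as_cov(C))
    lam_max = vcv.lambda_max()
    if not np.isfinite(lam_max):
        raise ValueError("lambda unidentifiable on a star tree")

    def ll(lam):
        Cl = vcv.transform(lam).matrix
        w, _ = _gls_mean_and_weights(Cl)
        return _gauss_loglik(x - (w @ x), Cl)[0]

    res = optimize.minimize_scalar(lambda l: -ll(l), bounds=(0.0, lam_max),
                                   method="bounded", options={"xatol": 1e-8})
    ll0 = ll(0.0)
    cands = [(-res.fun, float(res.x)), (ll0, 0.0)]
    if lam_max >= 1.0:
        cands.append((ll(1.0), 1.0))
    best_ll, best_lam = max(cands)
    lr = 2.0 * (best_ll - ll0)
    p = 1.0 if lr <= 0 else 0.5 * stats.chi2.sf(lr, df=1)
    return SignalResult(trait=trait, lam=best_lam, loglik=float(best_ll),
                        loglik0=float(ll0), p_lambda=float(p))


# ---------------------------------------------------------------------
# phylogenetic PCA


class PhylogeneticPCA(TransformerMixin, BaseEstimator):
    """PCA of the evolutionary rate matrix (phylogenetic PCA).

    In ``correlation`` mode (default) the rate matrix is scaled to a
    correlation matrix before eigendecomposition, loadings are
    trait-component correlations (|loading| <= 1), and scores are
    computed from GLS-centered, rate-standardized data.  In
    ``covariance`` mode the rate matrix is decomposed directly.  With
    ``C = I`` both reduce to ordinary PCA.  Component signs are fixed so
    the largest-magnitude loading on each axis is positive.
    """

    def __init__(self, vcv=None, mode: str = "correlation"):
        self.vcv = vcv
        self.mode = mode

    def fit(self, X, y=None):
        if self.mode not in ("correlation", "covariance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        Xa, names = _table_to_array(X)
        n, p = Xa.shape
        if p < 2:
            raise ValueError("need at least 2 traits")
        est = PhylogeneticCovariance(vcv=self.vcv).fit(
            pd.DataFrame(Xa, columns=names))
        R = est.covariance_
        sd = np.sqrt(np.diag(R))
        M = est.correlation_ if self.mode == "correlation" else R
        d, V = np.linalg.eigh(M)
        order = np.argsort(d)[::-1]
        d, V = d[order], V[:, order]
        d = np.clip(d, 0.0, None)

        if self.mode == "correlation":
            L = V * np.sqrt(d)            # = M V / sqrt(d): trait-PC correlations
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                L = (R @ V) / np.outer(sd, np.sqrt(d))
            L = np.nan_to_num(L)
        # deterministic sign: largest-|loading| entry positive per axis
        for j in range(p):
            i = int(np.argmax(np.abs(L[:, j])))
            if L[i, j] < 0:
                L[:, j] = -L[:, j]
                V[:, j] = -V[:, j]

        n_comp = p
        if p > n - 1:
            warnings.warn(f"more traits ({p}) than species - 1; returning "
                          f"{n - 1} components", UserWarning)
            n_comp = n - 1
        self.n_components_ = n_comp
        self.feature_names_in_ = names
        self.mean_ = est.location_
        self.rate_matrix_ = R
        self.scale_ = sd
        self.components_ = V[:, :n_comp].T
        self.eigenvalues_ = d[:n_comp]
        self.explained_variance_ = d[:n_comp]
        self.explained_variance_ratio_ = d[:n_comp] / d.sum()
        self._full_eigenvalues = d
        self.loadings_ = L[:, :n_comp]
        return self

    def transform(self, X):
        Xa, _ = _table_to_array(X)
        D = Xa - self.mean_
        if self.mode == "correlation":
            D = D / self.scale_
        return D @ self.components_.T

    def results(self, X) -> PPCAResult:
        d = self._full_eigenvalues
        prop = d / d.sum()
        names = [f"PC{j + 1}" for j in range(self.n_components_)]
        S = self.transform(X)
        index = X.species if isinstance(X, TraitTable) else (
            X.index if isinstance(X, pd.DataFrame) else range(S.shape[0]))
        return PPCAResult(
            eigenvalues=self.eigenvalues_, sdev=np.sqrt(self.eigenvalues_),
            proportion=prop[:self.n_components_],
            cumulative=np.cumsum(prop)[:self.n_components_],
            loadings=pd.DataFrame(self.loadings_, index=self.feature_names_in_,
                                  columns=names),
            scores=pd.DataFrame(S, index=index, columns=names),
            mode=self.mode)


def phylo_pca(X, C, mode: str = "correlation") -> PPCAResult:
    """Phylogenetic PCA; see :class:`PhylogeneticPCA`."""
    est = PhylogeneticPCA(vcv=C, mode=mode).fit(X)
    return est.results(X)
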