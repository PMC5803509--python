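"""Partial least squares of regional gene expression on regional WM loss.

The model regresses a response matrix of per-ROI atrophy scores (one to four
columns, depending on the connection class analysed) on a wide predictor
matrix of regional gene expression (ROIs x genes, typically p >> n).  Both
blocks are z-scored across ROIs.  Components are extracted SIMPLS-style: each
gene-weight vector is the dominant left singular vector of the current
cross-covariance X'Y, ROI scores are t = X w, and both blocks are deflated by
the score subspace.  This maximises covariance between X- and Y-scores and
makes component 1 exactly the dominant singular direction of the standardized
cross-covariance — a property the test suite exploits as an oracle.

Because a PLS component's sign is arbitrary, fitted components are aligned so
ROI scores correlate positively with the first response column; "top" gene
lists are then reproducible.

Usage::

    model = ExpressionAtrophyPLS(expression, atrophy, n_components=2)
    res = model.fit()
    res.summary()
    res.gene_ranking(component=1)
    res.permutation_null_genes(n_perm=1000, seed=7)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import AtrophyMatrix
from .expression import ExpressionMatrix


def _zscore_columns(a: np.ndarray, what: str, allow_constant: bool) -> np.ndarray:
    mu = a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        if not allow_constant:
            raise ValueError(f"constant column in {what}")
        sd = np.where(const, 1.0, sd)
    z = (a - mu) / sd
    if allow_constant and const.any():
        z[:, const] = 0.0
    return z


def _simpls(Xz: np.ndarray, Yz: np.ndarray, n_components: int):
    """Cross-covariance-SVD PLS with score deflation on standardized blocks."""
    X, Y = Xz.copy(), Yz.copy()
    n, p = X.shape
    q = Y.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    for k in range(n_components):
        C = X.T @ Y
        u, s, _ = np.linalg.svd(C, full_matrices=False)
        if s[0] <= 1e-12 * max(1.0, s.sum()):
            W, T = W[:, :k], T[:, :k]
            break
        w = u[:, 0]
        t = X @ w
        tt = t @ t
        if tt <= 0:
            W, T = W[:, :k], T[:, :k]
            break
        W[:, k] = w
        T[:, k] = t
        X = X - np.outer(t, (t @ X) / tt)
        Y = Y - np.outer(t, (t @ Y) / tt)
    return W, T


def _y_variance_fractions(T: np.ndarray, Yz: np.ndarray) -> np.ndarray:
    """Incremental fraction of (standardized) Y variance explained per component."""
    total = float((Yz ** 2).sum())
    fracs = []
    prev = 0.0
    for k in range(1, T.shape[1] + 1):
        beta, *_ = np.linalg.lstsq(T[:, :k], Yz, rcond=None)
        resid = Yz - T[:, :k] @ beta
        r2 = 1.0 - float((resid ** 2).sum()) / total
        fracs.append(max(r2 - prev, 0.0))
        prev = r2
    return np.asarray(fracs)


class ExpressionAtrophyPLS:
    """PLS regression of regional expression (predictors) on atrophy (response).

    Parameters
    ----------
    expression : ExpressionMatrix or DataFrame
        Gene x ROI regional expression.
    atrophy : AtrophyMatrix or DataFrame
        ROI x response-column atrophy scores; rows with missing cells
        (excluded zero-variance cells) are dropped before alignment.
    n_components : int
        Components to extract; truncated with a warning if above the rank
        bound min(n_rois - 1, n_genes).
    """

    def __init__(self, expression, atrophy, n_components: int = 2):
        xdf = expression.values if isinstance(expression, ExpressionMatrix) else expression
        ydf = atrophy.values if isinstance(atrophy, AtrophyMatrix) else atrophy
        ydf = ydf.dropna(axis=0)
        shared = [r for r in xdf.columns if r in set(ydf.index)]
        if len(shared) < 3:
            raise ValueError("fewer than 3 ROIs shared between expression and atrophy")
        self.rois = shared
        self.genes = list(xdf.index)
        self.response_columns = list(ydf.columns)
        self.X = xdf.loc[:, shared].T.to_numpy(dtype=float)  # ROI x gene
        self.Y = ydf.loc[shared].to_numpy(dtype=float)
        rank_bound = min(len(shared) - 1, len(self.genes))
        if n_components > rank_bound:
            warnings.warn(f"n_components={n_components} exceeds rank bound {rank_bound}; truncated")
            n_components = rank_bound
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = n_components

    @classmethod
    def from_matrices(cls, X: pd.DataFrame, Y: pd.DataFrame, n_components: int = 2):
        """Build from an ROI x gene predictor and ROI x response DataFrame."""
        return cls(X.T, Y, n_components=n_components)

    def fit(self, align: bool = True) -> "PLSResults":
        Xz = _zscore_columns(self.X, "X", allow_constant=True)
        Yz = _zscore_columns(self.Y, "Y", allow_constant=False)
        W, T = _simpls(Xz, Yz, self.n_components)
        fracs = _y_variance_fractions(T, Yz)
        res = PLSResults(self, W, T, fracs, Xz, Yz)
        return res.align_sign() if align else res


class PLSResults:
    """Fitted PLS components: gene weights, ROI scores, variance fractions."""

    def __init__(self, model: ExpressionAtrophyPLS, W: np.ndarray, T: np.ndarray,
                 y_variance_fraction: np.ndarray, Xz: np.ndarray, Yz: np.ndarray,
                 sign_flips: tuple[int, ...] | None = None):
        self.model = model
        comps = [f"PLS{k + 1}" for k in range(W.shape[1])]
        self.gene_weights = pd.DataFrame(W, index=pd.Index(model.genes, name="gene"),
                                         columns=comps)
        self.roi_scores = pd.DataFrame(T, index=pd.Index(model.rois, name="roi"),
                                       columns=comps)
        self.y_variance_fraction = np.asarray(y_variance_fraction)
        self._Xz, self._Yz = Xz, Yz
        self.sign_flips = sign_flips or tuple(1 for _ in comps)

    @property
    def n_components(self) -> int:
        return self.gene_weights.shape[1]

    # -- sign convention ---------------------------------------------------
    def align_sign(self) -> "PLSResults":
        """Flip components so ROI scores correlate positively with Y column 1.

        Zero correlation leaves the component unflipped.  Idempotent.
        """
        y1 = self._Yz[:, 0]
        flips = []
        W = self.gene_weights.to_numpy().copy()
        T = self.roi_scores.to_numpy().copy()
        for k in range(W.shape[1]):
            r = float(np.corrcoef(T[:, k], y1)[0, 1]) if T[:, k].std() > 0 else 0.0
            s = -1 if r < 0 else 1
            W[:, k] *= s
            T[:, k] *= s
            flips.append(s)
        return PLSResults(self.model, W, T, self.y_variance_fraction, self._Xz, self._Yz,
                          sign_flips=tuple(flips))

    # -- summaries ---------------------------------------------------------
    def variance_explained(self) -> pd.DataFrame:
        """Per-component and cumulative fraction of response variance explained."""
        frac = self.y_variance_fraction
        return pd.DataFrame({
            "component": [f"PLS{k + 1}" for k in range(len(frac))],
            "y_variance_fraction": frac,
            "cumulative": np.cumsum(frac),
        }).set_index("component")

    def gene_ranking(self, component: int = 1, ascending: bool = False) -> pd.DataFrame:
        """Genes ordered by signed weight on one component (1-based index).

        Descending by default (positive pole first); ties break
        lexicographically by gene id.
        """
        if not (1 <= component <= self.n_components):
            raise IndexError(f"component must be in 1..{self.n_components}")
        col = f"PLS{component}"
        w = self.gene_weights[col]
        order = pd.DataFrame({"gene": w.index, "weight": w.to_numpy()})
        order = order.sort_values(["weight", "gene"], ascending=[ascending, True],
                                  kind="mergesort").reset_index(drop=True)
        order.index.name = "rank"
        return order

    def summary(self) -> str:
        lines = ["Expression-atrophy PLS regression",
                 "=" * 48,
                 f"ROIs: {len(self.model.rois)}   genes: {len(self.model.genes)}   "
                 f"response columns: {len(self.model.response_columns)}",
                 f"components: {self.n_components}   sign flips: {self.sign_flips}",
                 "",
                 self.variance_explained().to_string(float_format=lambda v: f"{v:.4f}"),
                 "",
                 "top genes (component 1):"]
        top = self.gene_ranking(1).head(10)
        lines += [f"  {r.gene:>12s}  {r.weight:+.4f}" for r in top.itertuples()]
        return "\n".join(lines)

    # -- permutation and robustness nulls ----------------------------------
    def permutation_null_genes(self, n_perm: int = 1000, seed: int = 0,
                               return_weights: bool = False) -> "PermutationNull":
        """Null distribution of component-1 Y-variance from permuted predictors.

        Each replicate permutes the ROI rows of standardized X (breaking the
        X-Y correspondence) and refits.  p = (1 + #{null >= observed}) /
        (n_perm + 1).
        """
        rng = np.random.default_rng(seed)
        obs = float(self.y_variance_fraction[0])
        null = np.empty(n_perm)
        weights = np.empty((n_perm, self._Xz.shape[1])) if return_weights else None
        for i in range(n_perm):
            perm = rng.permutation(self._Xz.shape[0])
            W, T = _simpls(self._Xz[perm], self._Yz, 1)
            null[i] = _y_variance_fractions(T, self._Yz)[0] if T.shape[1] else 0.0
            if return_weights:
                weights[i] = W[:, 0] if W.shape[1] else 0.0
        p = (1 + int((null >= obs).sum())) / (n_perm + 1)
        return PermutationNull(observed=obs, null=null, p_value=p, null_weights=weights)

    def permutation_null_rois(self, n_perm: int = 1000, seed: int = 0) -> "ROIPermutationNull":
        """Null per-ROI component-1 score bands from permuted response rows."""
        rng = np.random.default_rng(seed)
        null = np.empty((n_perm, self._Xz.shape[0]))
        for i in range(n_perm):
            perm = rng.permutation(self._Yz.shape[0])
            W, T = _simpls(self._Xz, self._Yz[perm], 1)
            t = T[:, 0] if T.shape[1] else np.zeros(self._Xz.shape[0])
            r = np.corrcoef(t, self._Yz[perm][:, 0])[0, 1] if t.std() > 0 else 0.0
            null[i] = -t if r < 0 else t
        bands = pd.DataFrame({
            "lo": np.quantile(null, 0.025, axis=0),
            "hi": np.quantile(null, 0.975, axis=0),
        }, index=pd.Index(self.model.rois, name="roi"))
        return ROIPermutationNull(observed=self.roi_scores.iloc[:, 0].copy(),
                                  null_scores=null, bands=bands)

    def noise_robustness(self, sigma: float, n_rep: int = 50, seed: int = 0) -> "NoiseRobustness":
        """Stability of component-1 gene weights under added predictor noise.

        Gaussian noise N(0, sigma) is added to the standardized predictors per
        replicate; replicates are sign-aligned before the Spearman correlation
        with the baseline weights is taken.
        """
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        rng = np.random.default_rng(seed)
        base = self.gene_weights.iloc[:, 0].to_numpy()
        cors = np.empty(n_rep)
        for i in range(n_rep):
            Xn = self._Xz + rng.normal(0.0, sigma, self._Xz.shape)
            W, T = _simpls(Xn, self._Yz, 1)
            w = W[:, 0]
            r = np.corrcoef(T[:, 0], self._Yz[:, 0])[0, 1] if T[:, 0].std() > 0 else 0.0
            if r < 0:
                w = -w
            cors[i] = stats.spearmanr(w, base).statistic
        return NoiseRobustness(sigma=sigma, correlations=cors)

    # -- plotting ----------------------------------------------------------
    def plot_permutation_null(self, null: "PermutationNull", ax=None):
        """Histogram of the null variance fractions with the observed value."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(null.null, bins=30, color="0.7")
        ax.axvline(null.observed, color="red", lw=2)
        ax.set_xlabel("component-1 Y-variance fraction")
        ax.set_ylabel("permutations")
        ax.set_title(f"permutation null (p = {null.p_value:.4g})")
        return ax


@dataclass
class PermutationNull:
    observed: float
    null: np.ndarray
    p_value: float
    null_weights: np.ndarray | None = None


@dataclass
class ROIPermutationNull:
    observed: pd.Series
    null_scores: np.ndarray
    bands: pd.DataFrame

    def outside_band(self) -> pd.Series:
        return (self.observed < self.bands["lo"]) | (self.observed > self.bands["hi"])


@dataclass
class NoiseRobustness:
    sigma: float
    correlations: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.correlations))
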