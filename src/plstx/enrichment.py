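"""Statistics on ranked gene lists.

The central statistic is the minimum hypergeometric (mHG) score: for a gene
set of K members inside a ranked universe of N genes, the hypergeometric
tail P(X >= b(n)) is evaluated at every cutoff n and minimised over cutoffs,
making the enrichment test threshold-free.  The exact p-value of the minimum
is computed by dynamic programming over the (cutoff, hits) lattice: a random
placement of the K members is a monotone lattice path, and the DP absorbs
path mass the first time it enters a cell whose tail probability is at most
the observed minimum.

Around it: the enrichment ratio E = (b/n)/(B/N) at the optimal cutoff,
Benjamini-Hochberg FDR across tested terms, permutation tests on mean gene
weights (against random same-size sets, or competitively against curated
competitor sets), the hypergeometric overlap test between two gene lists,
and the Spearman correlation between PLS weights and log2 fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .synth import GeneSetCollection

_REL_TOL = 1e-12


def _log_comb(n, k):
    n, k = np.asarray(n, dtype=float), np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _validate_counts(b: int, n: int, B: int, N: int) -> None:
    if not (0 <= b <= min(n, B) <= N and n <= N and B <= N and n >= 0):
        raise ValueError(f"inconsistent counts: b={b}, n={n}, B={B}, N={N}")


def hypergeom_tail(b: int, n: int, B: int, N: int) -> float:
    """Upper tail P(X >= b) for X ~ Hypergeometric(N, B, n), in log space."""
    _validate_counts(b, n, B, N)
    if b == 0:
        return 1.0
    ks = np.arange(b, min(n, B) + 1)
    if len(ks) == 0:
        return 0.0
    logpmf = _log_comb(B, ks) + _log_comb(N - B, n - ks) - _log_comb(N, n)
    return float(min(np.exp(logsumexp(logpmf)), 1.0))


def enrichment_ratio(b: int, n: int, B: int, N: int) -> float:
    """E = (b/n) / (B/N) — observed vs expected member fraction at the cutoff."""
    if n == 0 or B == 0:
        raise ZeroDivisionError("enrichment ratio undefined for n=0 or B=0")
    _validate_counts(b, n, B, N)
    return (b / n) / (B / N)


def _tail_grid(N: int, K: int) -> np.ndarray:
    """(N+1) x (K+1) grid of tails P(X >= b) at cutoff n; invalid cells 0."""
    n = np.arange(N + 1)[:, None]
    b = np.arange(K + 1)[None, :]
    valid = (b <= np.minimum(n, K)) & (n - b <= N - K)
    logpmf = np.where(valid,
                      _log_comb(K, b) + _log_comb(N - K, n - b) - _log_comb(N, n),
                      -np.inf)
    pmf = np.exp(logpmf)
    tail = pmf[:, ::-1].cumsum(axis=1)[:, ::-1]
    return np.where(valid, np.minimum(tail, 1.0), 0.0)


def _mhg_exact_p(N: int, K: int, s: float, tail: np.ndarray | None = None) -> float:
    """P(min-tail <= s) over all C(N, K) equally likely member placements.

    Forward DP in probability space over path cells (n, b); mass entering a
    cell whose tail is <= s (up to relative tolerance) is absorbed as a hit.
    """
    if s >= 1.0 - _REL_TOL:
        return 1.0
    if tail is None:
        tail = _tail_grid(N, K)
    thresh = s * (1.0 + _REL_TOL)
    f = np.zeros(K + 1)
    f[0] = 1.0
    b = np.arange(K + 1)
    absorbed = 0.0  # accumulated hit mass avoids 1 - f[K] cancellation at tiny p
    for n in range(N):
        p_member = np.clip((K - b) / (N - n), 0.0, 1.0)
        new = f * (1.0 - p_member)
        new[1:] += (f * p_member)[:-1]
        hit = (tail[n + 1] > 0) & (tail[n + 1] <= thresh)
        absorbed += float(new[hit].sum())
        new[hit] = 0.0
        f = new
    return float(min(max(absorbed, 0.0), 1.0))


@dataclass
class MHGResult:
    n_star: int
    b_star: int
    score: float  # minimal hypergeometric tail over cutoffs
    p_value: float  # exact p of that minimum
    N: int
    K: int


def mhg_scan(ranked_membership) -> MHGResult:
    """Threshold-free ranked enrichment of a binary membership vector.

    ``ranked_membership[i]`` indicates whether the gene at rank i (0 = top)
    belongs to the set.  Returns the minimising cutoff (smallest n on ties),
    the mHG score and its exact p-value.
    """
    member = np.asarray(ranked_membership, dtype=bool)
    N = len(member)
    K = int(member.sum())
    if K == 0:
        raise ValueError("gene set has no members in the ranked universe")
    tail = _tail_grid(N, K)
    b_at = np.cumsum(member)
    cutoffs = np.arange(1, N + 1)
    tails = tail[cutoffs, b_at]
    i = int(np.argmin(tails))  # first occurrence -> smallest n on ties
    score = float(tails[i])
    p = _mhg_exact_p(N, K, score, tail=tail)
    return MHGResult(n_star=int(cutoffs[i]), b_star=int(b_at[i]), score=score,
                     p_value=p, N=N, K=K)


@dataclass
class EnrichmentRecord:
    term_id: str
    description: str
    p_value: float
    q_value: float
    enrichment: float
    B: int
    n: int
    b: int
    N: int


def go_enrichment(ranked_genes, sets: GeneSetCollection, max_term_size: int = 1000,
                  min_term_size: int = 3, mode: str = "ranked",
                  top_fraction: float = 0.1) -> pd.DataFrame:
    """Ranked gene-set enrichment over a collection, with BH-FDR q-values.

    ``ranked_genes`` is the full ranked universe (descending weight);
    sets are intersected with it, exact-duplicate member sets are collapsed,
    and terms outside [min_term_size, max_term_size] after intersection are
    dropped.  ``mode='ranked'`` (default) uses the threshold-free mHG
    statistic; ``mode='top_fraction'`` tests the fixed top fraction of the
    ranking with a plain hypergeometric tail.
    """
    if isinstance(ranked_genes, pd.DataFrame):
        ranked_genes = ranked_genes["gene"].tolist()
    universe = list(ranked_genes)
    pos = {g: i for i, g in enumerate(universe)}
    N = len(universe)

    seen_members: dict[frozenset, str] = {}
    rows = []
    for term, members in sets.sets.items():
        inter = frozenset(m for m in members if m in pos)
        if not (min_term_size <= len(inter) <= max_term_size):
            continue
        if inter in seen_members:  # exact-duplicate member filter
            continue
        seen_members[inter] = term
        member_vec = np.zeros(N, dtype=bool)
        member_vec[[pos[m] for m in inter]] = True
        K = len(inter)
        if mode == "ranked":
            r = mhg_scan(member_vec)
            p, n_star, b_star = r.p_value, r.n_star, r.b_star
        elif mode == "top_fraction":
            n_star = max(int(round(top_fraction * N)), 1)
            b_star = int(member_vec[:n_star].sum())
            p = hypergeom_tail(b_star, n_star, K, N)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        E = enrichment_ratio(b_star, n_star, K, N) if b_star else 0.0
        rows.append((term, sets.descriptions.get(term, term), p, E, K, n_star, b_star))
    if not rows:
        raise ValueError("no gene set survives the size filters")
    out = pd.DataFrame(rows, columns=["term_id", "description", "p_value",
                                      "enrichment", "B", "n", "b"])
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["N"] = N
    out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return out[["term_id", "description", "p_value", "q_value", "enrichment", "B", "n", "b", "N"]]


@dataclass
class WeightEnrichment:
    observed_mean: float
    null_means: np.ndarray
    p_value: float


def geneset_weight_enrichment(weights: pd.Series, target, n_perm: int = 1000,
                              seed: int = 0) -> WeightEnrichment:
    """Mean weight of a target gene list vs random same-size gene sets.

    p = (1 + #{null mean >= observed mean}) / (n_perm + 1).
    """
    target = [g for g in target if g in weights.index]
    if not target:
        raise ValueError("target list is empty after intersecting the weight universe")
    rng = np.random.default_rng(seed)
    w = weights.to_numpy(dtype=float)
    obs = float(weights.loc[target].mean())
    k = len(target)
    idx = np.arange(len(w))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = w[rng.choice(idx, size=k, replace=False)].mean()
    p = (1 + int((null >= obs).sum())) / (n_perm + 1)
    return WeightEnrichment(observed_mean=obs, null_means=null, p_value=p)


@dataclass
class CompetitiveResult:
    observed_mean: float
    competitor_means: np.ndarray
    p_value: float
    n_competitors: int

    @property
    def p_bound(self) -> float:
        """Reported upper bound when the target beats every competitor."""
        return max(self.p_value, 0.0) if self.p_value > 0 else 1.0 / self.n_competitors


def competitive_geneset_comparison(weights: pd.Series, target, competitors,
                                   seed: int = 0) -> CompetitiveResult:
    """Target mean weight vs the mean weights of curated competitor sets.

    Competitors with a different size are subsampled (with a warning) to the
    target size, so all means are size-matched.  p = fraction of competitor
    sets whose mean weight >= the target's.
    """
    if len(competitors) < 20:
        raise ValueError("at least 20 competitor sets are required")
    target = [g for g in target if g in weights.index]
    if not target:
        raise ValueError("target list is empty after intersecting the weight universe")
    rng = np.random.default_rng(seed)
    obs = float(weights.loc[target].mean())
    k = len(target)
    means = []
    mismatched = 0
    for comp in competitors:
        comp = [g for g in comp if g in weights.index]
        if len(comp) != k:
            mismatched += 1
            if len(comp) > k:
                comp = list(rng.choice(comp, size=k, replace=False))
        means.append(float(weights.loc[comp].mean()))
    if mismatched:
        warnings.warn(f"{mismatched} competitor sets size-matched by subsampling")
    means = np.asarray(means)
    p = float((means >= obs).mean())
    return CompetitiveResult(observed_mean=obs, competitor_means=means,
                             p_value=p, n_competitors=len(means))


def overlap_test(list_a, list_b, universe: int) -> tuple[int, float]:
    """Overlap count and hypergeometric tail p between two gene lists."""
    a, b_ = set(list_a), set(list_b)
    if len(a) != len(list(list_a)) or len(b_) != len(list(list_b)):
        warnings.warn("duplicate genes within a list were deduplicated")
    if max(len(a), len(b_)) > universe:
        raise ValueError("list larger than the universe")
    b = len(a & b_)
    return b, hypergeom_tail(b, len(a), len(b_), universe)


def weight_foldchange_correlation(weights: pd.Series,
                                  log2fc: pd.DataFrame) -> tuple[float, float, int]:
    """Spearman correlation between PLS weights and log2 fold changes.

    Computed on the gene intersection; returns (rho, p, n_shared).
    """
    fc = log2fc.set_index("gene")["log2fc"] if "gene" in log2fc.columns else log2fc.iloc[:, 0]
    shared = weights.index.intersection(fc.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} genes shared; need >= 10")
    r = stats.spearmanr(weights.loc[shared], fc.loc[shared])
    return float(r.statistic), float(r.pvalue), len(shared)
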