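"""Synthetic data with planted ground truth for the full analysis chain.

The generators emulate the study design the pipeline expects without any
external downloads:

* a bilateral cortical parcellation (default 34 ROIs per hemisphere, i.e. 68
  cortical ROIs) plus four striatal nodes (left/right caudate and putamen);
* grouped patient/control structural connectomes at three visits, where
  patient edge weights in each connection class decay multiplicatively along
  a planted cortical gradient, linearly in time;
* multi-donor probe-level microarray-like expression whose regional signal is
  a planted rank-one (or rank-two) gene-loading x ROI-gradient pattern;
* gene-set collections with terms planted at the top of the loading ranking;
* log2 fold-change tables with a target Spearman correlation to the planted
  loadings (Gaussian-copula construction).

Every generator is a pure function of its arguments including ``seed``.
``GroundTruth`` stores unit-norm gradients and loadings; forward models use
max-scaled copies so that class effect sizes in [0, 1) bound the
multiplicative loss factor (monotone rescaling, so rank-based recovery
checks are unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io as pio
from .connectome import ANALYSIS_CLASSES, Connectome, edge_class_matrix

DEFAULT_EFFECTS = {
    "corticostriatal": 0.3,
    "interhemispheric": 0.2,
    "intrahemispheric": 0.1,
}


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic longitudinal patient/control cohort."""

    n_patients: int = 72
    n_controls: int = 85
    timepoints: tuple[float, ...] = (0.0, 12.0, 24.0)  # months
    effect_size_by_class: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    seed: int = 0
    edge_density: float = 0.35
    edge_noise_sd: float = 0.1
    edge_weight_logmean: float = np.log(100.0)
    edge_weight_logsd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("n_patients and n_controls must each be >= 2")
        tp = tuple(self.timepoints)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        for cls, eff in self.effect_size_by_class.items():
            if cls not in ANALYSIS_CLASSES:
                raise ValueError(f"unknown connection class {cls!r}")
            if not (0 <= eff < 1):
                raise ValueError(f"effect size for {cls} must be in [0, 1)")
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must be in (0, 1]")


@dataclass
class TruthProfile:
    """One planted latent component: a cortical gradient paired with gene loadings."""

    roi_gradient: pd.Series  # unit Euclidean norm, indexed by cortical ROI name
    gene_loadings: pd.Series  # unit Euclidean norm, indexed by gene

    def __post_init__(self) -> None:
        for name, v in (("roi_gradient", self.roi_gradient), ("gene_loadings", self.gene_loadings)):
            norm = np.linalg.norm(v.to_numpy(dtype=float))
            if not np.isclose(norm, 1.0):
                raise ValueError(f"{name} must have unit norm (got {norm:.6g})")


def _fwd(v: pd.Series) -> pd.Series:
    """Max-abs-scaled copy used by forward models (entries in [-1, 1])."""
    return v / np.abs(v.to_numpy()).max()


@dataclass
class GroundTruth:
    """Planted signal shared by all generators, the recovery target of tests."""

    profiles: dict[str, TruthProfile]
    class_to_profile: dict[str, str]
    planted_set_profiles: dict[str, str]  # planted gene-set id -> profile name
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for cls, prof in self.class_to_profile.items():
            if prof not in self.profiles:
                raise ValueError(f"class {cls!r} mapped to unknown profile {prof!r}")
        for term, prof in self.planted_set_profiles.items():
            if prof not in self.profiles:
                raise ValueError(f"planted set {term!r} mapped to unknown profile {prof!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def roi_gradient(self) -> pd.Series:
        return self.profiles["primary"].roi_gradient

    @property
    def gene_loadings(self) -> pd.Series:
        return self.profiles["primary"].gene_loadings

    @property
    def planted_sets(self) -> list[str]:
        return list(self.planted_set_profiles)


# ---------------------------------------------------------------------------
# atlas

def generate_atlas(n_cortical_per_hemisphere: int = 34, seed: int = 0) -> pd.DataFrame:
    """Bilateral cortical parcellation plus four striatal nodes.

    Cortical centroids are drawn in the right half-space (x > 0) and mirrored
    to the left, giving homologous pairs; the four striatal nodes (L/R caudate
    and putamen) sit near the midline at fixed anatomical-flavoured positions.
    """
    n = int(n_cortical_per_hemisphere)
    if n < 2:
        raise ValueError("n_cortical_per_hemisphere must be >= 2")
    rng = np.random.default_rng(seed)
    # centroids on a jittered 22 mm grid: the >=16 mm minimum separation keeps
    # nearest-centroid matching reliable at the donor sample jitter scale
    grid = np.array([(gx, gy, gz)
                     for gx in np.linspace(20, 64, 3)
                     for gy in np.linspace(-75, 57, 7)
                     for gz in np.linspace(-15, 51, 4)])
    if n > len(grid):
        raise ValueError(f"n_cortical_per_hemisphere must be <= {len(grid)}")
    chosen = grid[rng.choice(len(grid), size=n, replace=False)]
    chosen = chosen + rng.uniform(-3, 3, chosen.shape)
    x, y, z = chosen[:, 0], chosen[:, 1], chosen[:, 2]
    rows = []
    for i in range(n):
        rows.append((f"ctx-lh-{i + 1:02d}", "L", "cortical", -x[i], y[i], z[i]))
    for i in range(n):
        rows.append((f"ctx-rh-{i + 1:02d}", "R", "cortical", x[i], y[i], z[i]))
    rows += [
        ("caudate-lh", "L", "striatal", -14.0, 9.0, 12.0),
        ("caudate-rh", "R", "striatal", 14.0, 9.0, 12.0),
        ("putamen-lh", "L", "striatal", -25.0, -1.0, 2.0),
        ("putamen-rh", "R", "striatal", 25.0, -1.0, 2.0),
    ]
    atlas = pd.DataFrame(rows, columns=["name", "hemisphere", "node_class", "x", "y", "z"])
    atlas.insert(0, "roi_id", np.arange(len(atlas)))
    return atlas


def cortical_names(atlas: pd.DataFrame) -> list[str]:
    return atlas.loc[atlas["node_class"] == "cortical", "name"].tolist()


# ---------------------------------------------------------------------------
# ground truth

def _rank_uniform(v: np.ndarray) -> np.ndarray:
    r = stats.rankdata(v, method="ordinal")
    return r / (len(v) + 1.0)


def make_ground_truth(atlas: pd.DataFrame, genes: list[str], seed: int = 0,
                      noise_sd: float = 0.5, two_profile: bool = False) -> GroundTruth:
    """Plant gradients and loadings.

    The primary gradient follows the posterior-anterior axis (plus jitter),
    echoing posterior-weighted vulnerability; loadings are half-normal, so the
    expression-atrophy alignment has a fixed positive sign.  With
    ``two_profile``, a secondary gradient orthogonalised against the primary
    drives the intrahemispheric class, and the gene universe is split into
    disjoint loading pools (40% primary, 40% secondary, 20% unloaded).
    """
    rng = np.random.default_rng(seed)
    cort = atlas[atlas["node_class"] == "cortical"]
    names = cort["name"].tolist()
    n_roi, n_gene = len(names), len(genes)

    g1_raw = _rank_uniform(-cort["y"].to_numpy() + rng.normal(0, 30, n_roi))
    g1 = pd.Series(g1_raw / np.linalg.norm(g1_raw), index=names)

    if not two_profile:
        l_raw = np.abs(rng.normal(0, 1, n_gene))
        l1 = pd.Series(l_raw / np.linalg.norm(l_raw), index=genes)
        return GroundTruth(
            profiles={"primary": TruthProfile(g1, l1)},
            class_to_profile={c: "primary" for c in ANALYSIS_CLASSES},
            planted_set_profiles={"PLANTED:primary": "primary"},
            noise_sd=noise_sd,
        )

    # secondary gradient: rank-uniform transform of the residual of a random
    # vector against the centred primary gradient -> near-zero rank correlation
    z2 = rng.normal(0, 1, n_roi)
    g1c = g1_raw - g1_raw.mean()
    resid = z2 - (z2 @ g1c) / (g1c @ g1c) * g1c
    g2_raw = _rank_uniform(resid)
    g2 = pd.Series(g2_raw / np.linalg.norm(g2_raw), index=names)

    perm = rng.permutation(n_gene)
    n_pool = int(0.4 * n_gene)
    pool_a, pool_b = perm[:n_pool], perm[n_pool:2 * n_pool]
    l1_raw = np.zeros(n_gene)
    l2_raw = np.zeros(n_gene)
    l1_raw[pool_a] = np.abs(rng.normal(0, 1, n_pool))
    l2_raw[pool_b] = np.abs(rng.normal(0, 1, n_pool))
    l1 = pd.Series(l1_raw / np.linalg.norm(l1_raw), index=genes)
    l2 = pd.Series(l2_raw / np.linalg.norm(l2_raw), index=genes)

    return GroundTruth(
        profiles={"primary": TruthProfile(g1, l1), "secondary": TruthProfile(g2, l2)},
        class_to_profile={"corticostriatal": "primary",
                          "interhemispheric": "primary",
                          "intrahemispheric": "secondary"},
        planted_set_profiles={"PLANTED:primary": "primary", "PLANTED:secondary": "secondary"},
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# connectomes

def generate_cohort_connectomes(atlas: pd.DataFrame, spec: CohortSpec,
                                truth: GroundTruth) -> list[Connectome]:
    """Forward model standing in for tractography.

    A shared base connectome (Erdos-Renyi corticocortical mask at
    ``spec.edge_density`` with log-normal weights; corticostriatal edges always
    present, since every cortical region projects to the striatum) is
    perturbed per subject x visit by multiplicative log-normal noise.  Patient
    edges in class c are additionally scaled by
    ``1 - effect[c] * gradient_c(edge) * t / t_max`` where ``gradient_c`` is
    the max-scaled planted gradient of the profile driving class c (mean of
    the two endpoint values for corticocortical edges).
    """
    names = atlas["name"].tolist()
    cort_names = cortical_names(atlas)
    if list(truth.roi_gradient.index) != cort_names:
        raise ValueError("truth.roi_gradient must be indexed by the atlas cortical ROIs")

    n = len(names)
    classes = edge_class_matrix(atlas).to_numpy()
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss)

    iu = np.triu_indices(n, k=1)
    mask = np.zeros((n, n), dtype=bool)
    keep = rng.random(len(iu[0])) < spec.edge_density
    mask[iu] = keep
    cs = classes == "corticostriatal"
    ssx = classes == "striatostriatal"
    mask[iu] |= cs[iu] | ssx[iu]
    base = np.zeros((n, n))
    base[iu] = np.where(mask[iu], np.exp(rng.normal(spec.edge_weight_logmean,
                                                    spec.edge_weight_logsd, len(iu[0]))), 0.0)

    # per-node forward gradient value per class profile
    node_grad: dict[str, np.ndarray] = {}
    for cls in ANALYSIS_CLASSES:
        g = _fwd(truth.profiles[truth.class_to_profile[cls]].roi_gradient)
        vals = np.zeros(n)
        is_cort = (atlas["node_class"] == "cortical").to_numpy()
        vals[is_cort] = g.loc[np.asarray(names)[is_cort]].to_numpy()
        node_grad[cls] = vals

    # edge-level loss gradient (upper triangle)
    grad_edge = np.zeros(len(iu[0]))
    for cls in ANALYSIS_CLASSES:
        sel = classes[iu] == cls
        gi = node_grad[cls][iu[0][sel]]
        gj = node_grad[cls][iu[1][sel]]
        if cls == "corticostriatal":
            val = np.maximum(gi, gj)  # striatal endpoint carries 0
        else:
            val = 0.5 * (gi + gj)
        grad_edge[sel] = spec.effect_size_by_class.get(cls, 0.0) * val

    t_max = max(spec.timepoints)
    t_scale = t_max if t_max > 0 else 1.0
    out: list[Connectome] = []
    subjects = [("patient", f"pat{i:03d}") for i in range(spec.n_patients)] + \
               [("control", f"con{i:03d}") for i in range(spec.n_controls)]
    for group, sid in subjects:
        for t in spec.timepoints:
            noise = np.exp(rng.normal(0.0, spec.edge_noise_sd, len(iu[0])))
            w_edge = base[iu] * noise
            if group == "patient":
                w_edge = w_edge * (1.0 - grad_edge * (t / t_scale))
            w = np.zeros((n, n))
            w[iu] = w_edge
            w = w + w.T
            out.append(Connectome(subject_id=sid, group=group, timepoint=float(t),
                                  weights=pd.DataFrame(w, index=names, columns=names)))
    return out


# ---------------------------------------------------------------------------
# donor expression

@dataclass
class DonorExpression:
    donor_id: str
    samples: pd.DataFrame  # index sample_id, columns x, y, z
    probes: pd.DataFrame  # index probe_id, columns sample_id
    true_roi: pd.Series  # sample_id -> source cortical ROI name (generator oracle)


@dataclass
class ExpressionBundle:
    donors: list[DonorExpression]
    probe_map: pd.Series  # probe_id -> gene
    genes: list[str]


def generate_expression(atlas: pd.DataFrame, n_genes: int, n_donors: int,
                        truth: GroundTruth, probes_per_gene: int = 2, seed: int = 0,
                        jitter_sd: float = 2.0, samples_per_roi: int = 1,
                        amplitude: float = 2.0, n_background: int = 40,
                        background_amplitude: float = 1.5) -> ExpressionBundle:
    """Donor probe-level expression with samples jittered off cortical centroids.

    Probe value for gene g at a sample from ROI r:
    ``baseline_g + amplitude * sum_profiles lfwd_p(g) * gfwd_p(r) + background
    + N(0, noise_sd)`` with per-gene baselines ~ N(8, 1) on a log2-like
    microarray scale, shared across donors.  The background term adds
    ``n_background`` rank-one components with signed loadings and random ROI
    gradients *orthogonalised against the planted gradients*, emulating the
    many spatial expression patterns of a real transcriptome atlas: they
    leave the observed expression-atrophy alignment almost untouched, but
    they are what permuted-response fits latch onto, so null gene weights
    decorrelate from the planted loadings while null variance fractions stay
    large.  Set ``n_background=0`` for the bare baseline-plus-planted
    construction.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    if probes_per_gene < 1 or samples_per_roi < 1:
        raise ValueError("probes_per_gene and samples_per_roi must be >= 1")
    genes = list(truth.gene_loadings.index)
    if len(genes) != n_genes:
        raise ValueError(f"truth has {len(genes)} genes but n_genes={n_genes}")

    cort = atlas[atlas["node_class"] == "cortical"]
    roi_names = cort["name"].tolist()
    centroids = cort[["x", "y", "z"]].to_numpy(dtype=float)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    baseline = rng.normal(8.0, 1.0, n_genes)

    signal = np.zeros((n_genes, len(roi_names)))
    for prof in truth.profiles.values():
        lf = _fwd(prof.gene_loadings).to_numpy()
        gf = _fwd(prof.roi_gradient).to_numpy()
        signal += amplitude * np.outer(lf, gf)
    planted_dirs = []
    for prof in truth.profiles.values():
        g = _fwd(prof.roi_gradient).to_numpy()
        planted_dirs.append(g - g.mean())
    for _ in range(n_background):
        lb = rng.normal(0.0, 1.0, n_genes)
        gb = rng.normal(0.0, 1.0, len(roi_names))
        for q in planted_dirs:
            gb = gb - (gb @ q) / (q @ q) * q
        signal += background_amplitude * np.outer(lb / np.abs(lb).max(),
                                                  gb / np.abs(gb).max())

    probe_ids = [f"{g}_p{j}" for g in genes for j in range(probes_per_gene)]
    probe_gene = [g for g in genes for _ in range(probes_per_gene)]
    probe_map = pd.Series(probe_gene, index=pd.Index(probe_ids, name="probe_id"), name="gene")
    probe_signal = np.repeat(baseline[:, None] + signal, probes_per_gene, axis=0)

    donors: list[DonorExpression] = []
    for d in range(n_donors):
        did = f"donor{d + 1:02d}"
        sample_ids, coords, src = [], [], []
        for r, roi in enumerate(roi_names):
            for k in range(samples_per_roi):
                sample_ids.append(f"{did}|{roi}|{k}")
                coords.append(centroids[r] + rng.normal(0.0, jitter_sd, 3))
                src.append(roi)
        roi_idx = np.repeat(np.arange(len(roi_names)), samples_per_roi)
        values = probe_signal[:, roi_idx] + rng.normal(0.0, truth.noise_sd,
                                                       (len(probe_ids), len(sample_ids)))
        donors.append(DonorExpression(
            donor_id=did,
            samples=pd.DataFrame(np.asarray(coords), index=pd.Index(sample_ids, name="sample_id"),
                                 columns=["x", "y", "z"]),
            probes=pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                                columns=sample_ids),
            true_roi=pd.Series(src, index=sample_ids),
        ))
    return ExpressionBundle(donors=donors, probe_map=probe_map, genes=genes)


# ---------------------------------------------------------------------------
# gene sets

@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def to_gmt(self, path) -> None:
        pio.write_gmt(self.sets, path, self.descriptions)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets, desc = pio.read_gmt(path)
        return cls(sets=sets, descriptions=desc)


def generate_gene_sets(genes: list[str], n_terms: int, size_range: tuple[int, int],
                       planted: dict[str, float] | None = None, seed: int = 0,
                       loadings: pd.Series | None = None) -> GeneSetCollection:
    """Random member sets, plus planted terms concentrated at the loading top.

    For a planted term of size m with fraction f, ``round(f*m)`` members are
    drawn from the top-m genes of the |loadings| ranking and the remainder
    from outside that pool.
    """
    lo, hi = size_range
    if lo < 2 or hi > len(genes) or lo > hi:
        raise ValueError("size_range must lie within [2, n_genes]")
    planted = planted or {}
    for term, frac in planted.items():
        if not (0 < frac <= 1):
            raise ValueError(f"planted fraction for {term!r} must be in (0, 1]")
    if planted and loadings is None:
        raise ValueError("loadings are required to plant enriched terms")

    rng = np.random.default_rng(seed)
    genes = list(genes)
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for i in range(n_terms):
        term = f"T{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        sets[term] = set(rng.choice(genes, size=size, replace=False))
        desc[term] = "random member set"
    for term, frac in planted.items():
        size = int(rng.integers(lo, hi + 1))
        order = loadings.abs().sort_values(ascending=False, kind="mergesort").index
        pool = list(order[:size])
        rest = list(order[size:])
        k = int(round(frac * size))
        members = list(rng.choice(pool, size=k, replace=False))
        if size - k > 0:
            members += list(rng.choice(rest, size=size - k, replace=False))
        sets[term] = set(members)
        desc[term] = f"planted set (fraction {frac:g} from loading top)"
    return GeneSetCollection(sets=sets, descriptions=desc)


# ---------------------------------------------------------------------------
# fold change

def generate_foldchange(truth: GroundTruth, target_correlation: float, seed: int = 0,
                        profile: str = "primary", scale: float = 0.8) -> pd.DataFrame:
    """log2 fold-change table with a target Spearman correlation to the loadings.

    Latent normal scores of the loading ranks are mixed with independent
    noise, and the mixing coefficient is solved numerically so the realised
    Spearman correlation matches the target tightly at any gene count.
    """
    if not (-1 <= target_correlation <= 1):
        raise ValueError("target_correlation must be in [-1, 1]")
    l = truth.profiles[profile].gene_loadings
    n = len(l)
    rng = np.random.default_rng(seed)
    # break exact ties (e.g. unloaded genes at 0) so ranks are unambiguous
    jitter = rng.normal(0, 1e-9, n)
    ranks = stats.rankdata(l.to_numpy() + jitter, method="ordinal")
    z_l = stats.norm.ppf(ranks / (n + 1.0))
    if abs(target_correlation) == 1.0:
        fc = np.sign(target_correlation) * z_l
    else:
        from scipy.optimize import brentq
        eps = rng.normal(0, 1, n)

        def achieved(a: float) -> float:
            mix = a * z_l + np.sqrt(1.0 - a * a) * eps
            return stats.spearmanr(mix, z_l).statistic - target_correlation

        a = brentq(achieved, -1.0, 1.0, xtol=1e-4)
        fc = a * z_l + np.sqrt(1.0 - a * a) * eps
    return pd.DataFrame({"gene": list(l.index), "log2fc": scale * fc})


# ---------------------------------------------------------------------------
# full dataset

@dataclass
class SyntheticDataset:
    atlas: pd.DataFrame
    truth: GroundTruth
    connectomes: list[Connectome]
    expression: ExpressionBundle
    gene_sets: GeneSetCollection
    foldchange: pd.DataFrame
    gene_lists: dict[str, list[str]]
    spec: CohortSpec


def generate_dataset(seed: int = 0, n_cortical_per_hemisphere: int = 34,
                     n_genes: int = 2000, n_donors: int = 6, probes_per_gene: int = 2,
                     noise_sd: float = 0.5, two_profile: bool = False,
                     cohort: CohortSpec | None = None, n_terms: int = 30,
                     size_range: tuple[int, int] = (10, 60), planted_fraction: float = 0.9,
                     foldchange_rho: float = -0.23, list_size: int = 50) -> SyntheticDataset:
    """Generate every input the pipeline consumes, sharing one ground truth.

    Curated gene lists: per profile, a "disease-like" list of the ``list_size``
    top-loading genes (analog of transcriptionally dysregulated gene lists)
    and one random list of the same size.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)]
    atlas = generate_atlas(n_cortical_per_hemisphere, seed=seeds[0])
    genes = [f"g{i:05d}" for i in range(n_genes)]
    truth = make_ground_truth(atlas, genes, seed=seeds[1], noise_sd=noise_sd,
                              two_profile=two_profile)
    if cohort is None:
        cohort = CohortSpec(seed=seeds[2])
    connectomes = generate_cohort_connectomes(atlas, cohort, truth)
    expression = generate_expression(atlas, n_genes, n_donors, truth,
                                     probes_per_gene=probes_per_gene, seed=seeds[3])
    planted = {term: planted_fraction for term in truth.planted_sets}
    # plant each term against the loadings of its own profile
    sets = generate_gene_sets(genes, n_terms, size_range, seed=seeds[4],
                              planted={t: f for t, f in planted.items()
                                       if truth.planted_set_profiles[t] == "primary"},
                              loadings=truth.gene_loadings)
    for term in truth.planted_sets:
        prof = truth.planted_set_profiles[term]
        if prof == "primary":
            continue
        extra = generate_gene_sets(genes, 0, size_range, seed=seeds[4] + 1,
                                   planted={term: planted[term]},
                                   loadings=truth.profiles[prof].gene_loadings)
        sets.sets.update(extra.sets)
        sets.descriptions.update(extra.descriptions)
    foldchange = generate_foldchange(truth, foldchange_rho, seed=seeds[5])
    rng = np.random.default_rng(seeds[5] + 1)
    gene_lists: dict[str, list[str]] = {}
    for prof_name, prof in truth.profiles.items():
        top = prof.gene_loadings.abs().sort_values(ascending=False, kind="mergesort")
        gene_lists[f"disease_{prof_name}"] = list(top.index[:list_size])
    gene_lists["random"] = list(rng.choice(genes, size=list_size, replace=False))
    return SyntheticDataset(atlas=atlas, truth=truth, connectomes=connectomes,
                            expression=expression, gene_sets=sets, foldchange=foldchange,
                            gene_lists=gene_lists, spec=cohort)
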