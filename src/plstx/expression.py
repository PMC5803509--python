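"""Gene x ROI regional expression from donor probe-level samples.

Probe values are averaged per gene, samples are matched to cortical ROI
centroids, and regional values are averaged in two stages (within donor,
then across donors) so donors with more samples do not dominate a region.
A single-pass QC step excludes ROIs whose mean-over-genes expression or
expression range is an outlier across ROIs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .synth import DonorExpression


@dataclass
class ExpressionMatrix:
    """Gene x cortical-ROI regional expression with QC provenance."""

    values: pd.DataFrame  # gene x ROI
    excluded_rois: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)  # donor ids used

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("ExpressionMatrix must have no missing values")
        if self.values.index.duplicated().any():
            raise ValueError("gene index must be unique")
        overlap = set(self.excluded_rois) & set(self.values.columns)
        if overlap:
            raise ValueError(f"excluded ROIs still present as columns: {sorted(overlap)}")


@dataclass
class RegionAssignment:
    sample_to_roi: pd.Series  # sample_id -> cortical ROI name
    unmatched_rois: list[str]


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Unweighted mean over probes per gene; sample (column) order preserved."""
    unmapped = probe_matrix.index.difference(probe_map.index)
    if len(unmapped):
        raise ValueError(f"unmapped probes: {sorted(map(str, unmapped))[:10]}")
    genes = probe_map.loc[probe_matrix.index]
    out = probe_matrix.groupby(genes.to_numpy(), sort=True).mean()
    out.index.name = "gene"
    return out


def match_regions(samples: pd.DataFrame, atlas: pd.DataFrame, radius: float = 20.0,
                  mode: str = "nearest_roi") -> RegionAssignment:
    """Match donor samples and cortical ROI centroids by Euclidean distance.

    ``nearest_roi`` (default): every sample is assigned to its nearest cortical
    centroid within ``radius``, so each ROI receives a (possibly empty) sample
    set.  ``closest_sample``: each ROI takes only its single nearest sample —
    the strict one-to-one reading of centroid matching.  Exact distance ties
    break to the lowest sample_id / roi_id.
    """
    if samples.empty:
        raise ValueError("empty sample set")
    cort = atlas[atlas["node_class"] == "cortical"].sort_values("roi_id")
    roi_names = cort["name"].to_numpy()
    cent = cort[["x", "y", "z"]].to_numpy(dtype=float)
    # stable lowest-sample_id tie-break via lexicographic sample order
    samples = samples.sort_index(kind="mergesort")
    coords = samples[["x", "y", "z"]].to_numpy(dtype=float)
    dist = np.linalg.norm(coords[:, None, :] - cent[None, :, :], axis=2)

    if mode == "nearest_roi":
        nearest = dist.argmin(axis=1)  # argmin returns the first (lowest roi_id) on ties
        within = dist[np.arange(len(samples)), nearest] <= radius
        assign = pd.Series(roi_names[nearest], index=samples.index)[within]
        matched = set(assign)
        unmatched = [r for r in roi_names if r not in matched]
        return RegionAssignment(sample_to_roi=assign, unmatched_rois=unmatched)
    if mode == "closest_sample":
        nearest = dist.argmin(axis=0)  # first (lowest sample_id) on ties
        within = dist[nearest, np.arange(len(roi_names))] <= radius
        pairs = [(samples.index[s], roi_names[r])
                 for r, s in enumerate(nearest) if within[r]]
        assign = pd.Series({s: r for s, r in pairs})
        unmatched = [r for i, r in enumerate(roi_names) if not within[i]]
        return RegionAssignment(sample_to_roi=assign, unmatched_rois=unmatched)
    raise ValueError(f"unknown mode {mode!r}")


def regional_expression(donors: list[DonorExpression], probe_map: pd.Series,
                        assignments: dict[str, RegionAssignment]) -> ExpressionMatrix:
    """Two-stage mean: within-donor per ROI, then across donors having the ROI.

    ROIs with zero samples in every donor are dropped with a warning.
    """
    if not donors:
        raise ValueError("at least one donor is required")
    per_donor: list[pd.DataFrame] = []
    for donor in donors:
        gene_by_sample = collapse_probes(donor.probes, probe_map)
        roi_of = assignments[donor.donor_id].sample_to_roi
        use = gene_by_sample.loc[:, gene_by_sample.columns.intersection(roi_of.index)]
        grouped = use.T.groupby(roi_of.loc[use.columns].to_numpy()).mean().T
        per_donor.append(grouped)
    stacked = pd.concat(per_donor, axis=1, keys=[d.donor_id for d in donors])
    across = stacked.T.groupby(level=1).mean().T  # mean over donors having each ROI
    never_matched = set.intersection(
        *(set(assignments[d.donor_id].unmatched_rois) for d in donors))
    if never_matched:
        warnings.warn(f"ROIs with no samples in any donor dropped: {sorted(never_matched)}")
    return ExpressionMatrix(values=across, provenance=[d.donor_id for d in donors])


def qc_filter_rois(m: ExpressionMatrix, z_threshold: float = 2.0,
                   mode: str = "or") -> ExpressionMatrix:
    """Single-pass exclusion of outlier ROIs.

    Two per-ROI statistics are computed across genes — the mean and the range
    (max - min) — and an ROI is excluded when a statistic exceeds the
    cross-ROI mean + ``z_threshold`` * sd of that statistic.  ``mode`` selects
    which statistics can trigger exclusion: "or" (either, default), "mean" or
    "range".
    """
    if m.values.shape[1] < 3:
        raise ValueError("qc_filter_rois requires at least 3 ROIs")
    if mode not in ("or", "mean", "range"):
        raise ValueError("mode must be 'or', 'mean' or 'range'")
    stats_ = {
        "mean": m.values.mean(axis=0),
        "range": m.values.max(axis=0) - m.values.min(axis=0),
    }
    flags = pd.Series(False, index=m.values.columns)
    for name, stat in stats_.items():
        if mode != "or" and name != mode:
            continue
        sd = stat.std(ddof=1)
        if sd == 0 or not np.isfinite(z_threshold):
            continue
        flags |= stat > stat.mean() + z_threshold * sd
    excluded = list(m.values.columns[flags])
    if len(excluded) == m.values.shape[1]:
        raise ValueError("QC excluded every ROI")
    return ExpressionMatrix(values=m.values.drop(columns=excluded),
                            excluded_rois=list(m.excluded_rois) + excluded,
                            provenance=list(m.provenance))


def build_expression_matrix(donors: list[DonorExpression], probe_map: pd.Series,
                            atlas: pd.DataFrame, radius: float = 20.0,
                            match_mode: str = "nearest_roi", qc: bool = True,
                            z_threshold: float = 2.0, qc_mode: str = "or") -> ExpressionMatrix:
    """Collapse probes, match samples to ROIs, average, and (optionally) QC."""
    assignments = {d.donor_id: match_regions(d.samples, atlas, radius, match_mode)
                   for d in donors}
    m = regional_expression(donors, probe_map, assignments)
    if qc:
        m = qc_filter_rois(m, z_threshold=z_threshold, mode=qc_mode)
    return m


def donor_resamples(donors: list[DonorExpression], probe_map: pd.Series,
                    atlas: pd.DataFrame, mode: str = "leave_one_out", k: int = 3,
                    n_subsets: int = 8, seed: int = 0,
                    **build_kwargs) -> list[ExpressionMatrix]:
    """Expression matrices over donor subsets for robustness analyses.

    ``leave_one_out`` yields one matrix per left-out donor; ``choose_k``
    yields ``n_subsets`` distinct donor subsets of size k, sampled without
    replacement from the C(n, k) possibilities.
    """
    ids = [d.donor_id for d in donors]
    if mode == "leave_one_out":
        if len(donors) < 2:
            raise ValueError("leave_one_out requires at least 2 donors")
        subsets = [[d for d in donors if d.donor_id != left_out] for left_out in ids]
    elif mode == "choose_k":
        if not (0 < k < len(donors)):
            raise ValueError("choose_k requires 0 < k < n_donors")
        total = comb(len(donors), k)
        if n_subsets > total:
            raise ValueError(f"n_subsets={n_subsets} exceeds C({len(donors)},{k})={total}")
        all_combos = list(itertools.combinations(range(len(donors)), k))
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(all_combos), size=n_subsets, replace=False)
        subsets = [[donors[i] for i in all_combos[c]] for c in sorted(chosen)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [build_expression_matrix(sub, probe_map, atlas, **build_kwargs) for sub in subsets]
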