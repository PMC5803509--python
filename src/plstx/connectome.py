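"""Connection-class atrophy scoring of structural connectomes.

A structural connectome is a symmetric, nonnegative, zero-diagonal weighted
adjacency matrix over an atlas of cortical and striatal nodes.  Every
undirected edge falls into exactly one connection class:

* ``corticostriatal``  — cortex to caudate/putamen,
* ``interhemispheric`` — cortex to cortex across hemispheres,
* ``intrahemispheric`` — cortex to cortex within a hemisphere,
* ``striatostriatal``  — striatum to striatum (excluded from all analyses).

Per cortical ROI, connectivity within each class is summarised (sum of
incident masked edge weights; corticostriatal kept per striatal target), and
patient profiles are normalised against controls as z-scores with the sign
flipped so that *loss* is positive.  The same normalisation applied to
per-subject longitudinal slopes yields rate-of-atrophy scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EDGE_CLASSES = ("corticostriatal", "interhemispheric", "intrahemispheric", "striatostriatal")
ANALYSIS_CLASSES = ("corticostriatal", "interhemispheric", "intrahemispheric")


@dataclass
class Connectome:
    """One subject x timepoint structural network over the atlas nodes."""

    subject_id: str
    group: str  # "patient" | "control"
    timepoint: float  # months
    weights: pd.DataFrame  # symmetric ROI x ROI, nonnegative, zero diagonal

    def __post_init__(self) -> None:
        w = self.weights
        if list(w.index) != list(w.columns):
            raise ValueError("weights must have identical row and column labels")
        arr = w.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T):
            raise ValueError("weights must be symmetric")
        if np.any(arr < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(arr) != 0):
            raise ValueError("weights must have a zero diagonal")
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")


def classify_edge(roi_a: pd.Series, roi_b: pd.Series) -> str:
    """Connection class of the undirected edge between two atlas rows."""
    for roi in (roi_a, roi_b):
        if roi.get("node_class") not in ("cortical", "striatal"):
            raise KeyError(f"unknown node_class for ROI {roi.get('name')!r}")
    a_cort = roi_a["node_class"] == "cortical"
    b_cort = roi_b["node_class"] == "cortical"
    if a_cort and b_cort:
        return "intrahemispheric" if roi_a["hemisphere"] == roi_b["hemisphere"] else "interhemispheric"
    if a_cort or b_cort:
        return "corticostriatal"
    return "striatostriatal"


def edge_class_matrix(atlas: pd.DataFrame) -> pd.DataFrame:
    """ROI x ROI matrix of connection-class labels (diagonal included)."""
    cortical = (atlas["node_class"] == "cortical").to_numpy()
    hemi = atlas["hemisphere"].to_numpy()
    both_cort = np.outer(cortical, cortical)
    same_hemi = hemi[:, None] == hemi[None, :]
    out = np.where(both_cort & same_hemi, "intrahemispheric",
                   np.where(both_cort, "interhemispheric",
                            np.where(np.outer(~cortical, ~cortical), "striatostriatal",
                                     "corticostriatal")))
    names = atlas["name"].tolist()
    return pd.DataFrame(out, index=names, columns=names)


def consensus_mask(controls: list[Connectome], threshold: float) -> pd.DataFrame:
    """Edges retained iff nonzero in >= ``threshold`` fraction of baseline controls.

    The mask is defined from control anatomy at the earliest timepoint present
    among the given control connectomes.
    """
    if not controls:
        raise ValueError("consensus_mask requires at least one control connectome")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    baseline = min(c.timepoint for c in controls)
    base = [c for c in controls if c.timepoint == baseline]
    stack = np.stack([c.weights.to_numpy(dtype=float) > 0 for c in base])
    frac = stack.mean(axis=0)
    mask = frac >= threshold
    ref = base[0].weights
    return pd.DataFrame(mask, index=ref.index, columns=ref.columns)


def profile_columns(atlas: pd.DataFrame) -> list[str]:
    striatal = atlas.loc[atlas["node_class"] == "striatal", "name"].tolist()
    return [f"corticostriatal:{s}" for s in striatal] + ["interhemispheric", "intrahemispheric"]


def roi_class_connectivity(conn: Connectome, atlas: pd.DataFrame,
                           mask: pd.DataFrame | None = None,
                           agg: str = "sum") -> pd.DataFrame:
    """Per-cortical-ROI connection-class connectivity profile.

    Corticostriatal connectivity is kept per striatal target (one column per
    caudate/putamen node); inter- and intrahemispheric connectivity aggregate
    the masked cortico-cortical edge weights incident to each cortical ROI.
    """
    names = atlas["name"].tolist()
    if list(conn.weights.index) != names:
        raise ValueError("connectome node order does not match atlas")
    w = conn.weights.to_numpy(dtype=float).copy()
    if mask is not None:
        if list(mask.index) != names:
            raise ValueError("mask node order does not match atlas")
        w = w * mask.to_numpy(dtype=bool)
    if agg not in ("sum", "mean"):
        raise ValueError("agg must be 'sum' or 'mean'")

    classes = edge_class_matrix(atlas).to_numpy()
    cortical_idx = np.flatnonzero((atlas["node_class"] == "cortical").to_numpy())
    striatal_idx = np.flatnonzero((atlas["node_class"] == "striatal").to_numpy())
    cortical_names = atlas["name"].to_numpy()[cortical_idx]

    cols: dict[str, np.ndarray] = {}
    for s in striatal_idx:
        cols[f"corticostriatal:{atlas['name'].iloc[s]}"] = w[cortical_idx, s]
    for cls in ("interhemispheric", "intrahemispheric"):
        sel = classes[np.ix_(cortical_idx, range(len(names)))] == cls
        vals = np.where(sel, w[cortical_idx, :], 0.0)
        if agg == "sum":
            cols[cls] = vals.sum(axis=1)
        else:
            counts = np.maximum(sel.sum(axis=1), 1)
            cols[cls] = vals.sum(axis=1) / counts
    return pd.DataFrame(cols, index=pd.Index(cortical_names, name="roi"))


@dataclass
class AtrophyMatrix:
    """Control-referenced atrophy (or rate-of-atrophy) scores; positive = loss."""

    values: pd.DataFrame  # cortical ROI x response column, NaN where excluded
    analysis_tag: str = "all"
    mode: str = "cross_sectional"  # or "longitudinal"
    per_patient: dict[str, pd.DataFrame] = field(default_factory=dict)
    excluded_cells: list[tuple[str, str]] = field(default_factory=list)


def atrophy_scores(patient_profiles: dict[str, pd.DataFrame],
                   control_profiles: dict[str, pd.DataFrame],
                   mode: str = "cross_sectional") -> AtrophyMatrix:
    """Control-referenced z-scores of patient profiles, sign-flipped to loss.

    atrophy = -(x_patient - mean_controls) / sd_controls, per ROI x column;
    group matrix = mean over patients.  Cells with zero control variance are
    excluded (NaN) and reported.
    """
    if len(control_profiles) < 2:
        raise ValueError("atrophy_scores requires at least 2 control profiles")
    if not patient_profiles:
        raise ValueError("atrophy_scores requires at least 1 patient profile")
    ref = next(iter(control_profiles.values()))
    for p in list(patient_profiles.values()) + list(control_profiles.values()):
        if p.shape != ref.shape or list(p.index) != list(ref.index) or list(p.columns) != list(ref.columns):
            raise ValueError("all profiles must share the same ROI x column layout")

    ctrl = np.stack([p.to_numpy(dtype=float) for p in control_profiles.values()])
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.all():
        raise ValueError("all control cells have zero variance")
    sd_safe = np.where(bad, np.nan, sd)

    per_patient: dict[str, pd.DataFrame] = {}
    for sid, prof in patient_profiles.items():
        z = (prof.to_numpy(dtype=float) - mu) / sd_safe
        per_patient[sid] = pd.DataFrame(-z, index=ref.index, columns=ref.columns)
    group = pd.concat(per_patient.values()).groupby(level=0, sort=False).mean()
    group = group.loc[ref.index]
    excluded = [(str(ref.index[i]), str(ref.columns[j])) for i, j in zip(*np.nonzero(bad))]
    return AtrophyMatrix(values=group, mode=mode, per_patient=per_patient, excluded_cells=excluded)


def rate_of_change(subject_profiles: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """OLS slope across timepoints for each ROI x column, in units per year.

    ``subject_profiles`` maps timepoint (months) to that visit's profile.
    """
    if len(subject_profiles) < 2:
        raise ValueError("rate_of_change requires at least 2 timepoints")
    times = sorted(subject_profiles)
    ref = subject_profiles[times[0]]
    stack = np.stack([subject_profiles[t].to_numpy(dtype=float) for t in times])
    t_years = np.asarray(times, dtype=float) / 12.0
    flat = stack.reshape(len(times), -1)
    slope = np.polyfit(t_years, flat, 1)[0].reshape(ref.shape)
    return pd.DataFrame(slope, index=ref.index, columns=ref.columns)


def group_profiles(connectomes: list[Connectome], atlas: pd.DataFrame,
                   mask: pd.DataFrame | None = None, agg: str = "sum",
                   timepoint: float | None = None) -> dict[str, dict[str, pd.DataFrame]]:
    """Profiles keyed by group then subject, at one timepoint (default earliest)."""
    if timepoint is None:
        timepoint = min(c.timepoint for c in connectomes)
    out: dict[str, dict[str, pd.DataFrame]] = {"patient": {}, "control": {}}
    for c in connectomes:
        if c.timepoint == timepoint:
            out[c.group][c.subject_id] = roi_class_connectivity(c, atlas, mask, agg)
    return out


def slope_profiles(connectomes: list[Connectome], atlas: pd.DataFrame,
                   mask: pd.DataFrame | None = None, agg: str = "sum",
                   require_all_timepoints: bool = True) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-subject rate-of-change profiles, keyed by group then subject.

    Subjects lacking any study timepoint are dropped (with a warning) when
    ``require_all_timepoints`` is set, mirroring longitudinal designs that
    keep only subjects imaged at every visit.
    """
    all_times = sorted({c.timepoint for c in connectomes})
    by_subject: dict[str, dict[float, Connectome]] = {}
    for c in connectomes:
        by_subject.setdefault(c.subject_id, {})[c.timepoint] = c
    out: dict[str, dict[str, pd.DataFrame]] = {"patient": {}, "control": {}}
    dropped = []
    for sid, visits in by_subject.items():
        if require_all_timepoints and set(visits) != set(all_times):
            dropped.append(sid)
            continue
        if len(visits) < 2:
            dropped.append(sid)
            continue
        profiles = {t: roi_class_connectivity(c, atlas, mask, agg) for t, c in visits.items()}
        group = next(iter(visits.values())).group
        out[group][sid] = rate_of_change(profiles)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} subjects without all timepoints: {sorted(dropped)[:5]}...")
    return out
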