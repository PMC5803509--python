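"""Config-driven orchestration of the full analysis.

A run executes, for each requested connection class (corticostriatal,
interhemispheric, intrahemispheric) and mode (cross-sectional atrophy /
longitudinal rate of atrophy): connectome atrophy scoring -> regional
expression mapping -> PLS -> gene ranking -> ranked gene-set enrichment,
writing self-contained report directories whose tables are re-derivable from
the config alone.  Striatostriatal edges never enter any analysis class.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict
from scipy import stats

from . import io as pio
from .connectome import (ANALYSIS_CLASSES, AtrophyMatrix, Connectome, atrophy_scores,
                         consensus_mask, group_profiles, slope_profiles)
from .enrichment import go_enrichment
from .expression import ExpressionMatrix, build_expression_matrix
from .pls import ExpressionAtrophyPLS, PLSResults
from .synth import DonorExpression, ExpressionBundle, GeneSetCollection, SyntheticDataset

log = logging.getLogger("plstx")


# ---------------------------------------------------------------------------
# dataset serialization

def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a synthetic dataset in the pipeline's on-disk layout."""
    out = Path(out_dir)
    (out / "connectomes").mkdir(parents=True, exist_ok=True)
    (out / "donors").mkdir(exist_ok=True)
    (out / "lists").mkdir(exist_ok=True)
    pio.write_atlas(ds.atlas, out / "atlas.tsv")
    manifest = []
    for c in ds.connectomes:
        fname = f"{c.subject_id}_t{int(c.timepoint):03d}.tsv"
        pio.write_adjacency(c.weights, out / "connectomes" / fname)
        manifest.append((fname, c.subject_id, c.group, c.timepoint))
    pd.DataFrame(manifest, columns=["file", "subject_id", "group", "timepoint"]).to_csv(
        out / "connectomes" / "manifest.tsv", sep="\t", index=False)
    for donor in ds.expression.donors:
        table = donor.samples.join(donor.probes.T)
        table.to_csv(out / "donors" / f"{donor.donor_id}_samples.tsv", sep="\t",
                     float_format=pio.FLOAT_FMT)
    ds.expression.probe_map.rename("gene").to_csv(out / "donors" / "probe_map.tsv", sep="\t")
    ds.gene_sets.to_gmt(out / "gene_sets.gmt")
    pio.write_foldchange(ds.foldchange, out / "foldchange.tsv")
    for name, genes in ds.gene_lists.items():
        pio.write_gene_list(genes, out / "lists" / f"{name}.tsv")
    truth = {
        "noise_sd": ds.truth.noise_sd,
        "class_to_profile": ds.truth.class_to_profile,
        "planted_set_profiles": ds.truth.planted_set_profiles,
        "profiles": {name: {"roi_gradient": p.roi_gradient, "gene_loadings": p.gene_loadings}
                     for name, p in ds.truth.profiles.items()},
    }
    pio.write_json(truth, out / "ground_truth.json")
    return out


def read_connectomes(conn_dir: str | Path) -> list[Connectome]:
    conn_dir = Path(conn_dir)
    manifest = pd.read_csv(conn_dir / "manifest.tsv", sep="\t")
    out = []
    for row in manifest.itertuples():
        out.append(Connectome(subject_id=str(row.subject_id), group=str(row.group),
                              timepoint=float(row.timepoint),
                              weights=pio.read_adjacency(conn_dir / row.file)))
    return out


def read_donors(donor_dir: str | Path) -> ExpressionBundle:
    donor_dir = Path(donor_dir)
    probe_map = pd.read_csv(donor_dir / "probe_map.tsv", sep="\t", index_col=0)["gene"]
    donors = []
    for path in sorted(donor_dir.glob("*_samples.tsv")):
        table = pd.read_csv(path, sep="\t", index_col=0)
        samples = table[["x", "y", "z"]]
        probes = table.drop(columns=["x", "y", "z"]).T
        sample_ids = samples.index.astype(str)
        src = [sid.split("|")[1] if sid.count("|") >= 2 else "" for sid in sample_ids]
        donors.append(DonorExpression(donor_id=path.name.replace("_samples.tsv", ""),
                                      samples=samples, probes=probes,
                                      true_roi=pd.Series(src, index=samples.index)))
    return ExpressionBundle(donors=donors, probe_map=probe_map,
                            genes=sorted(probe_map.unique()))


# ---------------------------------------------------------------------------
# config

class AnalysisConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    atlas: str
    connectome_dir: str
    donor_dir: str
    gene_sets: str
    foldchange: str | None = None
    gene_lists: dict[str, str] = {}
    out_dir: str = "plstx_run"

    analyses: list[str] = list(ANALYSIS_CLASSES)
    modes: list[str] = ["cross_sectional", "longitudinal"]
    cross_sectional_timepoint: str = "last"  # "first" | "last"
    consensus_threshold: float = 0.75
    agg: str = "sum"
    n_components: int = 2
    n_perm: int = 200
    seed: int = 0
    match_radius: float = 20.0
    match_mode: str = "nearest_roi"
    qc: bool = True
    qc_z: float = 2.0
    qc_mode: str = "or"
    enrichment_max_term_size: int = 1000
    enrichment_min_term_size: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


ANALYSIS_COLUMNS = {
    "corticostriatal": lambda cols: [c for c in cols if c.startswith("corticostriatal:")],
    "interhemispheric": lambda cols: ["interhemispheric"],
    "intrahemispheric": lambda cols: ["intrahemispheric"],
}


@dataclass
class AnalysisReport:
    config: AnalysisConfig
    out_dir: Path
    results: dict[tuple[str, str], PLSResults] = field(default_factory=dict)
    enrichment: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    atrophy: dict[str, AtrophyMatrix] = field(default_factory=dict)
    expression: ExpressionMatrix | None = None
    provenance: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                result = fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            log.info("stage %s done in %.2fs", name, time.time() - t0)
            return result
        return wrapped
    return deco


def _input_paths(config: AnalysisConfig) -> list[Path]:
    paths = [Path(config.atlas), Path(config.connectome_dir), Path(config.donor_dir),
             Path(config.gene_sets)]
    if config.foldchange:
        paths.append(Path(config.foldchange))
    paths += [Path(p) for p in config.gene_lists.values()]
    return paths


def _provenance(config: AnalysisConfig) -> dict:
    h = hashlib.sha256()
    h.update(json.dumps(config.model_dump(), sort_keys=True).encode())
    for path in sorted(map(str, _input_paths(config))):
        p = Path(path)
        files = sorted(p.rglob("*")) if p.is_dir() else [p]
        for f in files:
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    from . import __version__
    return {"config": config.model_dump(), "hash": h.hexdigest(),
            "seed": config.seed, "version": __version__}


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute every requested analysis tag x mode; deterministic given config."""
    for p in _input_paths(config):
        if not p.exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport(config=config, out_dir=out, provenance=_provenance(config))

    atlas = _stage("read_atlas")(pio.read_atlas)(config.atlas)
    connectomes = _stage("read_connectomes")(read_connectomes)(config.connectome_dir)
    bundle = _stage("read_donors")(read_donors)(config.donor_dir)
    sets = GeneSetCollection.from_gmt(config.gene_sets)

    expr = _stage("map_expression")(build_expression_matrix)(
        bundle.donors, bundle.probe_map, atlas, radius=config.match_radius,
        match_mode=config.match_mode, qc=config.qc, z_threshold=config.qc_z,
        qc_mode=config.qc_mode)
    report.expression = expr
    pio.write_matrix(expr.values, out / "expression_matrix.tsv", index_label="gene")
    pio.write_json({"excluded_rois": expr.excluded_rois, "donors": expr.provenance},
                   out / "expression_qc.json")

    controls = [c for c in connectomes if c.group == "control"]
    mask = _stage("consensus_mask")(consensus_mask)(controls, config.consensus_threshold)

    @_stage("atrophy")
    def _atrophy(mode: str) -> AtrophyMatrix:
        if mode == "cross_sectional":
            times = sorted({c.timepoint for c in connectomes})
            tp = times[-1] if config.cross_sectional_timepoint == "last" else times[0]
            prof = group_profiles(connectomes, atlas, mask, config.agg, timepoint=tp)
            return atrophy_scores(prof["patient"], prof["control"], mode=mode)
        if mode == "longitudinal":
            prof = slope_profiles(connectomes, atlas, mask, config.agg)
            return atrophy_scores(prof["patient"], prof["control"], mode=mode)
        raise ValueError(f"unknown mode {mode!r}")

    for mode in config.modes:
        atrophy = _atrophy(mode)
        report.atrophy[mode] = atrophy
        for tag in config.analyses:
            if tag not in ANALYSIS_CLASSES:
                raise ValueError(f"unknown analysis tag {tag!r}")
            cols = ANALYSIS_COLUMNS[tag](atrophy.values.columns)
            y = atrophy.values[cols]
            res = _stage(f"pls[{tag},{mode}]")(
                lambda: ExpressionAtrophyPLS(expr, AtrophyMatrix(values=y, analysis_tag=tag,
                                                                mode=mode),
                                             n_components=config.n_components).fit())()
            report.results[(tag, mode)] = res
            ranked = res.gene_ranking(1)
            enr = _stage(f"enrich[{tag},{mode}]")(go_enrichment)(
                ranked, sets, max_term_size=config.enrichment_max_term_size,
                min_term_size=config.enrichment_min_term_size)
            report.enrichment[(tag, mode)] = enr

            sub = out / f"{tag}_{mode}"
            sub.mkdir(exist_ok=True)
            pio.write_matrix(y, sub / "atrophy.tsv", index_label="roi")
            pio.write_matrix(res.variance_explained(), sub / "variance.tsv")
            pio.write_matrix(res.gene_weights, sub / "gene_weights.tsv", index_label="gene")
            pio.write_matrix(res.roi_scores, sub / "roi_scores.tsv", index_label="roi")
            ranked.to_csv(sub / "ranked_genes.tsv", sep="\t", float_format=pio.FLOAT_FMT)
            enr.to_csv(sub / "enrichment.tsv", sep="\t", index=False,
                       float_format=pio.FLOAT_FMT)

    pio.write_json(report.provenance, out / "provenance.json")
    return report


def roi_weight_dissociation(res_a: PLSResults, res_b: PLSResults,
                            component: int = 1) -> tuple[pd.DataFrame, float]:
    """Paired ROI-score table for two analyses plus their Spearman correlation."""
    col = f"PLS{component}"
    a = res_a.roi_scores[col]
    b = res_b.roi_scores[col]
    if list(a.index) != list(b.index):
        shared = a.index.intersection(b.index)
        if len(shared) != len(a.index) or len(shared) != len(b.index):
            raise ValueError("analyses ran on different ROI sets")
        a, b = a.loc[shared], b.loc[shared]
    table = pd.DataFrame({
        "score_a": a, "score_b": b,
        "rank_a": a.rank(ascending=False).astype(int),
        "rank_b": b.rank(ascending=False).astype(int),
    })
    rho = float(stats.spearmanr(a, b).statistic)
    return table, rho
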