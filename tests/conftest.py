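import numpy as np
import pandas as pd
import pytest

import plstx as px


def fit_corticostriatal(ds):
    """Corticostriatal cross-sectional PLS fit on a synthetic dataset."""
    from plstx.connectome import atrophy_scores, consensus_mask, group_profiles
    from plstx.expression import build_expression_matrix

    controls = [c for c in ds.connectomes if c.group == "control"]
    mask = consensus_mask(controls, 0.75)
    last = max(c.timepoint for c in ds.connectomes)
    prof = group_profiles(ds.connectomes, ds.atlas, mask, timepoint=last)
    atrophy = atrophy_scores(prof["patient"], prof["control"])
    expr = build_expression_matrix(ds.expression.donors, ds.expression.probe_map, ds.atlas)
    cs = [c for c in atrophy.values.columns if c.startswith("corticostriatal:")]
    res = px.ExpressionAtrophyPLS(expr, atrophy.values[cs], n_components=2).fit()
    return atrophy, expr, res


@pytest.fixture(scope="session")
def small_dataset():
    """Scaled-down planted dataset shared across test modules (34 cortical ROIs)."""
    cohort = px.CohortSpec(n_patients=12, n_controls=14, seed=11)
    return px.generate_dataset(seed=7, n_cortical_per_hemisphere=17, n_genes=600,
                               n_donors=3, cohort=cohort)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    ds = small_dataset
    atrophy, expr, res = fit_corticostriatal(ds)
    return ds, atrophy, expr, res


@pytest.fixture(scope="session")
def strong_fit():
    """Low-noise, well-powered planted dataset: unambiguous signal regime."""
    cohort = px.CohortSpec(n_patients=20, n_controls=20, seed=5)
    ds = px.generate_dataset(seed=13, n_cortical_per_hemisphere=17, n_genes=600,
                             n_donors=6, noise_sd=0.1, cohort=cohort)
    atrophy, expr, res = fit_corticostriatal(ds)
    return ds, atrophy, expr, res


@pytest.fixture
def toy_atlas():
    """2 cortical (L/R) + 2 striatal nodes, fixed centroids."""
    return pd.DataFrame({
        "roi_id": [0, 1, 2, 3],
        "name": ["ctx-lh-01", "ctx-rh-01", "caudate-lh", "putamen-rh"],
        "hemisphere": ["L", "R", "L", "R"],
        "node_class": ["cortical", "cortical", "striatal", "striatal"],
        "x": [-40.0, 40.0, -14.0, 25.0],
        "y": [0.0, 0.0, 9.0, -1.0],
        "z": [30.0, 30.0, 12.0, 2.0],
    })


def complete_connectome(atlas, weight=1.0, subject="s0", group="control", timepoint=0.0):
    n = len(atlas)
    w = np.full((n, n), float(weight))
    np.fill_diagonal(w, 0.0)
    names = atlas["name"].tolist()
    return px.Connectome(subject_id=subject, group=group, timepoint=timepoint,
                         weights=pd.DataFrame(w, index=names, columns=names))
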