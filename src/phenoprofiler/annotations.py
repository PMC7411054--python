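"""Auxiliary calling rules: expression thresholds, core-fitness genes, and
activity-association tests.

The bespoke content here is the calling rules — the statistical tests
themselves are thin wrappers around scipy/sklearn routines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

Z_95 = float(stats.norm.ppf(0.95))  # 1.6449: 95th percentile of a unit normal


@dataclass
class ExpressionCallSet:
    """Per-gene expressed/absent calls with per-replicate thresholds."""

    expressed: pd.Series  # gene -> bool
    thresholds: Dict[str, float]  # replicate -> log2 threshold
    mixture_params: Dict[str, dict] = field(default_factory=dict)


def _fit_two_component_mixture(values: np.ndarray, seed: int = 0) -> GaussianMixture:
    """2-component Gaussian mixture with deterministic quantile-based init.

    Component means initialize at the 25th/75th percentiles; on
    non-convergence a k-means-initialized fit is attempted before giving up.
    """
    x = values[np.isfinite(values)].reshape(-1, 1)
    init_means = np.percentile(x, [25, 75]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2, means_init=init_means, random_state=seed, max_iter=500
    ).fit(x)
    if not gm.converged_:
        gm = GaussianMixture(
            n_components=2, init_params="kmeans", random_state=seed, max_iter=500
        ).fit(x)
        if not gm.converged_:
            raise RuntimeError("two-component Gaussian mixture did not converge")
    return gm


def expression_threshold(values: np.ndarray, seed: int = 0) -> tuple[float, dict]:
    """95th percentile of the lower-mean mixture component.

    The log2 intensity distribution of a replicate is modelled as a mixture
    of an unexpressed (lower) and an expressed (upper) mode; the threshold is
    ``mu_low + 1.6449 * sigma_low``.
    """
    gm = _fit_two_component_mixture(values, seed=seed)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    low = int(np.argmin(means))  # "first mode" = component with the lower mean
    params = {
        "means": means.tolist(),
        "sds": sds.tolist(),
        "weights": gm.weights_.ravel().tolist(),
        "lower_component": low,
    }
    return float(means[low] + Z_95 * sds[low]), params


def call_expressed(
    log2_intensities: pd.DataFrame,
    replicate_columns: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> ExpressionCallSet:
    """Call genes expressed from a probe-set-level log2 intensity table.

    ``log2_intensities`` has columns ``gene``, ``probe_set`` and one column
    per replicate. Per replicate, a two-component Gaussian mixture is fitted
    to the probe-set intensity distribution and the threshold set at the
    95th percentile of the lower-mean component. A gene is expressed only if
    *every* probe set of the gene is above the threshold in *every*
    replicate.
    """
    if "gene" not in log2_intensities.columns:
        raise ValueError("expression table needs a 'gene' column")
    reps = list(replicate_columns) if replicate_columns is not None else [
        c for c in log2_intensities.columns if c not in ("gene", "probe_set")
    ]
    if not reps:
        raise ValueError("expression table has no replicate columns")
    thresholds: Dict[str, float] = {}
    params: Dict[str, dict] = {}
    above = pd.DataFrame(index=log2_intensities.index)
    for rep in reps:
        thr, p = expression_threshold(log2_intensities[rep].to_numpy(dtype=float), seed=seed)
        thresholds[rep] = thr
        params[rep] = p
        above[rep] = log2_intensities[rep] > thr
    per_row = above.all(axis=1)
    expressed = per_row.groupby(log2_intensities["gene"]).all()
    expressed.name = "expressed"
    return ExpressionCallSet(expressed=expressed, thresholds=thresholds, mixture_params=params)


def call_core_fitness(defect_matrix: pd.DataFrame, min_fraction: float = 2.0 / 3.0) -> pd.DataFrame:
    """Core-fitness calls from a binary genes x cell-lines defect matrix.

    A gene is core-fitness when it causes a fitness defect in at least two
    thirds of the tested cell lines (6 or more of 9 in the reference
    CRISPR panels).
    """
    vals = defect_matrix.to_numpy()
    if not np.isin(vals[~pd.isna(vals)], [0, 1, True, False]).all():
        raise ValueError("defect matrix must be binary")
    n = defect_matrix.shape[1]
    need = math.ceil(min_fraction * n)
    counts = defect_matrix.fillna(0).astype(int).sum(axis=1)
    return pd.DataFrame(
        {"defect_count": counts, "n_tested": n, "core_fitness": counts >= need}
    )


def activity_association(
    compound_activity: pd.Series,
    compound_targets: pd.DataFrame,
    expressed: pd.Series,
    core_fitness: Optional[pd.Series] = None,
    lowest_active_concentration: Optional[pd.Series] = None,
) -> dict:
    """Association tests between phenotypic activity and target biology.

    Parameters
    ----------
    compound_activity : compound_id -> active (bool).
    compound_targets : long table with columns compound_id, gene.
    expressed : gene -> expressed flag (one cell type).
    core_fitness : gene -> core-fitness flag, optional.
    lowest_active_concentration : compound_id -> lowest active concentration
        (µM) of active compounds, optional.

    Returns a report dict with, where computable: Fisher's exact test of
    active vs target-expressed, a Wilcoxon rank-sum test of the lowest
    active concentration between expressed and non-expressed target groups,
    and Fisher's exact test of active vs core-fitness-target among
    compounds with an expressed target. A compound counts as
    "target expressed" when any of its annotated targets is expressed.
    """
    targets = compound_targets.dropna(subset=["gene"])
    has_target = targets.groupby("compound_id")["gene"].agg(list)
    report: dict = {"n_compounds_with_target": int(len(has_target))}
    if len(has_target) == 0:
        report["note"] = "no compounds with target annotations"
        return report

    expr_lookup = expressed.to_dict()
    comp_expr = has_target.map(lambda gs: any(expr_lookup.get(g, False) for g in gs))
    comp_act = compound_activity.reindex(comp_expr.index).fillna(False).astype(bool)

    table = pd.crosstab(comp_act, comp_expr).reindex(
        index=[True, False], columns=[True, False], fill_value=0
    )
    if (table.to_numpy().sum(axis=0) > 0).all() and (table.to_numpy().sum(axis=1) > 0).all():
        odds, p = stats.fisher_exact(table.to_numpy())
        report["active_vs_expressed"] = {
            "table": table.to_numpy().tolist(),
            "odds_ratio": float(odds),
            "p_value": float(p),
        }
    else:
        report["active_vs_expressed"] = {"note": "empty margin; test skipped"}

    if lowest_active_concentration is not None:
        lac = lowest_active_concentration.reindex(comp_expr.index)
        g_expr = lac[comp_expr & lac.notna()]
        g_not = lac[~comp_expr & lac.notna()]
        if len(g_expr) and len(g_not):
            stat, p = stats.ranksums(g_expr, g_not)
            report["lowest_active_conc_vs_expressed"] = {
                "n_expressed": int(len(g_expr)),
                "n_not_expressed": int(len(g_not)),
                "statistic": float(stat),
                "p_value": float(p),
            }
        else:
            report["lowest_active_conc_vs_expressed"] = {"note": "a group is empty; test skipped"}

    if core_fitness is not None:
        cf_lookup = core_fitness.to_dict()
        comp_core = has_target.map(lambda gs: any(cf_lookup.get(g, False) for g in gs))
        sel = comp_expr  # among compounds with an expressed target
        t2 = pd.crosstab(comp_act[sel], comp_core[sel]).reindex(
            index=[True, False], columns=[True, False], fill_value=0
        )
        if (t2.to_numpy().sum(axis=0) > 0).all() and (t2.to_numpy().sum(axis=1) > 0).all():
            odds, p = stats.fisher_exact(t2.to_numpy())
            report["active_vs_core_fitness"] = {
                "table": t2.to_numpy().tolist(),
                "odds_ratio": float(odds),
                "p_value": float(p),
            }
        else:
            report["active_vs_core_fitness"] = {"note": "empty margin; test skipped"}
    return report


def library_summary(
    annotations: pd.DataFrame, compound_targets: Optional[pd.DataFrame] = None
) -> dict:
    """Composition counts of a compound-annotation table.

    ``annotations`` is long-format with columns compound_id, moa. Returns
    unique-MoA and multi-annotation counts of the kind used to characterize
    reference libraries (single-MoA compounds, MoAs with >= 3 / >= 5
    compounds, target-gene coverage).
    """
    per_comp = annotations.groupby("compound_id")["moa"].nunique()
    per_moa = annotations.groupby("moa")["compound_id"].nunique()
    out = {
        "n_compounds": int(per_comp.size),
        "n_unique_moas": int(per_moa.size),
        "n_single_moa_compounds": int((per_comp == 1).sum()),
        "frac_single_moa": float((per_comp == 1).mean()) if per_comp.size else float("nan"),
        "n_moas_ge3_compounds": int((per_moa >= 3).sum()),
        "n_moas_ge5_compounds": int((per_moa >= 5).sum()),
    }
    if compound_targets is not None:
        t = compound_targets.dropna(subset=["gene"])
        out["n_compounds_with_targets"] = int(t["compound_id"].nunique())
        out["n_unique_targets"] = int(t["gene"].nunique())
    return out
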