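"""MoA distinguishability via nearest-reference AUC-ROC.

Every active treatment serves once as a query; all other active treatments —
except other concentrations of the query's own compound — are ranked by the
Pearson correlation of their treatment-level signatures to the query, and
collapsed to one entry per compound (keeping its best-correlated
concentration). Ranking members of the query's MoA above non-members is
scored as a rank-based AUC-ROC. Per-compound AUCs are aggregated by
maximum-over-concentrations then median-over-compounds within the MoA;
significance comes from permuting the compound-to-annotation-set mapping
among active compounds, with Benjamini-Hochberg FDR control across all
tested (MoA, cell line) pairs. MoAs with an aggregated AUC-ROC of at least
0.9 are called distinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .feature_select import SignatureSpec, _standardize_rows
from .activity import signature_matrix

logger = logging.getLogger(__name__)

DISTINGUISHABLE_AUC = 0.9
MIN_ACTIVE_COMPOUNDS = 3


# ---------------------------------------------------------------------------
# query machinery


@dataclass
class _QueryTable:
    """Per-query collapsed candidate lists, precomputed once per active set.

    For each active treatment: the candidate compounds (every active
    compound except the query's own), each at its best-correlated
    concentration, with the correlation score and its midrank. Candidate
    composition does not depend on the MoA under test, so permutation
    iterations reuse these tables.
    """

    treatment_ids: np.ndarray
    compounds: np.ndarray  # query compound per treatment
    cand_compounds: List[np.ndarray]
    cand_scores: List[np.ndarray]
    cand_ranks: List[np.ndarray]  # midranks of the scores


def _build_query_table(actives: pd.DataFrame, features: Sequence[str]) -> _QueryTable:
    tids = actives["treatment_id"].to_numpy()
    comps = actives["compound_id"].to_numpy()
    Z = _standardize_rows(signature_matrix(actives, features))
    degenerate = np.isnan(Z).all(axis=1)
    if degenerate.any():
        logger.warning(
            "%d active treatments have degenerate (zero-variance) signatures; "
            "they are excluded from rankings",
            int(degenerate.sum()),
        )
    R = np.where(np.isnan(Z), 0.0, Z) @ np.where(np.isnan(Z), 0.0, Z).T
    R[degenerate, :] = np.nan
    R[:, degenerate] = np.nan

    cand_c, cand_s, cand_r = [], [], []
    for q in range(len(tids)):
        mask = (comps != comps[q]) & ~np.isnan(R[q])
        if not mask.any():
            cand_c.append(np.empty(0, dtype=object))
            cand_s.append(np.empty(0))
            cand_r.append(np.empty(0))
            continue
        df = pd.DataFrame({"compound_id": comps[mask], "r": R[q][mask]})
        # collapse: keep each compound's highest-ranked (best-correlated) conc
        best = df.groupby("compound_id", sort=True)["r"].max()
        scores = best.to_numpy()
        cand_c.append(best.index.to_numpy())
        cand_s.append(scores)
        cand_r.append(rankdata(scores))
    return _QueryTable(tids, comps, cand_c, cand_s, cand_r)


def rank_neighbors(
    query_treatment_id: str, actives: pd.DataFrame, features: Sequence[str]
) -> pd.DataFrame:
    """Rank all other active compounds by signature correlation to the query.

    All treatments of the query's own compound are excluded; every other
    active compound appears exactly once, at its best-correlated
    concentration, sorted by descending correlation (ties broken by
    compound id for determinism).
    """
    tids = actives["treatment_id"].to_numpy()
    (qi,) = np.where(tids == query_treatment_id)
    if len(qi) != 1:
        raise KeyError(f"query treatment {query_treatment_id!r} not in active set")
    q = qi[0]
    comps = actives["compound_id"].to_numpy()
    Z = _standardize_rows(signature_matrix(actives, features))
    r = Z @ Z[q]
    mask = (comps != comps[q]) & ~np.isnan(r)
    df = pd.DataFrame(
        {"compound_id": comps[mask], "treatment_id": tids[mask], "r": r[mask]}
    )
    idx = df.groupby("compound_id")["r"].idxmax()
    out = df.loc[idx].sort_values(["r", "compound_id"], ascending=[False, True])
    return out.reset_index(drop=True)


def query_auc(ranked: pd.DataFrame, moa_members: Sequence[str]) -> Optional[float]:
    """AUC-ROC of a ranked candidate list against MoA membership flags.

    Rank-based (Mann-Whitney) AUC with midrank credit for correlation ties.
    Returns None when the list has no positive or no negative.
    """
    members = set(moa_members)
    flags = ranked["compound_id"].isin(members).to_numpy()
    n1 = int(flags.sum())
    n0 = len(flags) - n1
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(ranked["r"].to_numpy())
    return float((ranks[flags].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _auc_from_ranks(ranks: np.ndarray, flags: np.ndarray) -> Optional[float]:
    n1 = int(flags.sum())
    n0 = len(flags) - n1
    if n1 == 0 or n0 == 0:
        return None
    return float((ranks[flags].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _aggregate_moa(
    qt: _QueryTable, members: FrozenSet[str]
) -> Tuple[Optional[float], Dict[str, float]]:
    """Max-over-concentrations then median-over-compounds aggregation."""
    per_compound: Dict[str, float] = {}
    for q in range(len(qt.treatment_ids)):
        c = qt.compounds[q]
        if c not in members:
            continue
        flags = np.fromiter((cc in members for cc in qt.cand_compounds[q]), dtype=bool,
                            count=len(qt.cand_compounds[q]))
        auc = _auc_from_ranks(qt.cand_ranks[q], flags)
        if auc is None:
            continue
        if c not in per_compound or auc > per_compound[c]:
            per_compound[c] = auc
    if not per_compound:
        return None, per_compound
    return float(np.median(list(per_compound.values()))), per_compound


def moa_auc(
    moa: str,
    actives: pd.DataFrame,
    annotations: pd.DataFrame,
    features: Sequence[str],
    cell_line: str = "",
    min_compounds: int = MIN_ACTIVE_COMPOUNDS,
) -> Optional[dict]:
    """Aggregated AUC-ROC of one MoA (no p-value).

    Every active treatment of the MoA's member compounds is used once as a
    query; per compound the maximum AUC over its concentrations is taken,
    and the MoA aggregate is the median of the per-compound maxima. Requires
    at least ``min_compounds`` active member compounds.
    """
    members = frozenset(annotations.loc[annotations["moa"] == moa, "compound_id"])
    active_members = members & set(actives["compound_id"])
    if len(active_members) < min_compounds:
        return None
    qt = _build_query_table(actives, features)
    agg, per_compound = _aggregate_moa(qt, frozenset(active_members))
    if agg is None:
        return None
    return {
        "moa": moa,
        "cell_line": cell_line,
        "n_compounds": len(active_members),
        "auc": agg,
        "per_compound_auc": per_compound,
        "distinguishable": agg >= DISTINGUISHABLE_AUC,
    }


def evaluate_moas(
    actives: pd.DataFrame,
    annotations: pd.DataFrame,
    features: Sequence[str],
    cell_line: str = "",
    min_compounds: int = MIN_ACTIVE_COMPOUNDS,
) -> pd.DataFrame:
    """Aggregated AUC-ROC for every MoA with enough active compounds."""
    qt = _build_query_table(actives, features)
    active_comps = set(actives["compound_id"])
    rows = []
    for moa, grp in annotations.groupby("moa"):
        members = frozenset(set(grp["compound_id"]) & active_comps)
        if len(members) < min_compounds:
            continue
        agg, per_compound = _aggregate_moa(qt, members)
        if agg is None:
            continue
        rows.append(
            {
                "moa": moa,
                "cell_line": cell_line,
                "n_compounds": len(members),
                "auc": agg,
                "distinguishable": agg >= DISTINGUISHABLE_AUC,
            }
        )
    return pd.DataFrame(rows, columns=["moa", "cell_line", "n_compounds", "auc", "distinguishable"])


def permutation_significance(
    results: pd.DataFrame,
    actives: pd.DataFrame,
    annotations: pd.DataFrame,
    features: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    return_null: bool = False,
):
    """Empirical permutation p-values and BH-FDR for MoA AUC-ROC results.

    Each iteration permutes the compound-to-annotation-set mapping among the
    active compounds — a compound's full MoA set moves as one unit, so the
    MoA size spectrum and the multi-MoA structure are preserved — and the
    aggregated AUC of every tested MoA is recomputed on the unchanged
    signature correlations. ``p = (1 + #{null >= observed}) / (1 + n_perm)``;
    BH adjustment is applied jointly across all rows of ``results``
    (all tested (MoA, cell line) pairs).

    With ``return_null=True`` also returns a dict mapping (cell_line, moa)
    to the array of permuted aggregated AUCs.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d gives unstable empirical p-values", n_perm)
    out = results.reset_index(drop=True).copy()
    if out.empty:
        out["p_value"] = []
        out["p_adj"] = []
        out["significant"] = []
        return (out, {}) if return_null else out

    rng = np.random.default_rng(seed)
    p_values = np.ones(len(out))
    null_store: Dict[tuple, list] = {}
    for cl, sub in out.groupby("cell_line", sort=False):
        cl_actives = actives if "cell_line" not in actives.columns else actives[
            actives["cell_line"] == cl
        ]
        qt = _build_query_table(cl_actives, features)
        active_comps = sorted(set(cl_actives["compound_id"]))
        ann_sets = {
            c: frozenset(annotations.loc[annotations["compound_id"] == c, "moa"])
            for c in active_comps
        }
        sets_list = [ann_sets[c] for c in active_comps]
        moas = list(sub["moa"])
        observed = sub["auc"].to_numpy()
        exceed = np.zeros(len(moas))
        valid = np.zeros(len(moas))
        for _ in range(n_perm):
            perm = rng.permutation(len(active_comps))
            perm_sets = {active_comps[i]: sets_list[perm[i]] for i in range(len(active_comps))}
            moa_members: Dict[str, set] = {m: set() for m in moas}
            for c, s in perm_sets.items():
                for m in s:
                    if m in moa_members:
                        moa_members[m].add(c)
            for k, m in enumerate(moas):
                agg, _ = _aggregate_moa(qt, frozenset(moa_members[m]))
                if agg is None:
                    continue
                valid[k] += 1
                null_store.setdefault((cl, m), []).append(agg)
                if agg >= observed[k] - 1e-12:
                    exceed[k] += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
        p_values[sub.index.to_numpy()] = p
    out["p_value"] = p_values
    reject, p_adj, _, _ = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")
    out["p_adj"] = p_adj
    out["significant"] = reject
    if return_null:
        return out, {k: np.asarray(v) for k, v in null_store.items()}
    return out


def greedy_cell_line_ranking(
    results: pd.DataFrame, cutoff: float = DISTINGUISHABLE_AUC
) -> pd.DataFrame:
    """Greedy set-cover ranking of cell lines by added distinguishable MoAs.

    Repeatedly picks the cell line contributing the most not-yet-covered
    MoAs with AUC >= cutoff (ties by cell line id) and reports the
    cumulative coverage curve.
    """
    sets = {
        cl: set(sub.loc[sub["auc"] >= cutoff, "moa"])
        for cl, sub in results.groupby("cell_line")
    }
    covered: set = set()
    rows = []
    remaining = dict(sets)
    while remaining:
        gains = {cl: len(s - covered) for cl, s in remaining.items()}
        best = min(gains, key=lambda cl: (-gains[cl], cl))
        covered |= remaining.pop(best)
        rows.append({"cell_line": best, "n_new": gains[best], "cumulative": len(covered)})
    return pd.DataFrame(rows, columns=["cell_line", "n_new", "cumulative"])


# ---------------------------------------------------------------------------
# design-of-experiments subset analyses


def concentration_subset_analysis(
    actives: pd.DataFrame,
    annotations: pd.DataFrame,
    features: Sequence[str],
    concentrations: Sequence[float],
    full_results: pd.DataFrame,
    cell_line: str = "",
    min_compounds: int = MIN_ACTIVE_COMPOUNDS,
) -> pd.DataFrame:
    """Recompute MoA aggregates using active treatments at a concentration subset.

    Active calling is not redone: the active treatments of the full run are
    simply restricted to the included concentrations.
    """
    if len(concentrations) == 0:
        raise ValueError("concentration subset must be non-empty")
    sub = actives[actives["concentration_uM"].isin(list(concentrations))]
    res = evaluate_moas(sub, annotations, features, cell_line=cell_line, min_compounds=min_compounds)
    return _deltas(full_results, res)


def channel_subset_analysis(
    prefiltered: pd.DataFrame,
    actives_wells: pd.DataFrame,
    annotations: pd.DataFrame,
    channels: Sequence[str],
    full_results: pd.DataFrame,
    cell_line: str = "",
    signature_kwargs: Optional[dict] = None,
    min_compounds: int = MIN_ACTIVE_COMPOUNDS,
) -> Tuple[pd.DataFrame, SignatureSpec]:
    """Recompute MoA aggregates using only the descriptors of some channels.

    For an unbiased comparison the mRMR feature selection is *re-run* on the
    channel-restricted descriptor set (rather than dropping excluded-channel
    features from the full signature), while the set of active treatments is
    kept from the full-channel run.

    ``actives_wells`` are the normalized well profiles of the treatments
    called active in the full run; treatment-level signatures are
    re-aggregated on the new signature features.
    """
    from .feature_select import compute_relevance, mrmr_rank, select_signature
    from .preprocess import descriptor_columns

    channels = list(channels)
    if not channels:
        raise ValueError("channel subset must be non-empty")
    keep_desc = [
        d for d in descriptor_columns(prefiltered)
        if descriptor_channel(d) is None or descriptor_channel(d) in channels
    ]
    restricted = prefiltered[
        [c for c in prefiltered.columns if c not in descriptor_columns(prefiltered)] + keep_desc
    ]
    rel = compute_relevance(restricted)
    ranking = mrmr_rank(restricted, rel)
    sig = select_signature(ranking, restricted, cell_line=cell_line, **(signature_kwargs or {}))

    med = (
        actives_wells.groupby("treatment_id")
        .agg(
            compound_id=("compound_id", "first"),
            concentration_uM=("concentration_uM", "first"),
            **{f: (f, "median") for f in sig.features},
        )
        .reset_index()
    )
    res = evaluate_moas(med, annotations, sig.features, cell_line=cell_line, min_compounds=min_compounds)
    return _deltas(full_results, res), sig


def descriptor_channel(descriptor: str) -> Optional[str]:
    """Channel tag of a well descriptor, or None for channel-agnostic ones."""
    parts = descriptor.split("_")
    if parts[-1] in ("mean", "median") and len(parts) >= 3:
        return parts[-2]
    return None


def _deltas(full_results: pd.DataFrame, subset_results: pd.DataFrame) -> pd.DataFrame:
    merged = full_results[["moa", "cell_line", "auc"]].merge(
        subset_results[["moa", "cell_line", "n_compounds", "auc"]],
        on=["moa", "cell_line"],
        how="left",
        suffixes=("_full", "_subset"),
    )
    merged["delta"] = merged["auc_subset"] - merged["auc_full"]
    return merged
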