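"""Imaging-signature definition: modified mRMR ranking with a replicate-AUC
stopping rule.

The signature of a cell line is an ordered subset of the well descriptors,
chosen without using MoA annotations: features are ranked by a greedy
minimum-redundancy-maximum-relevance (mRMR) procedure with the treatment ID
as the class variable, and the signature size is the smallest prefix whose
replicate-discrimination AUC is within one SD of the best achievable mean
AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import descriptor_columns

DEFAULT_MIN_CELLS = 100


class EmptySelectionError(ValueError):
    """Prefiltering removed every well."""


def prefilter_wells(
    profiles: pd.DataFrame,
    min_cells: int = DEFAULT_MIN_CELLS,
    control_percentile: float = 95.0,
    trim: float = 0.01,
) -> pd.DataFrame:
    """Remove uninformative wells and tame outliers before feature selection.

    Three steps, on normalized profiles:

    1. Wells whose Euclidean distance (over all descriptors) to the mean
       DMSO control profile falls below the ``control_percentile`` of the
       null distribution of control-well distances are removed — they are
       statistically indistinguishable from vehicle.
    2. Wells with fewer than ``min_cells`` live cells are removed.
    3. Each descriptor is winsorized at its ``trim`` and ``1 - trim``
       quantiles over the remaining wells (clipping, so treatment class
       sizes are preserved for the F-statistic).
    """
    desc = descriptor_columns(profiles)
    X = profiles[desc].to_numpy(dtype=float)
    ctrl = profiles["is_control"].to_numpy()
    if ctrl.sum() < 2:
        raise ValueError("prefilter needs at least 2 control wells")
    ctrl_mean = np.nanmean(X[ctrl], axis=0)
    dist = np.sqrt(np.nansum((X - ctrl_mean) ** 2, axis=1))
    dist[np.all(np.isnan(X), axis=1)] = np.nan
    cutoff = np.percentile(dist[ctrl][~np.isnan(dist[ctrl])], control_percentile)
    keep = (dist >= cutoff) & (profiles["n_live"].to_numpy() >= min_cells)
    keep &= ~np.isnan(dist)
    if not keep.any():
        raise EmptySelectionError(
            f"all {len(profiles)} wells removed (distance cutoff {cutoff:.3g}, "
            f"min_cells {min_cells})"
        )
    out = profiles.loc[keep].reset_index(drop=True).copy()
    Y = out[desc].to_numpy(dtype=float)
    lo = np.nanquantile(Y, trim, axis=0)
    hi = np.nanquantile(Y, 1.0 - trim, axis=0)
    out[desc] = np.clip(Y, lo, hi)
    return out


def compute_relevance(
    profiles: pd.DataFrame, treatment_col: str = "treatment_id"
) -> pd.Series:
    """Per-feature relevance: one-way ANOVA F over treatments, scaled to (0, 1].

    The F-statistic of each descriptor with the treatment ID as the grouping
    factor, divided by the maximum F across descriptors. Constant features
    get relevance 0; features with zero within-treatment variance but
    nonzero between-treatment variance saturate at the maximum.
    """
    desc = descriptor_columns(profiles)
    codes, _ = pd.factorize(profiles[treatment_col])
    k = codes.max() + 1
    if k < 2:
        raise ValueError("relevance needs at least 2 treatments")
    X = profiles[desc].to_numpy(dtype=float)
    N = len(X)
    counts = np.bincount(codes, minlength=k).astype(float)
    sums = np.zeros((k, X.shape[1]))
    np.add.at(sums, codes, X)
    gmeans = sums / counts[:, None]
    grand = X.mean(axis=0)
    ssb = (counts[:, None] * (gmeans - grand) ** 2).sum(axis=0)
    sst = ((X - grand) ** 2).sum(axis=0)
    ssw = np.maximum(sst - ssb, 0.0)
    dfb, dfw = k - 1, N - k
    if dfw < 1:
        raise ValueError("no within-treatment degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F = np.where(sst <= 1e-12 * N, 0.0, F)
    finite = np.isfinite(F)
    if not finite.all():
        # zero within-group variance: saturate at the largest finite F
        cap = F[finite].max(initial=1.0)
        F = np.where(finite, F, cap)
    fmax = F.max()
    rel = F / fmax if fmax > 0 else np.zeros_like(F)
    return pd.Series(rel, index=desc, name="relevance")


@dataclass
class FeatureRanking:
    """Full mRMR ranking with per-step diagnostics.

    ``redundancy[i]`` and ``score[i]`` are the redundancy and trade-off score
    of ``features[i]`` at the step it was selected.
    """

    features: List[str]
    relevance: np.ndarray
    redundancy: np.ndarray
    score: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "relevance": self.relevance,
                "redundancy": self.redundancy,
                "score": self.score,
            }
        )


def mrmr_rank(profiles: pd.DataFrame, relevance: pd.Series) -> FeatureRanking:
    """Greedy minimum-redundancy-maximum-relevance ranking of all descriptors.

    Starting from the most relevant feature, each step selects the feature
    maximizing ``relevance * (1 - redundancy)`` where redundancy is the
    maximum absolute Pearson correlation with any already-selected feature
    (an anti-correlated copy is as redundant as a correlated one). Ties are
    broken toward the lower feature index; the result is deterministic.
    """
    desc = list(relevance.index)
    X = profiles[desc].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        C = np.abs(np.corrcoef(X, rowvar=False))
    C = np.nan_to_num(C, nan=0.0)  # constant features: define correlation 0
    rel = relevance.to_numpy(dtype=float)
    n = len(desc)

    order: List[int] = []
    red_sel = np.zeros(n)
    score_sel = np.zeros(n)
    redundancy = np.zeros(n)  # max |r| to selected set, updated each step
    remaining = np.ones(n, dtype=bool)
    for _ in range(n):
        score = np.where(remaining, rel * (1.0 - redundancy), -np.inf)
        j = int(np.argmax(score))  # argmax returns the first (lowest) index on ties
        order.append(j)
        red_sel[len(order) - 1] = redundancy[j]
        score_sel[len(order) - 1] = score[j]
        remaining[j] = False
        redundancy = np.maximum(redundancy, C[j])
    return FeatureRanking(
        features=[desc[j] for j in order],
        relevance=rel[order],
        redundancy=red_sel.copy(),
        score=score_sel.copy(),
    )


# ---------------------------------------------------------------------------
# replicate-discrimination AUC


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center and L2-normalize rows so dot products are Pearson correlations."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Xc, axis=1, keepdims=True)
    norm[norm == 0] = np.nan
    return Xc / norm


def _replicate_pairs(treatments: np.ndarray) -> np.ndarray:
    pairs = []
    s = pd.Series(np.arange(len(treatments))).groupby(treatments)
    for _, idx in s:
        idx = idx.to_numpy()
        if len(idx) >= 2:
            i, j = np.triu_indices(len(idx), k=1)
            pairs.append(np.column_stack([idx[i], idx[j]]))
    return np.vstack(pairs) if pairs else np.empty((0, 2), dtype=int)


def _sample_nonreplicate_pairs(
    treatments: np.ndarray, n_pairs: int, rng: np.random.Generator,
    enumerate_cap: int = 500_000,
) -> np.ndarray:
    """Up to ``n_pairs`` distinct well pairs with different treatments.

    Exhaustive enumeration when the total number of pairs is small (exact,
    reproducible); otherwise rejection sampling without replacement.
    """
    n = len(treatments)
    total = n * (n - 1) // 2
    if total <= enumerate_cap:
        i, j = np.triu_indices(n, k=1)
        mask = treatments[i] != treatments[j]
        pairs = np.column_stack([i[mask], j[mask]])
        if len(pairs) > n_pairs:
            pick = rng.choice(len(pairs), size=n_pairs, replace=False)
            pairs = pairs[pick]
        return pairs
    seen: set = set()
    out = []
    while len(out) < n_pairs:
        ii = rng.integers(0, n, size=2 * (n_pairs - len(out)))
        jj = rng.integers(0, n, size=len(ii))
        for a, b in zip(ii, jj):
            if a == b or treatments[a] == treatments[b]:
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            out.append(key)
            if len(out) == n_pairs:
                break
    return np.array(out, dtype=int)


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Probability a positive outranks a negative (Mann-Whitney, midranks)."""
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def replicate_auc(
    profiles: pd.DataFrame,
    feature_subset: Sequence[str],
    max_pairs: int = 10_000,
    repeats: int = 10,
    seed: int = 0,
) -> Tuple[float, float]:
    """How well Pearson correlation separates replicate from non-replicate pairs.

    Per repeat, up to ``max_pairs`` replicate pairs (same compound and
    concentration) and ``max_pairs`` non-replicate pairs (different
    treatment) are sampled without replacement; each pair is scored by the
    Pearson correlation of the two wells restricted to ``feature_subset``,
    and the AUC is the probability that a replicate pair outscores a
    non-replicate pair (midrank handling of ties). Returns the mean and SD
    of the AUC over repeats.
    """
    treatments = profiles["treatment_id"].to_numpy()
    rep_all = _replicate_pairs(treatments)
    if len(rep_all) == 0:
        raise ValueError("no replicate pairs: every treatment has a single well")
    Z = _standardize_rows(profiles[list(feature_subset)].to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(repeats):
        rep = rep_all
        if len(rep) > max_pairs:
            rep = rep[rng.choice(len(rep), size=max_pairs, replace=False)]
        non = _sample_nonreplicate_pairs(treatments, max_pairs, rng)
        if len(non) == 0:
            raise ValueError("no non-replicate pairs available")
        r_rep = np.einsum("ij,ij->i", Z[rep[:, 0]], Z[rep[:, 1]])
        r_non = np.einsum("ij,ij->i", Z[non[:, 0]], Z[non[:, 1]])
        ok_rep, ok_non = ~np.isnan(r_rep), ~np.isnan(r_non)
        aucs.append(_rank_auc(r_rep[ok_rep], r_non[ok_non]))
    return float(np.mean(aucs)), float(np.std(aucs, ddof=0))


@dataclass
class SignatureSpec:
    """The imaging-signature definition of one cell line."""

    cell_line: str
    features: List[str]  # the selected, ordered signature features (length k)
    k: int
    auc_curve: List[dict] = field(default_factory=list)  # size, mean_auc, sd_auc
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cell_line": self.cell_line,
                    "features": self.features,
                    "k": self.k,
                    "auc_curve": self.auc_curve,
                    "seed": self.seed,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureSpec":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def default_size_grid(n_features: int, dense_to: int = 40, stride: int = 5, cap: int = 120) -> List[int]:
    """Candidate signature sizes: every size up to ``dense_to``, then strided."""
    grid = list(range(1, min(dense_to, n_features) + 1))
    grid += list(range(dense_to + stride, min(cap, n_features) + 1, stride))
    return grid


def choose_k(sizes: Sequence[int], means: Sequence[float], sds: Sequence[float]) -> int:
    """One-SD stopping rule on a replicate-AUC curve.

    Returns the minimal candidate size whose mean AUC is at least the
    maximum mean AUC minus the SD at the size achieving that maximum.
    Sizes with undefined (NaN) mean AUC are never chosen.
    """
    means_a = np.where(np.isnan(means), -np.inf, np.asarray(means, dtype=float))
    imax = int(np.argmax(means_a))
    threshold = means_a[imax] - np.asarray(sds, dtype=float)[imax]
    return int(list(sizes)[int(np.argmax(means_a >= threshold))])


def select_signature(
    ranking: FeatureRanking,
    profiles: pd.DataFrame,
    grid: Optional[Sequence[int]] = None,
    max_pairs: int = 10_000,
    repeats: int = 10,
    seed: int = 0,
    cell_line: str = "",
) -> SignatureSpec:
    """Choose the signature size by the one-SD rule on the replicate AUC.

    The replicate-discrimination AUC is evaluated at increasing prefix sizes
    of the mRMR ranking; the chosen ``k`` is the minimal size whose mean AUC
    is at least the maximum mean AUC minus the SD at the size achieving that
    maximum.
    """
    sizes = list(grid) if grid is not None else default_size_grid(len(ranking.features))
    means, sds = [], []
    for i, size in enumerate(sizes):
        m, s = replicate_auc(
            profiles, ranking.features[:size], max_pairs=max_pairs, repeats=repeats,
            seed=seed + i,
        )
        means.append(m)
        sds.append(s)
    k = choose_k(sizes, means, sds)
    curve = [
        {"size": int(s), "mean_auc": float(m), "sd_auc": float(sd)}
        for s, m, sd in zip(sizes, means, sds)
    ]
    return SignatureSpec(
        cell_line=cell_line, features=ranking.features[:k], k=int(k), auc_curve=curve, seed=seed
    )
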