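"""Phenotypic active calling and treatment-level signature aggregation.

A treatment (compound at one concentration) is phenotypically active when

1. strictly more than 50% of its replicate wells deviate from vehicle
   (Euclidean distance of the well's imaging signature to the zero vector —
   the mean control signature after z-normalization — exceeds ``tau``, the
   95th percentile of the control-well distance null), and
2. its replicate signatures are reproducible: the median Pearson correlation
   over all replicate pairs exceeds the 95th percentile of a null of
   non-replicate (different-compound) correlations built from wells of
   Euclidean-active treatments.

Both criteria operate on the selected signature features only. A compound is
active if at least one of its concentrations is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .feature_select import SignatureSpec, _standardize_rows

logger = logging.getLogger(__name__)

QUANTILE = 95.0  # percentile used for both nulls; linear interpolation


@dataclass
class ActivityThresholds:
    """Empirical null thresholds of the two activity criteria."""

    tau: float  # Euclidean activity threshold
    rho_null: float  # reproducibility (correlation) threshold
    n_null_pairs_used: int = 0


def signature_matrix(profiles: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    return profiles[list(features)].to_numpy(dtype=float)


def compute_tau(
    control_profiles: pd.DataFrame,
    signature: SignatureSpec,
    min_controls: int = 20,
) -> float:
    """95th percentile of control-well signature distances to the zero vector.

    After control-based z-normalization the mean control signature is the
    zero vector, so the null is simply the distribution of control signature
    norms. By construction 5% of individual control wells exceed ``tau``.
    """
    if len(control_profiles) < min_controls:
        raise ValueError(
            f"need >= {min_controls} control wells for a stable 95th percentile, "
            f"got {len(control_profiles)}"
        )
    X = signature_matrix(control_profiles, signature.features)
    dists = np.sqrt(np.nansum(X**2, axis=1))
    return float(np.percentile(dists, QUANTILE))


def euclidean_distances(profiles: pd.DataFrame, signature: SignatureSpec) -> np.ndarray:
    X = signature_matrix(profiles, signature.features)
    return np.sqrt(np.nansum(X**2, axis=1))


def call_euclidean_active(
    treatment_wells: pd.DataFrame, signature: SignatureSpec, tau: float
) -> Tuple[np.ndarray, bool]:
    """Flag replicate wells beyond ``tau``; the treatment is Euclidean-active
    when strictly more than half of its wells are flagged (3 of 4 in the
    standard design; 2 of 3 when a replicate well was lost)."""
    d = euclidean_distances(treatment_wells, signature)
    flags = d > tau
    return flags, bool(flags.sum() > 0.5 * len(flags))


def _pair_correlations(Z: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ij->i", Z[pairs[:, 0]], Z[pairs[:, 1]])


def compute_reproducibility_null(
    active_wells: pd.DataFrame,
    signature: SignatureSpec,
    cap_pairs: int = 2_000_000,
    seed: int = 0,
) -> Tuple[float, int]:
    """95th percentile of non-replicate signature correlations.

    Non-replicates are pairs of wells of *different compounds* among the
    Euclidean-active treatments — pairs of the same compound at different
    concentrations are excluded, since a compound's concentrations often
    share a phenotype. Pairs are enumerated exhaustively when their total
    count is at most ``cap_pairs``, otherwise uniformly subsampled.

    Returns ``(rho_null, n_pairs_used)``.
    """
    compounds = active_wells["compound_id"].to_numpy()
    n = len(active_wells)
    if len(np.unique(compounds)) < 2:
        raise ValueError("reproducibility null needs >= 2 distinct active compounds")
    Z = _standardize_rows(signature_matrix(active_wells, signature.features))
    total = n * (n - 1) // 2
    rng = np.random.default_rng(seed)
    if total <= cap_pairs:
        i, j = np.triu_indices(n, k=1)
        mask = compounds[i] != compounds[j]
        pairs = np.column_stack([i[mask], j[mask]])
    else:
        pairs_set: set = set()
        while len(pairs_set) < cap_pairs:
            a = rng.integers(0, n, size=cap_pairs)
            b = rng.integers(0, n, size=cap_pairs)
            ok = (a != b) & (compounds[a] != compounds[b])
            for x, y in zip(a[ok], b[ok]):
                pairs_set.add((x, y) if x < y else (y, x))
                if len(pairs_set) == cap_pairs:
                    break
        pairs = np.array(sorted(pairs_set), dtype=int)
    if len(pairs) == 0:
        raise ValueError("no eligible non-replicate pairs")
    r = _pair_correlations(Z, pairs)
    r = r[~np.isnan(r)]
    return float(np.percentile(r, QUANTILE)), int(len(r))


def call_active(
    profiles: pd.DataFrame,
    signature: SignatureSpec,
    thresholds: Optional[ActivityThresholds] = None,
    cap_pairs: int = 2_000_000,
    seed: int = 0,
) -> Tuple[pd.DataFrame, ActivityThresholds]:
    """Classify every treatment as phenotypically active or not.

    Parameters
    ----------
    profiles : normalized well profiles (controls included) of one cell line.
    signature : the cell line's imaging-signature definition.
    thresholds : reuse precomputed thresholds; computed from the data when
        ``None``.

    Returns
    -------
    calls : one row per treatment with per-criterion flags, the median
        replicate correlation, the activity call, and the treatment-level
        signature (component-wise median over replicate wells) in the
        signature feature columns.
    thresholds : the ``ActivityThresholds`` used.
    """
    controls = profiles[profiles["is_control"]]
    samples = profiles[~profiles["is_control"]]
    tau = thresholds.tau if thresholds is not None else compute_tau(controls, signature)

    dists = euclidean_distances(samples, signature)
    flagged = dists > tau
    samples = samples.assign(_dist=dists, _flag=flagged)

    # criterion 1: strictly > 50% of replicate wells beyond tau
    eucl = samples.groupby("treatment_id").agg(
        compound_id=("compound_id", "first"),
        concentration_uM=("concentration_uM", "first"),
        n_wells=("_flag", "size"),
        n_flagged=("_flag", "sum"),
    )
    eucl["euclidean_active"] = eucl["n_flagged"] > 0.5 * eucl["n_wells"]

    if thresholds is not None:
        rho_null, n_pairs = thresholds.rho_null, thresholds.n_null_pairs_used
    else:
        active_tids = eucl.index[eucl["euclidean_active"]]
        active_wells = samples[samples["treatment_id"].isin(active_tids)]
        try:
            rho_null, n_pairs = compute_reproducibility_null(
                active_wells, signature, cap_pairs=cap_pairs, seed=seed
            )
        except ValueError:
            # fewer than 2 distinct Euclidean-active compounds (e.g. a null
            # screen): no null is estimable and nothing can be called active
            logger.warning(
                "call_active: reproducibility null not estimable; "
                "no treatment can satisfy the reproducibility criterion"
            )
            rho_null, n_pairs = np.inf, 0
    thresholds = ActivityThresholds(tau=float(tau), rho_null=float(rho_null), n_null_pairs_used=n_pairs)

    # criterion 2: median replicate-pair correlation above the null threshold
    Z = _standardize_rows(signature_matrix(samples, signature.features))
    med_r = {}
    med_sig = {}
    X = signature_matrix(samples, signature.features)
    for tid, idx in samples.groupby("treatment_id").indices.items():
        med_sig[tid] = np.nanmedian(X[idx], axis=0)
        if len(idx) < 2:
            med_r[tid] = np.nan
            continue
        i, j = np.triu_indices(len(idx), k=1)
        r = _pair_correlations(Z, np.column_stack([idx[i], idx[j]]))
        med_r[tid] = float(np.nanmedian(r))

    calls = eucl.reset_index()
    calls["median_replicate_r"] = calls["treatment_id"].map(med_r)
    reproducible = calls["median_replicate_r"] > rho_null
    undefined = calls["median_replicate_r"].isna()
    if undefined.any():
        logger.warning(
            "call_active: %d treatments with < 2 replicate wells marked inactive",
            int(undefined.sum()),
        )
    calls["reproducible"] = reproducible.fillna(False) & ~undefined
    calls["active"] = calls["euclidean_active"] & calls["reproducible"]
    sig_mat = np.vstack([med_sig[t] for t in calls["treatment_id"]])
    calls = pd.concat(
        [calls, pd.DataFrame(sig_mat, columns=signature.features, index=calls.index)], axis=1
    )
    return calls, thresholds


def compound_activity(calls: pd.DataFrame) -> pd.Series:
    """Per-compound activity: active at >= 1 concentration."""
    return calls.groupby("compound_id")["active"].any()
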