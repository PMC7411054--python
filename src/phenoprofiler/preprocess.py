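"""Live-cell filtering, well-level aggregation, and control normalization.

Well descriptors are the mean and the median of every raw feature over the
live cells of the well, plus the live-cell count — ``2 * n_features + 1``
descriptors per well. Normalization is against the DMSO vehicle controls:
per descriptor, subtract the mean of the control wells plate-wise, then
divide by the standard deviation of the (plate-centered) control wells
batch-wise, yielding z-scores relative to vehicle.
"""

from __future__ import annotations

import logging
from typing import List

import numpy as np
import pandas as pd

from .synthgen import DMSO, QC_LIVE, treatment_id

logger = logging.getLogger(__name__)

#: metadata columns of a well-profile table; everything else is a descriptor
META_COLUMNS = [
    "plate_id",
    "batch_id",
    "well",
    "compound_id",
    "concentration_uM",
    "treatment_id",
    "is_control",
    "n_live",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ConsistencyError(ValueError):
    """Cells and plate maps disagree about the screen layout."""


def descriptor_columns(profiles: pd.DataFrame) -> List[str]:
    """Descriptor (feature) columns of a well-profile table."""
    return [c for c in profiles.columns if c not in META_COLUMNS]


def filter_live(cells: pd.DataFrame) -> pd.DataFrame:
    """Keep live-classified cells only.

    Dead and mis-segmented cells (as labelled by the upstream QC classifier)
    are dropped; removal counts are logged.
    """
    if "qc_label" not in cells.columns:
        raise SchemaError("cell table has no 'qc_label' column")
    counts = cells["qc_label"].value_counts()
    n_removed = int(len(cells) - counts.get(QC_LIVE, 0))
    logger.info(
        "filter_live: kept %d live cells, removed %d (%s)",
        counts.get(QC_LIVE, 0),
        n_removed,
        {k: int(v) for k, v in counts.items() if k != QC_LIVE},
    )
    return cells[cells["qc_label"] == QC_LIVE].reset_index(drop=True)


def aggregate_wells(cells: pd.DataFrame, plate_maps: pd.DataFrame) -> pd.DataFrame:
    """Aggregate live cells to one profile per well.

    Per raw feature, the mean (``<feature>_mean``) and the median
    (``<feature>_median``) over the live cells of the well are computed; the
    live-cell count is appended as the ``cell_count`` descriptor. Wells that
    lost all their cells (e.g. everything dead) keep a row with count 0 and
    missing descriptors.

    Raises
    ------
    ConsistencyError
        If the cell table contains a (plate, well) absent from the plate map.
    """
    feat_cols = [
        c for c in cells.columns if c not in ("plate_id", "batch_id", "well", "cell_id", "qc_label")
    ]
    pm_keys = set(zip(plate_maps["plate_id"], plate_maps["well"]))
    cell_keys = set(zip(cells["plate_id"], cells["well"]))
    orphans = cell_keys - pm_keys
    if orphans:
        raise ConsistencyError(f"{len(orphans)} wells in cell table missing from plate map, e.g. {sorted(orphans)[:3]}")

    grouped = cells.groupby(["plate_id", "well"], sort=True)[feat_cols]
    means = grouped.mean()
    medians = grouped.median()
    counts = grouped.size().rename("cell_count")
    means.columns = [f"{c}_mean" for c in feat_cols]
    medians.columns = [f"{c}_median" for c in feat_cols]
    agg = pd.concat([means, medians, counts], axis=1).reset_index()

    # keep every plate-map well of the plates actually measured
    plates_seen = set(cells["plate_id"].unique())
    pm = plate_maps[plate_maps["plate_id"].isin(plates_seen)] if plates_seen else plate_maps
    profiles = pm.merge(agg, on=["plate_id", "well"], how="left")
    profiles["cell_count"] = profiles["cell_count"].fillna(0).astype(float)
    profiles["n_live"] = profiles["cell_count"].astype(int)
    profiles["is_control"] = profiles["compound_id"] == DMSO
    profiles["treatment_id"] = np.where(
        profiles["is_control"],
        DMSO,
        [treatment_id(c, k) for c, k in zip(profiles["compound_id"], profiles["concentration_uM"])],
    )
    meta = [c for c in META_COLUMNS if c in profiles.columns]
    desc = [c for c in profiles.columns if c not in meta + ["well_row", "well_col"]]
    return profiles[meta + desc]


def normalize(profiles: pd.DataFrame, min_controls: int = 2) -> pd.DataFrame:
    """Z-score descriptors against DMSO controls, plate-wise then batch-wise.

    Each descriptor is centered by the mean of the control wells of its plate
    and scaled by the sample SD (n-1 denominator) of the plate-centered
    control wells pooled over its batch. Descriptors whose batch control SD
    is zero (constant in controls) cannot be standardized and are dropped
    with a warning. Missing values (empty wells) propagate as missing.
    """
    desc = descriptor_columns(profiles)
    for col, n_req in (("plate_id", min_controls), ("batch_id", min_controls)):
        n_ctrl = profiles[profiles["is_control"]].groupby(col).size()
        if (n_ctrl < n_req).any() or n_ctrl.empty:
            raise ValueError(f"every {col} needs at least {n_req} control wells")

    out = profiles.copy()
    ctrl = out["is_control"].to_numpy()
    X = out[desc].to_numpy(dtype=float)

    # plate-wise control centering
    for pid, idx in out.groupby("plate_id").indices.items():
        cmean = np.nanmean(X[idx][ctrl[idx]], axis=0)
        X[idx] = X[idx] - cmean

    # batch-wise control SD on the plate-centered values
    dropped = []
    for bid, idx in out.groupby("batch_id").indices.items():
        csd = np.nanstd(X[idx][ctrl[idx]], axis=0, ddof=1)
        sub = X[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            sub = sub / csd
        sub[:, csd == 0] = np.nan
        X[idx] = sub
        dropped.append(csd == 0)
    constant = np.any(np.vstack(dropped), axis=0)
    out[desc] = X
    if constant.any():
        bad = [d for d, c in zip(desc, constant) if c]
        logger.warning("normalize: dropping %d constant descriptors: %s", len(bad), bad[:5])
        out = out.drop(columns=bad)
    return out
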