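"""Synthetic compound-screen generator with known ground truth.

Emulates the statistical structure of a live-cell imaging screen: 384-well
plates with 28 DMSO control and 280 sample wells, treatments screened at four
concentrations in two technical replicates per batch over two batches,
per-cell feature vectors with plate/batch nuisance offsets, MoA-coherent
treatment effects with saturating concentration response, redundant feature
blocks, pure-noise features, and dead / mis-segmented cells.

The generative model (per live cell, feature f):

    x = baseline_f + plate_offset + batch_offset + effect_f(treatment) + noise

with ``effect_f = effect_size * jitter_c * potency_c(conc) * direction_cf *
sigma_well`` on informative features, zero for DMSO and inactive compounds.
``sigma_well`` is the well-level control SD, so ``effect_size`` is a
standardized (z-score scale) magnitude. Redundant features are affine copies
of an informative parent plus small noise; noise features carry no effect.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (
    CHANNELS,
    CONTROL_WELLS_PER_PLATE,
    SAMPLE_WELLS_PER_PLATE,
    ConfigurationError,
    ScreenConfig,
)

DMSO = "DMSO"
QC_LIVE = "live"
QC_DEAD = "dead"
QC_MISSEGMENTED = "missegmented"

_ROWS = string.ascii_uppercase[:16]  # 384-well convention: rows A..P, cols 1..24


def treatment_id(compound_id: str, concentration_uM: float) -> str:
    return f"{compound_id}@{concentration_uM:g}"


def feature_names(n_features: int) -> List[str]:
    """Raw feature names, channel-tagged round-robin over BFP/GFP/RFP."""
    return [f"f{i:03d}_{CHANNELS[i % len(CHANNELS)]}" for i in range(n_features)]


@dataclass
class GroundTruth:
    """Planted truth of a simulated screen.

    Effect directions are unit-RMS vectors over the informative raw features;
    redundant features inherit the effect of their parent through the affine
    copy, noise features carry none.
    """

    compound_moas: Dict[str, List[str]]
    compound_active: Dict[str, bool]
    compound_direction: Dict[str, np.ndarray]
    compound_ec50: Dict[str, float]
    compound_magnitude: Dict[str, float]
    moa_direction: Dict[str, np.ndarray]
    moa_coherent: Dict[str, bool]
    feature_roles: pd.DataFrame  # feature, role, parent, channel
    baseline: np.ndarray
    redundant_slope: np.ndarray
    redundant_intercept: np.ndarray
    plate_offsets: Dict[str, np.ndarray] = field(default_factory=dict)
    batch_offsets: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def informative_features(self) -> List[str]:
        r = self.feature_roles
        return list(r.loc[r["role"] == "informative", "feature"])

    @property
    def main_moas(self) -> List[str]:
        return list(self.moa_coherent)

    def effect_multiplier(self, compound_id: str, concentration_uM: float) -> float:
        """Saturating (Hill) concentration response in [0, 1)."""
        ec50 = self.compound_ec50[compound_id]
        h = self._hill
        c = concentration_uM**h
        return c / (c + ec50**h)

    _hill: float = 2.0


def _rng(config: ScreenConfig, stream: int) -> np.random.Generator:
    # independent, reproducible per-stage streams derived from the master seed
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_library(config: ScreenConfig) -> Tuple[pd.DataFrame, GroundTruth]:
    """Generate the compound library, its MoA annotations, and planted truth.

    Compounds are assigned to the main MoAs according to
    ``moa_size_distribution``; compounds beyond that sum each receive a
    singleton MoA descriptor, mimicking the long tail of rarely represented
    mechanisms in real reference libraries. A fraction ``frac_multi_moa`` of
    compounds carries a second main-MoA descriptor (multi-target compounds).

    Returns
    -------
    annotations : DataFrame with one row per (compound_id, moa) pair.
    truth : GroundTruth with activity flags, effect directions, potencies and
        the raw-feature role structure.
    """
    rng = _rng(config, 1)
    n = config.n_compounds
    compounds = [f"C{i:04d}" for i in range(n)]
    main_moas = [f"MOA{m:02d}" for m in range(config.n_moas)]

    sizes = list(config.moa_size_distribution)
    if sum(sizes) > n:
        raise ConfigurationError("moa size distribution infeasible for n_compounds")

    compound_moas: Dict[str, List[str]] = {}
    i = 0
    for moa, size in zip(main_moas, sizes):
        for _ in range(size):
            compound_moas[compounds[i]] = [moa]
            i += 1
    for cid in compounds[i:]:
        compound_moas[cid] = [f"moa_{cid}"]

    # second descriptor for multi-target compounds
    n_multi = int(round(config.frac_multi_moa * n))
    if n_multi > 0 and config.n_moas >= 1:
        multi = rng.choice(n, size=n_multi, replace=False)
        for j in sorted(multi):
            cid = compounds[j]
            extra = [m for m in main_moas if m not in compound_moas[cid]]
            if extra:
                compound_moas[cid].append(extra[rng.integers(len(extra))])

    # activity: main-MoA members are always active so planted MoAs stay
    # testable; the active fraction applies to the singleton-MoA tail
    n_grouped = sum(sizes)
    compound_active = {}
    for j, cid in enumerate(compounds):
        if j < n_grouped:
            compound_active[cid] = True
        else:
            compound_active[cid] = bool(rng.random() < config.frac_active_compounds)

    # feature role structure: informative | redundant (affine copy) | noise
    names = feature_names(config.n_features)
    n_inf = config.n_informative_features
    n_red = config.n_redundant_features
    roles = ["informative"] * n_inf + ["redundant"] * n_red + ["noise"] * config.n_noise_features
    parents: List[Optional[str]] = [None] * config.n_features
    for k in range(n_red):
        parents[n_inf + k] = names[k % n_inf]  # parent among informative features
    feature_roles = pd.DataFrame(
        {
            "feature": names,
            "role": roles,
            "parent": parents,
            "channel": [f.rsplit("_", 1)[1] for f in names],
        }
    )
    baseline = rng.normal(5.0, 2.0, size=config.n_features)
    slope = rng.uniform(0.8, 1.2, size=n_red) * rng.choice([-1.0, 1.0], size=n_red)
    intercept = rng.normal(0.0, 1.0, size=n_red)

    def unit_rms_direction() -> np.ndarray:
        d = np.zeros(config.n_features)
        v = rng.standard_normal(n_inf)
        d[:n_inf] = v / np.sqrt(np.mean(v**2))
        return d

    moa_coherent = {
        moa: (k < config.n_moas - config.n_incoherent_moas)
        for k, moa in enumerate(main_moas)
    }
    moa_direction = {moa: unit_rms_direction() for moa in main_moas if moa_coherent[moa]}

    compound_direction: Dict[str, np.ndarray] = {}
    for cid in compounds:
        if not compound_active[cid]:
            compound_direction[cid] = np.zeros(config.n_features)
            continue
        shared = [moa_direction[m] for m in compound_moas[cid] if m in moa_direction]
        if shared:
            d = np.mean(shared, axis=0)
            rms = np.sqrt(np.mean(d[:n_inf] ** 2))
            compound_direction[cid] = d / rms if rms > 0 else unit_rms_direction()
        else:
            compound_direction[cid] = unit_rms_direction()

    compound_ec50 = {
        cid: float(config.ec50_median_uM * np.exp(rng.normal(0.0, config.ec50_log_sigma)))
        for cid in compounds
    }
    compound_magnitude = {
        cid: float(np.exp(rng.normal(0.0, config.magnitude_log_sigma))) for cid in compounds
    }

    annotations = pd.DataFrame(
        [(cid, moa) for cid in compounds for moa in compound_moas[cid]],
        columns=["compound_id", "moa"],
    )
    truth = GroundTruth(
        compound_moas=compound_moas,
        compound_active=compound_active,
        compound_direction=compound_direction,
        compound_ec50=compound_ec50,
        compound_magnitude=compound_magnitude,
        moa_direction=moa_direction,
        moa_coherent=moa_coherent,
        feature_roles=feature_roles,
        baseline=baseline,
        redundant_slope=slope,
        redundant_intercept=intercept,
    )
    truth._hill = config.hill_coefficient
    return annotations, truth


def _well_positions(n_used: int) -> List[Tuple[str, int]]:
    """First ``n_used`` well positions of a 384-well plate, row-major A1..P24."""
    pos = [(r, c) for r in _ROWS for c in range(1, 25)]
    return pos[:n_used]


def generate_plate_maps(config: ScreenConfig) -> pd.DataFrame:
    """Lay treatments out on 384-well plates.

    Every plate carries 28 DMSO control wells interleaved among 280 sample
    positions (controls every 11th used well). Each treatment (compound x
    concentration) is placed on ``n_tech_replicates`` wells in every batch,
    so the default design gives 4 replicate wells per treatment.

    Returns a DataFrame with columns plate_id, batch_id, well_row, well_col,
    well, compound_id (``"DMSO"`` for controls), concentration_uM (0 for
    controls).
    """
    rng = _rng(config, 2)
    treatments = [
        (cid, conc)
        for cid in (f"C{i:04d}" for i in range(config.n_compounds))
        for conc in config.concentrations
    ]
    slots = [t for t in treatments for _ in range(config.n_tech_replicates)]
    order = rng.permutation(len(slots)) if slots else np.array([], dtype=int)

    n_plates = max(1, -(-len(slots) // SAMPLE_WELLS_PER_PLATE))
    used = CONTROL_WELLS_PER_PLATE + SAMPLE_WELLS_PER_PLATE
    positions = _well_positions(used)
    control_idx = set(range(0, used, used // CONTROL_WELLS_PER_PLATE))

    rows = []
    for b in range(config.n_batches):
        batch_id = f"B{b + 1}"
        it = iter(order)
        for p in range(n_plates):
            plate_id = f"{config.cell_line}-{batch_id}-P{p + 1:02d}"
            for k, (r, c) in enumerate(positions):
                if k in control_idx:
                    rows.append((plate_id, batch_id, r, c, DMSO, 0.0))
                else:
                    j = next(it, None)
                    if j is None:
                        continue
                    cid, conc = slots[j]
                    rows.append((plate_id, batch_id, r, c, cid, conc))
    pm = pd.DataFrame(
        rows,
        columns=["plate_id", "batch_id", "well_row", "well_col", "compound_id", "concentration_uM"],
    )
    pm["well"] = pm["well_row"] + pm["well_col"].map("{:02d}".format)
    return pm[["plate_id", "batch_id", "well_row", "well_col", "well", "compound_id", "concentration_uM"]]


def simulate_cells(
    plate_maps: pd.DataFrame, truth: GroundTruth, config: ScreenConfig
) -> pd.DataFrame:
    """Simulate the per-cell feature table for a laid-out screen.

    Per-well cell counts are negative-binomial; each cell is labelled live,
    dead or mis-segmented, with dead/mis-segmented cells shifted in feature
    space so the downstream live-cell filter has something to remove.
    Plate and batch offsets are drawn here and recorded in ``truth``.
    """
    rng = _rng(config, 3)
    names = list(truth.feature_roles["feature"])
    n_feat = len(names)
    n_inf = config.n_informative_features
    n_red = config.n_redundant_features
    sigma_well = config.well_level_sd

    for pid in plate_maps["plate_id"].unique():
        truth.plate_offsets[pid] = rng.normal(0.0, config.plate_effect_sd, n_feat)
    for bid in plate_maps["batch_id"].unique():
        truth.batch_offsets[bid] = rng.normal(0.0, config.batch_effect_sd, n_feat)

    nb_n = config.cells_per_well_size
    nb_p = nb_n / (nb_n + config.cells_per_well_mean)

    blocks: List[np.ndarray] = []
    meta_plate: List[str] = []
    meta_batch: List[str] = []
    meta_well: List[str] = []
    meta_qc: List[np.ndarray] = []

    for row in plate_maps.itertuples(index=False):
        n_cells = int(rng.negative_binomial(nb_n, nb_p))
        if n_cells == 0:
            continue
        u = rng.random(n_cells)
        qc = np.where(
            u < config.frac_dead,
            QC_DEAD,
            np.where(u < config.frac_dead + config.frac_missegmented, QC_MISSEGMENTED, QC_LIVE),
        )
        mean_vec = (
            truth.baseline
            + truth.plate_offsets[row.plate_id]
            + truth.batch_offsets[row.batch_id]
        )
        if row.compound_id != DMSO and truth.compound_active.get(row.compound_id, False):
            mult = truth.effect_multiplier(row.compound_id, row.concentration_uM)
            mean_vec = mean_vec + (
                config.effect_size_active
                * truth.compound_magnitude[row.compound_id]
                * mult
                * sigma_well
                * truth.compound_direction[row.compound_id]
            )
        x = np.empty((n_cells, n_feat))
        # informative + noise features: independent per-cell noise
        base_cols = np.r_[0:n_inf, n_inf + n_red : n_feat]
        x[:, base_cols] = mean_vec[base_cols] + rng.normal(
            0.0, config.cell_noise_sd, (n_cells, len(base_cols))
        )
        # redundant features: affine copies of informative parents
        if n_red:
            parent_idx = np.arange(n_red) % n_inf
            eps_sd = config.redundant_noise_frac * config.cell_noise_sd
            x[:, n_inf : n_inf + n_red] = (
                truth.redundant_slope * x[:, parent_idx]
                + truth.redundant_intercept
                + rng.normal(0.0, eps_sd, (n_cells, n_red))
            )
        x[qc == QC_DEAD] += config.dead_shift
        x[qc == QC_MISSEGMENTED] -= config.dead_shift

        blocks.append(x)
        meta_plate.extend([row.plate_id] * n_cells)
        meta_batch.extend([row.batch_id] * n_cells)
        meta_well.extend([row.well] * n_cells)
        meta_qc.append(qc)

    if blocks:
        feats = np.vstack(blocks)
        qc_all = np.concatenate(meta_qc)
    else:
        feats = np.empty((0, n_feat))
        qc_all = np.array([], dtype=object)
    cells = pd.DataFrame(
        {
            "plate_id": pd.Series(meta_plate, dtype="object"),
            "batch_id": pd.Series(meta_batch, dtype="object"),
            "well": pd.Series(meta_well, dtype="object"),
            "cell_id": np.arange(len(qc_all)),
            "qc_label": qc_all,
        }
    )
    cells = pd.concat([cells, pd.DataFrame(feats, columns=names)], axis=1)
    return cells


@dataclass
class SimulatedScreen:
    config: ScreenConfig
    annotations: pd.DataFrame
    truth: GroundTruth
    plate_maps: pd.DataFrame
    cells: pd.DataFrame


def simulate_screen(config: ScreenConfig) -> SimulatedScreen:
    """Run library generation, plate layout and cell simulation end to end."""
    annotations, truth = generate_library(config)
    plate_maps = generate_plate_maps(config)
    cells = simulate_cells(plate_maps, truth, config)
    return SimulatedScreen(config, annotations, truth, plate_maps, cells)
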