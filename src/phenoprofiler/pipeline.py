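"""End-to-end pipeline orchestration with provenance.

Runs simulate -> preprocess -> select-features -> call-active -> moa-auc
(-> subset analyses) in order, records a manifest (config, seeds, stage
outputs, versions), and optionally writes every intermediate to disk as a
columnar binary table with a delimited-text mirror for inspection.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .activity import ActivityThresholds, call_active, compound_activity
from .config import ScreenConfig
from .feature_select import (
    SignatureSpec,
    compute_relevance,
    mrmr_rank,
    prefilter_wells,
    select_signature,
)
from .moa_eval import evaluate_moas, permutation_significance
from .preprocess import aggregate_wells, filter_live, normalize
from .synthgen import simulate_screen

logger = logging.getLogger(__name__)

MIN_CELLS = 100


def config_hash(config: ScreenConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: ScreenConfig
    annotations: pd.DataFrame
    truth: object
    plate_maps: pd.DataFrame
    profiles: pd.DataFrame  # normalized well profiles
    signature: SignatureSpec
    thresholds: ActivityThresholds
    calls: pd.DataFrame
    actives: pd.DataFrame
    moa_results: pd.DataFrame
    manifest: Dict = field(default_factory=dict)

    @property
    def compound_active(self) -> pd.Series:
        return compound_activity(self.calls)


def run_pipeline(
    config: ScreenConfig,
    n_perm: int = 1000,
    outdir: Optional[str | Path] = None,
    signature_kwargs: Optional[dict] = None,
    min_cells: int = MIN_CELLS,
) -> PipelineResult:
    """Execute the full analysis on a simulated screen.

    Active calling excludes wells removed by the ``min_cells`` prefilter
    (replicate denominators shrink accordingly); feature selection
    additionally removes wells indistinguishable from vehicle.
    """
    t0 = time.time()
    manifest: Dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name: str) -> None:
        manifest["stages"][name] = {"t_elapsed_s": round(time.time() - t0, 2)}
        logger.info("stage %s done (%.1fs)", name, time.time() - t0)

    screen = simulate_screen(config)
    stage("simulate")

    live = filter_live(screen.cells)
    wells = aggregate_wells(live, screen.plate_maps)
    profiles = normalize(wells)
    stage("preprocess")

    prefiltered = prefilter_wells(profiles, min_cells=min_cells)
    relevance = compute_relevance(prefiltered)
    ranking = mrmr_rank(prefiltered, relevance)
    signature = select_signature(
        ranking, prefiltered, cell_line=config.cell_line,
        seed=config.seed, **(signature_kwargs or {}),
    )
    stage("select-features")

    usable = profiles[profiles["n_live"] >= min_cells]
    calls, thresholds = call_active(usable, signature, seed=config.seed)
    actives = calls[calls["active"]].reset_index(drop=True)
    stage("call-active")

    moa_results = evaluate_moas(
        actives, screen.annotations, signature.features, cell_line=config.cell_line
    )
    if n_perm > 0 and not moa_results.empty:
        moa_results = permutation_significance(
            moa_results, actives, screen.annotations, signature.features,
            n_perm=n_perm, seed=config.seed,
        )
    stage("moa-auc")

    result = PipelineResult(
        config=config,
        annotations=screen.annotations,
        truth=screen.truth,
        plate_maps=screen.plate_maps,
        profiles=profiles,
        signature=signature,
        thresholds=thresholds,
        calls=calls,
        actives=actives,
        moa_results=moa_results,
        manifest=manifest,
    )
    if outdir is not None:
        write_artifacts(result, Path(outdir))
    return result


def _write_table(df: pd.DataFrame, base: Path) -> List[str]:
    """Columnar binary plus delimited-text mirror."""
    paths = []
    try:
        df.to_parquet(base.with_suffix(".parquet"))
        paths.append(str(base.with_suffix(".parquet")))
    except Exception:  # pragma: no cover - parquet backend missing
        pass
    df.to_csv(base.with_suffix(".csv"), index=False)
    paths.append(str(base.with_suffix(".csv")))
    return paths


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    m = result.manifest
    m["outputs"] = {}
    m["outputs"]["plate_maps"] = _write_table(result.plate_maps, outdir / "plate_maps")
    m["outputs"]["annotations"] = _write_table(result.annotations, outdir / "annotations")
    m["outputs"]["wells"] = _write_table(result.profiles, outdir / "wells")
    result.signature.to_json(outdir / "signature.json")
    m["outputs"]["signature"] = [str(outdir / "signature.json")]
    m["outputs"]["activity"] = _write_table(result.calls, outdir / "activity")
    m["outputs"]["moa_results"] = _write_table(result.moa_results, outdir / "moa_results")
    m["thresholds"] = {
        "tau": result.thresholds.tau,
        "rho_null": result.thresholds.rho_null,
        "n_null_pairs_used": result.thresholds.n_null_pairs_used,
    }
    (outdir / "manifest.json").write_text(json.dumps(m, indent=2))
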