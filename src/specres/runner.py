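"""Study orchestration: experiments x matrix ladder x reconstruction ladder.

``run_experiment`` simulates one acquisition per (experiment, seed) at the
fine acquisition matrix, rebins the *same* projections down the matrix
ladder (coarser matrices are never re-acquired), reconstructs every ladder
entry, measures every analyzed source and aggregates a tidy results table.
OSEM entries that share a subset count are produced from a single run with
iteration snapshots, which is exactly equivalent to separate runs because
the subset schedule is deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .acquisition import (COUNTS_PER_VIEW, SinogramSet, rebin,
                          simulate_acquisition)
from .grid import GridSpec, MATRIX_LADDER
from .metrics import SourceNotFoundError, resolution_record
from .phantom import BackgroundSpec, build_layout, compose_phantom
from .projector import CollimatorResponse, OrbitGeometry
from .recon import IT_SUB_LADDER, ReconConfig, ReconVolume, fbp, reconstruct

log = logging.getLogger("specres")

EXPERIMENT_KINDS = {"A": "warm", "B": "air", "C": "cold"}
_DEFAULT_RADII = {"A": tuple(range(2, 11)), "B": tuple(range(2, 12)),
                  "C": tuple(range(2, 11))}
#: sources used in the analysis (outer sources are imaged but excluded)
ANALYSIS_RADII_CM = tuple(range(2, 10))


@dataclass(frozen=True)
class ExperimentConfig:
    """Full study description for one experiment kind."""

    experiment: str = "B"
    matrices: tuple = MATRIX_LADDER
    n_views: int = 360
    counts_per_view: float | None = COUNTS_PER_VIEW  # None -> noise-free
    it_sub: tuple = IT_SUB_LADDER
    include_fbp: bool | None = None  # None -> only experiment B
    seed: int = 0
    radii_cm: tuple | None = None
    analysis_radii_cm: tuple = ANALYSIS_RADII_CM
    acq_matrix: int = 256
    acq_voxel_mm: float = 0.9
    orbit_radius_mm: float = 250.0
    rr: bool = True
    ac: bool = True
    sc: bool = True
    half_length_mm: float | None = None  # None -> 40 warm, 25 air/cold
    half_length_fbp_mm: float = 40.0
    save_artifacts: bool = True

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_KINDS:
            raise ValueError(f"experiment must be A, B or C, got {self.experiment!r}")
        for m in self.matrices:
            if self.acq_matrix % m:
                raise ValueError(f"matrix {m} does not divide acquisition matrix")

    @property
    def kind(self) -> str:
        return EXPERIMENT_KINDS[self.experiment]

    @property
    def source_radii_cm(self) -> tuple:
        return self.radii_cm if self.radii_cm is not None else _DEFAULT_RADII[self.experiment]

    @property
    def fbp_enabled(self) -> bool:
        return self.experiment == "B" if self.include_fbp is None else self.include_fbp

    def profile_half_length(self, algorithm: str) -> float:
        if algorithm == "FBP":
            return self.half_length_fbp_mm
        if self.half_length_mm is not None:
            return self.half_length_mm
        return 40.0 if self.kind == "warm" else 25.0


@dataclass
class ExperimentResult:
    table: pd.DataFrame
    layout: list
    sinograms: dict
    volumes: dict
    config: ExperimentConfig


def _osem_groups(ladder) -> dict[int, list[int]]:
    """Group the IT ladder by subset count -> sorted iteration snapshots."""
    groups: dict[int, list[int]] = {}
    for it, sub in ladder:
        groups.setdefault(sub, []).append(it)
    return {sub: sorted(set(its)) for sub, its in groups.items()}


def simulate_experiment(cfg: ExperimentConfig) -> tuple[SinogramSet, list]:
    """Acquire the experiment's fine-matrix sinogram and the source layout."""
    grid = GridSpec(cfg.acq_matrix, cfg.acq_voxel_mm)
    layout = build_layout(cfg.source_radii_cm, grid)
    background = BackgroundSpec(cfg.kind)
    phantom = compose_phantom(layout, background, grid)
    geom = OrbitGeometry(n_views=cfg.n_views, n_bins=cfg.acq_matrix,
                         bin_mm=cfg.acq_voxel_mm,
                         orbit_radius_mm=cfg.orbit_radius_mm)
    t0 = time.perf_counter()
    sino = simulate_acquisition(phantom, geom, CollimatorResponse(),
                                counts_per_view=cfg.counts_per_view, seed=cfg.seed)
    log.info("simulated experiment %s: %d views x %d bins in %.1f s",
             cfg.experiment, geom.n_views, geom.n_bins, time.perf_counter() - t0)
    return sino, layout


def _analyze(cfg: ExperimentConfig, vol: ReconVolume, layout, rcfg: ReconConfig,
             matrix: int, rows: list) -> None:
    half = cfg.profile_half_length(rcfg.algorithm)
    # search window must enclose the blob: scale with the profile extent
    search = max(15.0, min(25.0, half / 2.0))
    by_radius = {s.radius_cm: s for s in layout}
    for r in cfg.analysis_radii_cm:
        src = by_radius.get(float(r), by_radius.get(r))
        if src is None:
            continue
        base = dict(experiment=cfg.experiment, matrix=matrix,
                    algorithm=rcfg.algorithm, iterations=rcfg.iterations,
                    subsets=rcfg.subsets,
                    it_sub=rcfg.it_sub if rcfg.algorithm == "OSEM" else 0,
                    radius_cm=float(r))
        try:
            rec = resolution_record(vol, src.center_mm, float(r),
                                    half_length_mm=half, source_id=f"r{r}",
                                    search_radius_mm=search)
            rows.append({**base, "rr_mm": rec.rr_mm, "tr_mm": rec.tr_mm,
                         "mean_mm": rec.mean_mm, "rr_err_mm": rec.rr_err_mm,
                         "tr_err_mm": rec.tr_err_mm, "valid": rec.valid})
        except (SourceNotFoundError, ValueError) as exc:
            log.warning("source r=%s cm failed (%s %s): %s", r, rcfg.algorithm,
                        rcfg.label(), exc)
            rows.append({**base, "rr_mm": np.nan, "tr_mm": np.nan,
                         "mean_mm": np.nan, "rr_err_mm": np.nan,
                         "tr_err_mm": np.nan, "valid": False})


def run_experiment(cfg: ExperimentConfig, outdir=None) -> ExperimentResult:
    """Run one experiment across its matrix and reconstruction ladders."""
    sino256, layout = simulate_experiment(cfg)
    background = BackgroundSpec(cfg.kind)
    rows: list[dict] = []
    sinograms: dict[int, SinogramSet] = {}
    volumes: dict[tuple, ReconVolume] = {}

    for matrix in cfg.matrices:
        factor = cfg.acq_matrix // matrix
        s = sino256
        while factor > 1:  # 256 -> 128 -> 64 by repeated pairwise rebinning
            s = rebin(s, 2)
            factor //= 2
        sinograms[matrix] = s

        if cfg.fbp_enabled:
            rcfg = ReconConfig(algorithm="FBP")
            vol = fbp(s, rcfg)
            volumes[(matrix, rcfg.label())] = vol
            _analyze(cfg, vol, layout, rcfg, matrix, rows)

        for sub, its in _osem_groups(cfg.it_sub).items():
            if cfg.n_views % sub:
                log.warning("skipping SUB=%d: does not divide %d views", sub,
                            cfg.n_views)
                continue
            snapshots: dict[int, np.ndarray] = {}
            want = set(its)

            def keep(it, x, want=want, snapshots=snapshots):
                if it in want:
                    snapshots[it] = x.copy()

            rcfg_full = ReconConfig(algorithm="OSEM", iterations=max(its),
                                    subsets=sub, rr=cfg.rr, ac=cfg.ac, sc=cfg.sc)
            t0 = time.perf_counter()
            reconstruct(s, rcfg_full, background=background, callback=keep)
            log.info("OSEM sub=%d it<=%d at %d: %.1f s", sub, max(its), matrix,
                     time.perf_counter() - t0)
            for it in its:
                rcfg = replace(rcfg_full, iterations=it)
                vol = ReconVolume(snapshots[it], GridSpec(matrix, s.geometry.bin_mm),
                                  {"config": rcfg, "seed": s.seed})
                volumes[(matrix, rcfg.label())] = vol
                _analyze(cfg, vol, layout, rcfg, matrix, rows)

    table = pd.DataFrame(rows)
    result = ExperimentResult(table, layout, sinograms, volumes, cfg)
    if outdir is not None:
        _persist(result, Path(outdir))
    return result


def _persist(result: ExperimentResult, outdir: Path) -> None:
    cfg = result.config
    base = outdir / cfg.experiment
    base.mkdir(parents=True, exist_ok=True)
    sio.write_table(base / "results.csv", result.table)
    manifest = {
        "config": sio._jsonable(cfg),
        "sources": [{"radius_cm": s.radius_cm, "azimuth_deg": s.azimuth_deg}
                    for s in result.layout],
        "numpy": np.__version__,
    }
    (base / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if cfg.save_artifacts:
        for matrix, s in result.sinograms.items():
            d = base / str(matrix)
            d.mkdir(exist_ok=True)
            sio.write_sinogram(d / "sinogram.nii.gz", s)
        for (matrix, label), vol in result.volumes.items():
            d = base / str(matrix)
            d.mkdir(exist_ok=True)
            sio.write_volume(d / f"{label}.nii.gz", vol)
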