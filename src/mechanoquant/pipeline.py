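"""End-to-end orchestration: synthetic scenes -> quantification -> statistics.

A run is described by a single config mapping (YAML/JSON-serializable) with
a stage list and per-stage parameter sections. Every run writes into its own
directory: per-cell CSVs, masks and maps as TIFFs, a plain-text log, and a
snapshot of the fully resolved config (all defaults filled in), so the
parameters behind any output file are always recoverable. Reruns with the
same config and seed are byte-identical on all CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import fretindex, imgquant, synthgen, stats_qpcr, tfm as tfm_mod
from .containers import ChannelImage, FretCalibration, LabelMask, Substrate

__all__ = ["RunConfig", "ConfigError", "run"]

_CSV_FLOAT = "%.10g"
KNOWN_STAGES = ("synth_nc", "synth_fret", "synth_tfm", "ncquant", "fret", "tfm", "stats")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any processing)."""


@dataclass
class RunConfig:
    """Serializable description of a pipeline run."""

    stages: list[str]
    seed: int = 0
    out_dir: str = "run"
    params: dict[str, dict[str, Any]] = dc_field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            stages=doc.get("stages", []),
            seed=int(doc.get("seed", 0)),
            out_dir=doc.get("out_dir", "run"),
            params={k: dict(v) for k, v in doc.get("params", {}).items()},
        )

    def validate(self) -> None:
        if not self.stages:
            raise ConfigError("no stages requested")
        for s in self.stages:
            if s not in KNOWN_STAGES:
                raise ConfigError(f"unknown stage {s!r}; known: {KNOWN_STAGES}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        tfm_p = self.params.get("tfm", {})
        if tfm_p.get("regularization", 1e-4) < 0:
            raise ConfigError("regularization must be >= 0")
        if tfm_p.get("youngs_modulus", 1e4) <= 0:
            raise ConfigError("Young's modulus must be > 0")
        if not (0.0 <= tfm_p.get("poisson_ratio", 0.5) <= 0.5):
            raise ConfigError("Poisson ratio must be in [0, 0.5]")
        ring = self.params.get("ncquant", {}).get("ring_width_px", 5)
        if ring < 1:
            raise ConfigError("ring width must be >= 1 px")
        for stage in self.stages:
            p = self.params.get(stage, {})
            for key in ("dapi", "stain", "actin", "deformed", "relaxed", "mask", "cells_csv"):
                if key in p and not Path(p[key]).exists():
                    raise ConfigError(f"{stage}: input path {p[key]!r} does not exist")

    def snapshot(self) -> dict[str, Any]:
        return {
            "stages": list(self.stages),
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "params": {k: dict(v) for k, v in self.params.items()},
        }


def _read_channel(path: Path, pixel_size: float, name: str) -> ChannelImage:
    return ChannelImage(tifffile.imread(path).astype(float), pixel_size, name)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FLOAT, lineterminator="\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_synth_nc(cfg: RunConfig, run_dir: Path, log: logging.Logger) -> None:
    p = dict(cfg.params.get("synth_nc", {}))
    p.setdefault("n_cells", 5)
    p.setdefault("noise_sd", 5.0)
    dapi, stain, actin, gt = synthgen.make_nc_scene(seed=cfg.seed, **p)
    out = synthgen.write_scene(run_dir / "scene_nc", {"dapi": dapi, "stain": stain, "actin": actin}, gt)
    log.info("synth_nc: wrote %s (%d nuclei)", out, len(gt.nuclei))


def _stage_synth_fret(cfg: RunConfig, run_dir: Path, log: logging.Logger) -> None:
    p = dict(cfg.params.get("synth_fret", {}))
    p.setdefault("fret_true", 0.3)
    p.setdefault("dL_true", 0.6)
    p.setdefault("aL_true", 0.12)
    common = {k: p[k] for k in ("shape", "noise_sd", "background_true") if k in p}
    trip, gt = synthgen.make_fret_triplet(
        p["fret_true"], p["dL_true"], p["aL_true"], seed=cfg.seed,
        **{k: v for k, v in p.items() if k not in ("fret_true", "dL_true", "aL_true")},
    )
    synthgen.write_scene(
        run_dir / "scene_fret",
        {"donor": trip.donor, "fret": trip.fret, "acceptor": trip.acceptor},
        gt,
    )
    don, gt_d = synthgen.make_donor_only_control(p["dL_true"], seed=cfg.seed + 1, **common)
    acc, gt_a = synthgen.make_acceptor_only_control(p["aL_true"], seed=cfg.seed + 2, **common)
    synthgen.write_scene(
        run_dir / "scene_fret_donor_only",
        {"donor": don.donor, "fret": don.fret, "acceptor": don.acceptor}, gt_d,
    )
    synthgen.write_scene(
        run_dir / "scene_fret_acceptor_only",
        {"donor": acc.donor, "fret": acc.fret, "acceptor": acc.acceptor}, gt_a,
    )
    log.info("synth_fret: wrote main triplet and single-fluorophore controls")


def _stage_synth_tfm(cfg: RunConfig, run_dir: Path, log: logging.Logger) -> None:
    p = dict(cfg.params.get("synth_tfm", {}))
    shape = tuple(p.get("shape", (512, 512)))
    substrate = Substrate(
        youngs_modulus=p.get("youngs_modulus", 1e4),
        poisson_ratio=p.get("poisson_ratio", 0.5),
        regularization=p.get("regularization", 1e-4),
    )
    traction = synthgen.traction_dipole(
        shape,
        peak_pa=p.get("peak_pa", 300.0),
        sigma_um=p.get("sigma_um", 3.0),
        separation_um=p.get("separation_um", 15.0),
        pixel_size=p.get("pixel_size", 0.1),
    )
    deformed, relaxed, mask, gt = synthgen.make_tfm_pair(
        traction, substrate,
        bead_density=p.get("bead_density", 1.0),
        noise_sd=p.get("noise_sd", 2.0),
        seed=cfg.seed,
    )
    out = synthgen.write_scene(
        run_dir / "scene_tfm", {"beads_deformed": deformed, "beads_relaxed": relaxed}, gt
    )
    tifffile.imwrite(out / "cell_mask.tif", mask.labels.astype(np.int32))
    log.info("synth_tfm: wrote %s", out)


def _stage_ncquant(cfg: RunConfig, run_dir: Path, log: logging.Logger) -> None:
    p = dict(cfg.params.get("ncquant", {}))
    px = p.get("pixel_size", 0.1)
    scene = run_dir / "scene_nc"
    dapi = _read_channel(Path(p.get("dapi", scene / "dapi.tif")), px, "dapi")
    stain = _read_channel(Path(p.get("stain", scene / "stain.tif")), px, "stain")
    seg = imgquant.segment_nuclei(dapi, imgquant.SegmentationParams(**p.get("canny", {})))
    rings = imgquant.ring_mask(seg, width_px=p.get("ring_width_px", 5))
    records = imgquant.nc_ratio(stain, seg, rings)
    df = pd.DataFrame([r.as_dict() for r in records])
    df = df.rename(columns={"nuclear_area": "nuclear_area_um2", "cell_area": "cell_area_um2"})

    actin_path = Path(p.get("actin", scene / "actin.tif"))
    areas: list[float] = []
    if actin_path.exists():
        actin = _read_channel(actin_path, px, "actin")
        area_mask, areas = imgquant.cell_area(actin, threshold=p.get("actin_threshold"))
        tifffile.imwrite(run_dir / "cell_area_mask.tif", area_mask.labels.astype(np.int32))
    _write_csv(df, run_dir / "cells.csv")
    _write_csv(
        pd.DataFrame({"cell_id": np.arange(1, len(areas) + 1), "cell_area_um2": areas}),
        run_dir / "cell_areas.csv",
    )
    tifffile.imwrite(run_dir / "nuclei_mask.tif", seg.labels.astype(np.int32))
    tifffile.imwrite(run_dir / "ring_mask.tif", rings.labels.astype(np.int32))
    log.info("ncquant: %d nuclei, %d cell footprints", seg.n_labels, len(areas))


def _stage_fret(cfg: RunConfig, run_dir: Path, log: logging.Logger) -> None:
    p = dict(cfg.params.get("fret", {}))
    px = p.get("pixel_size", 0.1)

    def load_triplet(d: Path) -> "fretindex.FretTriplet":
        from .containers import FretTriplet

        return FretTriplet(
            _read_channel(d / "donor.tif", px, "donor"),
            _read_channel(d / "fret.tif", px, "fret"),
            _read_channel(d / "acceptor.tif", px, "acceptor"),
        )

    smooth = p.get("smooth", "box3")
    donor_dir = Path(p.get("donor_only", run_dir / "scene_fret_donor_only"))
    acc_dir = Path(p.get("acceptor_only", run_dir / "scene_fret_acceptor_only"))
    cal_d = fretindex.calibrate_bleedthrough(
        fretindex.correct_channels(load_triplet(donor_dir), smooth=smooth), "donor-only"
    )
    cal_a = fretindex.calibrate_bleedthrough(
        fretindex.correct_channels(load_triplet(acc_dir), smooth=smooth), "acceptor-only"
    )
    cal = FretCalibration.merge(cal_d, cal_a)
    (run_dir / "fret_calibration.json").write_text(json.dumps(cal.as_dict(), indent=2, sort_keys=True))

    main_dir = Path(p.get("triplet", run_dir / "scene_fret"))
    corrected = fretindex.correct_channels(load_triplet(main_dir), smooth=smooth)
    result = fretindex.compute_fret_index(corrected, cal)
    mean_fret, adh = fretindex.adhesion_mean_fret(result, corrected.acceptor)
    tifffile.imwrite(run_dir / "fret_index.tif", np.nan_to_num(result.index_map).astype(np.float32))
    tifffile.imwrite(run_dir / "adhesion_mask.tif", adh.labels.astype(np.int32))
    _write_csv(
        pd.DataFrame(
            [{
                "cell_id": 1,
                "mean_fret": mean_fret,
                "n_adhesion_px": int((adh.labels > 0).sum()),
                "normalized_fret": result.normalized_fret,
                "status": result.status,
            }]
        ),
        run_dir / "fret_cells.csv",
    )
    log.info("fret: dL=%.4f aL=%.4f mean_fret=%.4f", cal.dL, cal.aL, mean_fret)


def _stage_tfm(cfg: RunConfig, run_dir: Path, log: logging.Logger) -> None:
    p = dict(cfg.params.get("tfm", {}))
    px = p.get("pixel_size", 0.1)
    scene = run_dir / "scene_tfm"
    deformed = _read_channel(Path(p.get("deformed", scene / "beads_deformed.tif")), px, "deformed")
    relaxed = _read_channel(Path(p.get("relaxed", scene / "beads_relaxed.tif")), px, "relaxed")
    mask = LabelMask(
        tifffile.imread(Path(p.get("mask", scene / "cell_mask.tif"))).astype(np.int32), px
    )
    substrate = Substrate(
        youngs_modulus=p.get("youngs_modulus", 1e4),
        poisson_ratio=p.get("poisson_ratio", 0.5),
        regularization=p.get("regularization", 1e-4),
        regularization_mode=p.get("regularization_mode", "relative"),
    )
    disp = tfm_mod.estimate_displacement(
        deformed, relaxed,
        window_px=p.get("window_px", 32),
        overlap=p.get("overlap", 0.5),
    )
    traction = tfm_mod.invert_fttc(disp, substrate)
    per_cell = tfm_mod.avg_traction_stress(traction, mask)

    h, w = disp.shape
    grid = pd.DataFrame(
        {
            "node_y": np.repeat(np.arange(h), w),
            "node_x": np.tile(np.arange(w), h),
            "u_y_um": disp.vectors[..., 0].ravel(),
            "u_x_um": disp.vectors[..., 1].ravel(),
            "t_y_Pa": traction.vectors[..., 0].ravel(),
            "t_x_Pa": traction.vectors[..., 1].ravel(),
        }
    )
    _write_csv(grid, run_dir / "tfm_fields.csv")
    _write_csv(per_cell, run_dir / "tfm_cells.csv")
    tifffile.imwrite(run_dir / "traction_magnitude.tif", traction.magnitude().astype(np.float32))
    log.info("tfm: %d cells, peak |t|=%.1f Pa", len(per_cell), traction.magnitude().max())


def _stage_stats(cfg: RunConfig, run_dir: Path, log: logging.Logger) -> None:
    p = dict(cfg.params.get("stats", {}))
    csv_path = Path(p.get("cells_csv", run_dir / "cells.csv"))
    value_col = p.get("value_column", "nc_ratio")
    group_col = p.get("group_column", "group")
    df = pd.read_csv(csv_path)
    if group_col not in df.columns:
        raise ConfigError(f"stats: column {group_col!r} not in {csv_path}")
    groups = {
        str(g): sub[value_col].dropna().to_numpy()
        for g, sub in df.groupby(group_col, sort=True)
    }
    comp = stats_qpcr.compare_groups(groups, dunn_adjust=p.get("dunn_adjust", "bonferroni"))
    (run_dir / "stats_report.txt").write_text(comp.summary() + "\n")
    _write_csv(comp.pairwise_p.reset_index(names="group"), run_dir / "stats_pairwise_p.csv")
    log.info("stats: %s omnibus p=%.4g", comp.chosen_test, comp.omnibus_p)


_STAGE_FNS: dict[str, Callable[[RunConfig, Path, logging.Logger], None]] = {
    "synth_nc": _stage_synth_nc,
    "synth_fret": _stage_synth_fret,
    "synth_tfm": _stage_synth_tfm,
    "ncquant": _stage_ncquant,
    "fret": _stage_fret,
    "tfm": _stage_tfm,
    "stats": _stage_stats,
}


def run(config: RunConfig) -> Path:
    """Validate the config, execute the requested stages, return the run dir.

    Stage failures are logged with the stage name and re-raised after the
    remaining *independent* stages (those not consuming the failed stage's
    outputs) have been attempted; the resolved config snapshot is always
    written first so a failed run is still reproducible.
    """
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config_snapshot.yaml").write_text(
        yaml.safe_dump(config.snapshot(), sort_keys=True)
    )

    log = logging.getLogger("mechanoquant.run")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fh = logging.FileHandler(run_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.addHandler(logging.StreamHandler())

    errors: list[tuple[str, Exception]] = []
    failed: set[str] = set()
    depends = {"ncquant": "synth_nc", "fret": "synth_fret", "tfm": "synth_tfm"}
    try:
        for stage in config.stages:
            dep = depends.get(stage)
            if dep in failed:
                log.error("skipping stage %s: dependency %s failed", stage, dep)
                continue
            try:
                _STAGE_FNS[stage](config, run_dir, log)
            except Exception as exc:  # noqa: BLE001 - reported per stage
                log.error("stage %s failed: %s", stage, exc)
                errors.append((stage, exc))
                failed.add(stage)
    finally:
        fh.close()
        log.handlers.clear()
    if errors:
        stage, exc = errors[0]
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return run_dir
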