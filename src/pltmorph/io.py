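"""Scene file I/O, measurement tables, and the end-to-end pipeline.

Scenes travel as integer label rasters — multi-page TIFF or MRC volumes —
with a JSON sidecar mapping label ids to organelle class names.  All CSV
outputs carry a comment header stamping the seed and configuration hash,
use UTF-8 with '.' decimals, and duplicate every area in nm^2 and
10^5 nm^2 columns so values can be read against published tables without
unit conversion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import diagnostic, stats, synthetic
from .morphometry import (
    AREA_SCALE,
    DEFAULT_CIRCULARITY_THRESHOLD,
    Group,
    LabelScene,
    OrganelleClass,
    PlateletRecord,
    measure_platelet,
)

__all__ = [
    "SceneFormatError",
    "read_scene",
    "write_scene",
    "measurements_frame",
    "platelets_frame",
    "write_csv",
    "read_measurements",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: fixed column order of the per-organelle measurement table
MEASUREMENT_COLUMNS = [
    "platelet_id", "group", "label_id", "class", "slice_index",
    "area_nm2", "area_1e5nm2", "perimeter_nm", "circularity", "abnormal",
]


class SceneFormatError(ValueError):
    """Scene file is not a readable integer label raster."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".classes.json")


def _read_mrc(path: Path) -> np.ndarray:
    import gemmi
    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True)
    if not np.allclose(data, np.round(data), atol=1e-3):
        raise SceneFormatError(f"{path}: MRC voxel values are not integers")
    return np.round(data).astype(np.int32)


def _write_mrc(path: Path, data: np.ndarray) -> None:
    import gemmi
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(data, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(*data.shape[::-1], 90, 90, 90)
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_scene(
    path,
    class_table_path=None,
    pixel_size_nm: float | None = None,
    group: Group | str | None = None,
) -> LabelScene:
    """Load a label scene (TIFF or MRC) plus its JSON class table.

    The class table defaults to the ``<scene>.classes.json`` sidecar.  A
    2D raster stored as a single-section volume is returned as 2D.  The
    sidecar may carry ``pixel_size_nm`` and ``metadata``; an explicit
    ``pixel_size_nm`` argument wins.
    """
    path = Path(path)
    class_table_path = Path(class_table_path) if class_table_path else _sidecar_path(path)
    if not class_table_path.exists():
        raise FileNotFoundError(f"class table not found: {class_table_path}")
    sidecar = json.loads(class_table_path.read_text())
    if "classes" in sidecar:
        table = {int(k): OrganelleClass(v) for k, v in sidecar["classes"].items()}
        meta = dict(sidecar.get("metadata", {}))
        px = pixel_size_nm or sidecar.get("pixel_size_nm")
    else:  # bare {label: class} mapping
        table = {int(k): OrganelleClass(v) for k, v in sidecar.items()}
        meta, px = {}, pixel_size_nm
    if px is None:
        raise ValueError(
            f"{path}: pixel size not in sidecar; pass pixel_size_nm explicitly"
        )

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        data = np.asarray(tifffile.imread(str(path)))
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data), atol=1e-3):
                raise SceneFormatError(f"{path}: TIFF values are not integers")
            data = np.round(data).astype(np.int32)
    elif suffix in (".mrc", ".map", ".ccp4"):
        data = _read_mrc(path)
    else:
        raise SceneFormatError(f"{path}: unknown scene format {suffix!r}")
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    if group is not None:
        meta["group"] = Group(group).value
    meta.setdefault("source_path", str(path))
    return LabelScene(label_map=data, pixel_size_nm=float(px),
                      class_table=table, metadata=meta)


def write_scene(scene: LabelScene, path, class_table_path=None) -> Path:
    """Write a scene as TIFF or MRC (by suffix) plus its JSON sidecar."""
    path = Path(path)
    data = scene.label_map
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(str(path), data.astype(np.int32))
    elif suffix in (".mrc", ".map", ".ccp4"):
        vol = data[None] if data.ndim == 2 else data
        _write_mrc(path, vol)
    else:
        raise SceneFormatError(f"{path}: unknown scene format {suffix!r}")
    sidecar = {
        "classes": {str(k): v.value for k, v in scene.class_table.items()},
        "pixel_size_nm": scene.pixel_size_nm,
        "metadata": {k: v for k, v in scene.metadata.items()
                     if isinstance(v, (str, int, float, bool, type(None)))},
    }
    sc_path = Path(class_table_path) if class_table_path else _sidecar_path(path)
    sc_path.write_text(json.dumps(sidecar, indent=1))
    return path


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

def measurements_frame(records: Iterable[PlateletRecord]) -> pd.DataFrame:
    """Per-organelle long table in the fixed column order."""
    rows = []
    for r in records:
        for m in r.organelles:
            rows.append((
                r.platelet_id, r.group.value if r.group else "",
                m.label_id, m.organelle_class.value, m.slice_index,
                m.area_nm2, m.area_nm2 / AREA_SCALE, m.perimeter_nm,
                m.circularity,
                "" if m.abnormal is None else bool(m.abnormal),
            ))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def platelets_frame(records: Iterable[PlateletRecord]) -> pd.DataFrame:
    """Per-platelet aggregate table (areas in both unit conventions)."""
    rows = []
    for r in records:
        row = dict(
            platelet_id=r.platelet_id,
            group=r.group.value if r.group else "",
            platelet_area_nm2=r.platelet_area_1e5nm2 * AREA_SCALE,
            platelet_area_1e5nm2=r.platelet_area_1e5nm2,
            n_abnormal_mito=r.n_abnormal_mito,
            has_ts=r.has_ts,
            is_ghost=r.is_ghost,
        )
        for cls in (OrganelleClass.ALPHA_GRANULE, OrganelleClass.DENSE_GRANULE,
                    OrganelleClass.GAMMA_GRANULE, OrganelleClass.MITOCHONDRION):
            short = cls.value.split("_")[0]
            row[f"{short}_count"] = r.count(cls)
            row[f"{short}_avg_area_1e5nm2"] = r.avg_area(cls)
            row[f"{short}_area_fraction"] = r.area_fraction(cls)
        rows.append(row)
    return pd.DataFrame(rows)


def write_csv(frame: pd.DataFrame, path, seed=None, config_hash=None) -> Path:
    """CSV with a provenance comment header (seed + config hash)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# pltmorph seed={seed} config={config_hash}\n")
        frame.to_csv(fh, index=False)
    return path


def read_measurements(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run configuration (simulate -> measure -> stats -> design)."""

    out_dir: str = "pltmorph_out"
    seed: int = 0
    synthetic: synthetic.SyntheticCohortConfig = dataclasses.field(
        default_factory=synthetic.SyntheticCohortConfig)
    circularity_threshold: float = DEFAULT_CIRCULARITY_THRESHOLD
    tests: tuple[str, ...] = ("student_t", "mann_whitney")
    n_test: int = 12
    alpha: float = 0.05
    detection_target: float = 0.95
    write_scenes: bool = False
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = dict(
            seed=self.seed, synthetic=self.synthetic.to_dict(),
            circularity_threshold=self.circularity_threshold,
            tests=list(self.tests), n_test=self.n_test, alpha=self.alpha,
            detection_target=self.detection_target,
        )
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "synthetic" in d:
            d["synthetic"] = synthetic.SyntheticCohortConfig.from_dict(d["synthetic"])
        if "tests" in d:
            d["tests"] = tuple(d["tests"])
        return cls(**d)


def _setup_run_logging(out_dir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("pltmorph")
    root.setLevel(level.upper())
    root.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        root.addHandler(logging.StreamHandler(sys.stderr))
    return handler


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Simulate a cohort, measure it, and write every output table.

    Outputs: manifest.csv, organelles.csv, platelets.csv, summary.csv,
    comparisons.csv, prevalences.csv, diagnostic.json and run.log, all
    under ``config.out_dir`` and stamped with the seed and config hash.
    Deterministic for a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out, config.log_level)
    try:
        return _run_pipeline_inner(config, out)
    finally:
        logging.getLogger("pltmorph").removeHandler(handler)
        handler.close()


def _run_pipeline_inner(config: PipelineConfig, out: Path) -> dict[str, Path]:
    chash = config.config_hash()
    scfg = dataclasses.replace(config.synthetic, seed=config.seed)
    logger.info("pipeline start: seed=%d config=%s", config.seed, chash)

    scene_dir = out / "scenes"
    if config.write_scenes:
        scene_dir.mkdir(exist_ok=True)
    records: list[PlateletRecord] = []
    manifest_rows = []
    for scene, gt in synthetic.iter_cohort(scfg):
        try:
            rec = measure_platelet(
                scene, gt.group,
                circularity_threshold=config.circularity_threshold,
                platelet_id=gt.scene_id,
            )
        except Exception as e:
            raise RuntimeError(
                f"measurement stage failed on scene {gt.scene_id}: {e}"
            ) from e
        records.append(rec)
        manifest_rows.append(dict(
            scene_id=gt.scene_id, group=gt.group.value,
            n_labels=len(gt.table), is_ghost_truth=gt.is_ghost,
            n_abnormal_truth=gt.n_abnormal,
        ))
        if config.write_scenes:
            write_scene(scene, scene_dir / f"{gt.scene_id}.tif")
    logger.info("measured %d platelets", len(records))

    paths: dict[str, Path] = {}
    paths["manifest"] = write_csv(pd.DataFrame(manifest_rows),
                                  out / "manifest.csv", config.seed, chash)
    paths["organelles"] = write_csv(measurements_frame(records),
                                    out / "organelles.csv", config.seed, chash)
    paths["platelets"] = write_csv(platelets_frame(records),
                                   out / "platelets.csv", config.seed, chash)

    summary = stats.cohort_summary(records, tests=config.tests,
                                   alpha=config.alpha)
    paths["summary"] = write_csv(summary.summaries, out / "summary.csv",
                                 config.seed, chash)
    paths["comparisons"] = write_csv(summary.comparisons,
                                     out / "comparisons.csv", config.seed, chash)
    paths["prevalences"] = write_csv(summary.prevalences,
                                     out / "prevalences.csv", config.seed, chash)

    pre = [r for r in records if r.group is Group.PRE_AML]
    nonmal = [r for r in records if r.group in
              (Group.UNIRRADIATED_WT, Group.CONTROL_1WK, Group.CONTROL_3WK)]
    design_path = out / "diagnostic.json"
    if pre and nonmal:
        k = sum(1 for r in pre if r.n_abnormal_mito > 0)
        n_neg = sum(1 for r in nonmal if r.n_abnormal_mito == 0)
        design = diagnostic.screening_report(
            k=k, n_pre=len(pre), n_negatives=n_neg,
            n_test=config.n_test, alpha=config.alpha,
            target=config.detection_target,
        )
        payload = json.loads(design.to_json())
        payload["_provenance"] = {"seed": config.seed, "config": chash}
        design_path.write_text(json.dumps(payload, indent=1))
        paths["diagnostic"] = design_path
        logger.info("screening design: p=%.4f detection(n=%d)=%.4f fp<=%.4f",
                    design.p, config.n_test, design.detection_probability,
                    design.fp_upper_bound)
    else:
        logger.warning("cohort lacks pre-AML or non-malignant groups; "
                       "no diagnostic design written")
    logger.info("pipeline done: %d outputs in %s", len(paths), out)
    return paths
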