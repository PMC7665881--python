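"""End-to-end orchestration: simulate -> reconstruct -> segment -> features ->
train/evaluate -> explain -> cca.

The pipeline operates at two granularities, mirroring how the data would be
handled at the bench: multi-cell scenes are synthesised as off-axis holograms
and pushed through reconstruction and watershed segmentation to measure
instance-level segmentation quality (mean IoU), while the classifier and the
statistical analyses run on per-cell feature tables extracted with
ground-truth masks (the manual-delineation analogue).  Every stage writes its
artifact plus a JSON manifest of parameters and output hashes; all
stochastic stages are seeded from the single run seed, so a run re-executed
from its saved config reproduces all outputs bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .cca import cca_fit
from .classify import (
    SplitPlan,
    evaluate,
    features_from_records,
    CellImage,
    save_model,
    shapley_exact,
    split_dataset,
    train_classifier,
    xgb_margin_fn,
)
from .errors import ValidationError
from .features2d import FEATURE_COLUMNS, PHASE_FEATURES
from .holography import reconstruct_phase
from .morphology3d import FEATURE3D_COLUMNS, cell_features3d
from .segmentation import match_instances, segment_cells
from .synth import compose_scene, hologram_forward, render_cell, sample_population

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "n_per_class": 400,
    "pixel_size_um": 0.1,
    "wavelength_um": 0.532,
    "split_ratios": [0.8, 0.2],
    "glcm_levels": 32,
    "scene": {
        "n_scenes": 3,
        "cells_per_scene": 6,
        "canvas": 512,
        "min_gap_px": 6.0,
        "carrier": [0.25, 0.25],
        "fringe_contrast": 0.9,
        "noise_sd": 300.0,
    },
    "shapley": {"n_instances": 12, "n_background": 25},
    "classifier": {},
    "cca_x_cols": ["ov_rad_um2", "phase_mean_rad", "phase_p5_rad", "phase_sd_rad"],
    "cca_y_cols": FEATURE3D_COLUMNS[:1] + FEATURE3D_COLUMNS[2:],
}

REQUIRED_FIELDS = ["seed", "n_per_class", "pixel_size_um", "wavelength_um"]


def validate_config(config: dict) -> dict:
    """Merge over defaults and check the schema, naming any missing field."""
    for f in REQUIRED_FIELDS:
        if f not in config:
            raise ValidationError(f"config is missing required field {f!r}")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(run_dir: Path, stage: str, params: dict, outputs: list[Path], t0: float):
    man = {
        "stage": stage,
        "params": params,
        "outputs": {p.name: _sha256(p) for p in outputs},
        "wall_time_s": round(time.time() - t0, 3),
    }
    (run_dir / f"manifest_{stage}.json").write_text(json.dumps(man, indent=2))
    logger.info("stage %s done in %.1f s", stage, man["wall_time_s"])


def build_population_tables(
    n_per_class: int,
    seed: int,
    pixel_size: float = 0.1,
    wavelength: float = 0.532,
    glcm_levels: int = 32,
    imaging_effects: bool = True,
) -> pd.DataFrame:
    """Render a phantom population and extract the 2-D and 3-D feature tables.

    The 2-D features are measured on per-cell phase images carrying the
    acquisition effects of ``synth.apply_imaging_effects`` (speckle noise,
    focus jitter); the 3-D features come from the ground-truth thickness,
    emulating the separate tomographic modality.  Returns one merged frame:
    cell_id, class, the 15 2-D features, the six 3-D features and the
    analytic truth columns.
    """
    from .synth import apply_imaging_effects

    specs = sample_population(n_per_class, rng_seed=seed, wavelength=wavelength)
    rng = np.random.default_rng(seed + 500_000)
    records = []
    rows3d = []
    truth = []
    for i, spec in enumerate(specs, start=1):
        t, p, mask = render_cell(spec, pixel_size=pixel_size)
        phase = apply_imaging_effects(p.phase, rng) if imaging_effects else p.phase
        records.append(CellImage(i, spec.cell_class, phase, mask, pixel_size))
        row = {"cell_id": i}
        row.update(cell_features3d(t))
        rows3d.append(row)
        truth.append(
            {
                "cell_id": i,
                "ov_true_rad_um2": spec.analytic_ov,
                "volume_true_um3": spec.analytic_volume,
            }
        )
    table2d = features_from_records(records, glcm_levels=glcm_levels)
    table3d = pd.DataFrame(rows3d)
    out = table2d.merge(table3d, on="cell_id").merge(pd.DataFrame(truth), on="cell_id")
    return out


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory."""
    cfg = validate_config(config)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    seed = int(cfg["seed"])
    px = float(cfg["pixel_size_um"])
    wl = float(cfg["wavelength_um"])
    counts: dict[str, object] = {}

    # ----- simulate + reconstruct + segment scenes -----------------------
    t0 = time.time()
    sc = cfg["scene"]
    ious = []
    scene_files: list[Path] = []
    for s in range(int(sc["n_scenes"])):
        scene_seed = seed * 1000 + s
        specs = sample_population(
            (sc["cells_per_scene"] // 2 + sc["cells_per_scene"] % 2,
             sc["cells_per_scene"] // 2),
            rng_seed=scene_seed,
            wavelength=wl,
        )
        scene = compose_scene(
            specs, (sc["canvas"], sc["canvas"]), px,
            min_gap_px=float(sc["min_gap_px"]), rng_seed=scene_seed,
        )
        holo = hologram_forward(
            scene.phase,
            carrier=tuple(sc["carrier"]),
            fringe_contrast=float(sc["fringe_contrast"]),
            noise_sd=float(sc["noise_sd"]),
            rng_seed=scene_seed,
        )
        rec = reconstruct_phase(holo)
        pred = segment_cells(rec, threshold_method="fixed", fixed_threshold=0.1)
        m = match_instances(pred, scene.labels)
        ious.append(m.mean_iou)
        rms = float(
            np.sqrt(np.mean((rec.phase - scene.phase.phase)[scene.labels.labels > 0] ** 2))
        )
        logger.info(
            "scene %d: %d/%d instances matched, mean IoU %.3f, in-mask RMS %.4f rad",
            s, len(m.pairs), len(specs), m.mean_iou, rms,
        )
        if s == 0:
            qio.write_interferogram(run_dir / "scene0_hologram.tif", holo)
            qio.write_phase(run_dir / "scene0_phase_truth.tif", scene.phase)
            qio.write_phase(run_dir / "scene0_phase_reconstructed.tif", rec)
            qio.write_labels(run_dir / "scene0_labels_truth.tif", scene.labels)
            qio.write_labels(run_dir / "scene0_labels_watershed.tif", pred)
            scene_files = sorted(run_dir.glob("scene0_*.tif"))
    counts["mean_iou_watershed"] = float(np.mean(ious))
    _manifest(run_dir, "scenes", sc, scene_files, t0)

    # ----- population feature tables -------------------------------------
    t0 = time.time()
    table = build_population_tables(
        int(cfg["n_per_class"]), seed, pixel_size=px, wavelength=wl,
        glcm_levels=int(cfg["glcm_levels"]),
    )
    feat_path = run_dir / "features.csv"
    table.to_csv(feat_path, index=False)
    counts["n_cells"] = int(len(table))
    _manifest(run_dir, "features", {"n_per_class": cfg["n_per_class"]}, [feat_path], t0)

    # ----- train / evaluate ----------------------------------------------
    t0 = time.time()
    plan = SplitPlan(ratios=tuple(float(r) for r in cfg["split_ratios"]), seed=seed)
    train_tab, test_tab = split_dataset(table, plan)[:2]
    model = train_classifier(train_tab, hyperparams=cfg["classifier"], seed=seed)
    save_model(model, run_dir / "model", seed=seed)
    metrics = evaluate(model, test_tab)
    metrics_path = run_dir / "metrics.json"
    metrics_path.write_text(json.dumps(metrics.to_dict(), indent=2))
    counts["test_accuracy"] = metrics.accuracy
    _manifest(run_dir, "train_evaluate", {"split": cfg["split_ratios"]}, [metrics_path], t0)

    # ----- explain --------------------------------------------------------
    t0 = time.time()
    shp = cfg["shapley"]
    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(len(train_tab), size=min(int(shp["n_background"]), len(train_tab)), replace=False)
    inst = test_tab[FEATURE_COLUMNS].to_numpy()[: int(shp["n_instances"])]
    result = shapley_exact(
        xgb_margin_fn(model),
        inst,
        train_tab[FEATURE_COLUMNS].to_numpy()[bg_idx],
        feature_names=FEATURE_COLUMNS,
    )
    imp = pd.DataFrame(
        {
            "feature": result.feature_names,
            "mean_abs_shapley": result.importance,
        }
    ).sort_values("mean_abs_shapley", ascending=False)
    imp_path = run_dir / "importance.csv"
    imp.to_csv(imp_path, index=False)
    counts["top_feature"] = result.ranking[0]
    counts["top4_all_phase"] = all(f in PHASE_FEATURES for f in result.ranking[:4])
    _manifest(run_dir, "explain", shp, [imp_path], t0)

    # ----- cca ------------------------------------------------------------
    t0 = time.time()
    xc = list(cfg["cca_x_cols"])
    yc = list(cfg["cca_y_cols"])
    res = cca_fit(table[xc].to_numpy(), table[yc].to_numpy())
    cca_path = run_dir / "cca.json"
    cca_path.write_text(
        json.dumps({"x_cols": xc, "y_cols": yc, **res.to_dict()}, indent=2)
    )
    counts["cca_rho"] = [round(float(r), 4) for r in res.correlations]
    _manifest(run_dir, "cca", {"x_cols": xc, "y_cols": yc}, [cca_path], t0)

    (run_dir / "summary.json").write_text(json.dumps(counts, indent=2, default=str))
    return run_dir
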