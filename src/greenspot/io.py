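"""Readers/writers, the run log, report formatting and pipeline composition."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import classifier as cl
from . import preprocess as pp
from . import shape_features as sf
from . import spray_sim as ss
from . import synthgen as sg
from ._util import round_half_up
from .config import PipelineConfig

__all__ = [
    "read_image", "write_image", "write_mask", "blob_table",
    "feature_table", "image_features", "event_log", "stats_json",
    "load_scenario", "save_scenario", "load_sprayer", "save_sprayer",
    "write_report", "RunLog", "run_pipeline",
]


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    write_image(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def blob_table(blobs: list[pp.Blob]) -> pd.DataFrame:
    return pd.DataFrame([
        {"blob_id": i, "area": b.area,
         "centroid_row": round(b.centroid[0], 2),
         "centroid_col": round(b.centroid[1], 2),
         "top": b.bbox[0], "left": b.bbox[1],
         "bottom": b.bbox[2], "right": b.bbox[3]}
        for i, b in enumerate(blobs)])


def image_features(image: np.ndarray, cfg: PipelineConfig | None = None
                   ) -> list[tuple[pp.Blob, sf.ShapeFeatures]]:
    """Segment an image and compute the descriptor stack per blob."""
    cfg = cfg or PipelineConfig()
    _, blobs = pp.segment(image, kernel=cfg.mean_kernel, se=cfg.se_size,
                          min_area=cfg.min_area)
    return [(b, sf.compute_features(b, n_rings=cfg.n_rings,
                                    ring_denominator=cfg.ring_denominator))
            for b in blobs]


def feature_table(rows: list[tuple[str, int, sf.ShapeFeatures]],
                  labels: dict[str, str] | None = None) -> pd.DataFrame:
    """One row per blob: (image_id, blob_id, features...), optional species label."""
    out = []
    for image_id, blob_id, f in rows:
        rec = {"image_id": image_id, "blob_id": blob_id,
               "rat_i_l": f.rat_i_l, "rod": f.rod,
               "r_inscribed": f.r_inscribed, "b_over_a": f.b_over_a,
               "a": f.a, "b": f.b, "c": f.c,
               "skeleton_len": f.skeleton_len, "branches": f.branches,
               "r_enclosing": f.r_enclosing}
        if labels is not None:
            rec["species"] = labels.get(image_id, "")
        out.append(rec)
    return pd.DataFrame(out)


def event_log(events: list[ss.SprayEvent]) -> pd.DataFrame:
    return pd.DataFrame([
        {"target_id": e.target_id, "species": e.species,
         "plant_front": e.plant_front, "plant_rear": e.plant_rear,
         "deposit_start": e.deposit_start, "deposit_end": e.deposit_end,
         "d_open": e.d_open, "d_close": e.d_close,
         "spray_length": e.spray_length,
         "centroid_offset": e.centroid_offset, "outcome": e.outcome}
        for e in events])


def stats_json(stats: ss.SprayStats) -> dict:
    out = {}
    for k, v in asdict(stats).items():
        if isinstance(v, float):
            out[k] = round_half_up(v, 1)
        else:
            out[k] = v
    return out


def load_scenario(path: str | Path) -> ss.FieldScenario:
    data = yaml.safe_load(Path(path).read_text())
    plants = [ss.Plant(position_mm=p["position_mm"], length_mm=p["length_mm"],
                       species=p.get("species", "cabbage"))
              for p in data["plants"]]
    return ss.FieldScenario(plants=plants,
                            ridge_length_m=data.get("ridge_length_m", 70.0),
                            spacing_mm=data.get("spacing_mm", 400.0),
                            void_rate=data.get("void_rate", 0.0))


def save_scenario(scenario: ss.FieldScenario, path: str | Path) -> None:
    data = {"ridge_length_m": scenario.ridge_length_m,
            "spacing_mm": scenario.spacing_mm,
            "void_rate": scenario.void_rate,
            "plants": [{"position_mm": float(p.position_mm),
                        "length_mm": float(p.length_mm),
                        "species": p.species} for p in scenario.plants]}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_sprayer(path: str | Path) -> ss.SprayerConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return ss.SprayerConfig(**data)


def save_sprayer(cfg: ss.SprayerConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def write_report(stats: ss.SprayStats | None, metrics: cl.Metrics | None,
                 path: str | Path) -> Path:
    """Human-readable summary plus a machine JSON sidecar (same stem, .json).

    Percentages and millimetre quantities print to 1 decimal (half-up).
    """
    path = Path(path)
    lines = ["greenspot run report", "====================", ""]
    payload: dict = {}
    if metrics is not None:
        lines.append("Classification")
        lines.append(f"  accuracy:  {round_half_up(metrics.accuracy, 1)} %")
        lines.append(f"  precision: {round_half_up(metrics.precision, 1)} %")
        lines.append(f"  recall:    {round_half_up(metrics.recall, 1)} %")
        for cls, acc in metrics.per_class_accuracy.items():
            lines.append(f"  {cls}: {round_half_up(acc, 1)} %")
        payload["classification"] = {
            "accuracy": round_half_up(metrics.accuracy, 1),
            "precision": round_half_up(metrics.precision, 1),
            "recall": round_half_up(metrics.recall, 1),
            "per_class_accuracy": {k: round_half_up(v, 1)
                                   for k, v in metrics.per_class_accuracy.items()},
        }
    else:
        lines.append("no classification performed")
    lines.append("")
    if stats is not None:
        lines.append("Spraying")
        lines.append(f"  targets:        {stats.n_targets}")
        lines.append(f"  effective rate: {stats.effective_rate} %")
        lines.append(f"  invalid rate:   {stats.invalid_rate} %")
        lines.append(f"  missed rate:    {stats.missed_rate} %")
        if stats.mean_spray_length is not None:
            lines.append(f"  mean spray length: {round_half_up(stats.mean_spray_length, 1)} mm")
        if stats.mean_saving_rate is not None:
            lines.append(f"  theoretical saving: {round_half_up(stats.mean_saving_rate, 1)} %")
        payload["spraying"] = stats_json(stats)
    else:
        lines.append("no spraying simulated")
    path.write_text("\n".join(lines) + "\n")
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2))
    return path


@dataclass
class RunLog:
    seed: int
    stages: list[dict] = field(default_factory=list)
    version: str = ""

    def record(self, name: str, seconds: float, **extra) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3), **extra})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def run_pipeline(cfg: PipelineConfig) -> RunLog:
    """generate -> segment -> features -> train -> evaluate -> simulate -> report.

    All artifacts land under ``cfg.out_dir``; identical config and seed give
    byte-identical CSV outputs.
    """
    from . import __version__

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(seed=cfg.seed, version=__version__)

    t0 = time.time()
    records, manifest = sg.gen_dataset(cfg.n_per_class, seed=cfg.seed)
    manifest.to_csv(out / "manifest.csv", index=False)
    log.record("generate", time.time() - t0, n_images=len(records))

    t0 = time.time()
    rows, labels, feats, truth = [], {}, [], []
    for rec in records:
        pairs = image_features(rec.image, cfg)
        labels[rec.image_id] = rec.species
        for blob_id, (_, f) in enumerate(pairs[:1]):  # one plant per image
            rows.append((rec.image_id, blob_id, f))
            feats.append(f)
            truth.append(rec.species)
    table = feature_table(rows, labels)
    table.to_csv(out / "features.csv", index=False, float_format="%.6f")
    log.record("features", time.time() - t0, n_blobs=len(rows))

    t0 = time.time()
    scaler = sf.FeatureScaler.fit(feats)
    X = scaler.transform(feats)
    y = np.array(truth)
    n_folds = cl.select_fold_count(len(y), X.shape[1], default=cfg.n_folds)
    cv = cl.CvConfig(n_folds=n_folds, c_exponents=cfg.c_exponents,
                     sigma_exponents=cfg.sigma_exponents)
    model = cl.grid_search_train(X, y, cv, seed=cfg.seed, scaler=scaler)
    model.cv_report.to_csv(out / "cv_report.csv", index=False, float_format="%.6f")
    cl.save_model(model, out / "model.json")
    pred = cl.predict(model, X)
    pd.DataFrame({"image_id": [r[0] for r in rows], "predicted": pred,
                  "truth": y}).to_csv(out / "predictions.csv", index=False)
    metrics = cl.evaluate(pred, y, positive_class="cabbage")
    log.record("train", time.time() - t0, C=model.C, sigma=model.sigma,
               cv_accuracy=float(model.cv_report.mean_cv_accuracy.max()))

    t0 = time.time()
    scenario = (load_scenario(cfg.scenario_path) if cfg.scenario_path
                else sg.gen_scenario(seed=cfg.seed))
    sprayer = (load_sprayer(cfg.sprayer_path) if cfg.sprayer_path
               else ss.SprayerConfig())
    events = ss.simulate_pass(scenario, sprayer, seed=cfg.seed)
    event_log(events).to_csv(out / "events.csv", index=False, float_format="%.3f")
    stats = ss.aggregate(events, spacing_mm=scenario.spacing_mm)
    (out / "stats.json").write_text(json.dumps(stats_json(stats), indent=2))
    log.record("simulate", time.time() - t0, n_targets=len(events))

    write_report(stats, metrics, out / "report.txt")
    log.save(out / "runlog.json")
    return log
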