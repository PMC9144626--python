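"""End-to-end orchestration: simulate -> split -> train -> predict ->
evaluate -> score -> classify, as one reproducible run driven by a single
config and a single global seed.

Every stochastic stage derives its own seed deterministically from the
global seed and the stage name, so re-running a config reproduces the run.
Each stage records a ``<stage>.done`` marker containing a hash of the
relevant config; completed stages are skipped on re-run (resume semantics)
and re-executed when their config changed. ``run_manifest.json`` lists
every artifact with its SHA-256 checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import plots
from .classification import (
    build_block_features,
    classify,
    fit_lda,
    boundary_angle_to_shg_axis,
    image_features,
)
from .errors import PhyllosegError
from .evaluation import difference_image, evaluate_split
from .io import DatasetManifest, split_dataset, write_mask, read_mask
from .scoring import records_frame, score_dataset
from .segmentation import (
    NetworkConfig,
    SegNetSegmenter,
    TrainingConfig,
    train as train_op,
    predict as predict_op,
)
from .synthetic import (
    CohortSpec,
    MorphologyParams,
    OpticsParams,
    default_optics,
    fa_morphology,
    generate_cohort,
    pt_morphology,
)

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic sub-seed: hash of seed || stage || index, < 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Full-run configuration; nested dicts override the corresponding
    dataclass defaults field-by-field, so a YAML config only needs to name
    what it changes."""

    seed: int = 0
    out_dir: str = "runs/default"
    frame_size: int = 128
    train_fraction: float = 0.5
    cohort: dict = field(default_factory=dict)
    morphology_fa: dict = field(default_factory=dict)
    morphology_pt: dict = field(default_factory=dict)
    optics_fa: dict = field(default_factory=dict)
    optics_pt: dict = field(default_factory=dict)
    network: dict = field(default_factory=lambda: {"encoder_depth": 2, "base_filters": 8})
    training: dict = field(default_factory=lambda: {"epochs": 120})
    classification: dict = field(
        default_factory=lambda: {"block_px": 128, "n_per_class": 500, "source": "predicted"}
    )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PhyllosegError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    # -- resolved sub-configs --------------------------------------------
    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(**{"seed": stage_seed(self.seed, "simulate"), **self.cohort})

    def morph(self, lesion: str) -> MorphologyParams:
        base = fa_morphology() if lesion == "FA" else pt_morphology()
        over = self.morphology_fa if lesion == "FA" else self.morphology_pt
        return dataclasses.replace(base, **over)

    def optics(self, lesion: str) -> OpticsParams:
        base = default_optics(frame_size=self.frame_size, lesion=lesion)
        over = self.optics_fa if lesion == "FA" else self.optics_pt
        return dataclasses.replace(base, **over)

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(**self.network)

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(**{"seed": stage_seed(self.seed, "train"), **self.training})


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context helper: skip-if-done bookkeeping plus timing and logging."""

    def __init__(self, run_dir: Path, name: str, cfg_hash: str, outputs: list[Path]):
        self.run_dir, self.name, self.cfg_hash = run_dir, name, cfg_hash
        self.outputs = outputs
        self.marker = run_dir / f"{name}.done"

    @property
    def cached(self) -> bool:
        if not self.marker.exists():
            return False
        try:
            recorded = json.loads(self.marker.read_text())
        except json.JSONDecodeError:
            return False
        return recorded.get("config_hash") == self.cfg_hash and all(
            p.exists() for p in self.outputs
        )

    def done(self, t0: float) -> None:
        self.marker.write_text(
            json.dumps(
                {
                    "stage": self.name,
                    "config_hash": self.cfg_hash,
                    "wall_time_s": round(time.time() - t0, 3),
                }
            )
        )
        logger.info("stage %s finished in %.1fs", self.name, time.time() - t0)


def run_full(cfg: RunConfig) -> Path:
    """Execute (or resume) the whole pipeline; returns the run directory."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")

    # -- simulate --------------------------------------------------------
    sim_hash = _hash_obj(
        [asdict(cfg.cohort_spec())]
        + [asdict(cfg.morph(l)) for l in ("FA", "PT")]
        + [asdict(cfg.optics(l)) for l in ("FA", "PT")]
    )
    data_dir = run_dir / "data"
    stage = _Stage(run_dir, "simulate", sim_hash, [data_dir / "manifest.csv"])
    if not stage.cached:
        t0 = time.time()
        generate_cohort(
            cfg.cohort_spec(),
            morph_fa=cfg.morph("FA"),
            morph_pt=cfg.morph("PT"),
            optics_fa=cfg.optics("FA"),
            optics_pt=cfg.optics("PT"),
            out_dir=data_dir,
        )
        stage.done(t0)
    manifest = DatasetManifest.load_csv(data_dir / "manifest.csv")

    # -- split -----------------------------------------------------------
    split_hash = _hash_obj([sim_hash, cfg.train_fraction, stage_seed(cfg.seed, "split")])
    split_csv = data_dir / "manifest_split.csv"
    stage = _Stage(run_dir, "split", split_hash, [split_csv])
    if not stage.cached:
        t0 = time.time()
        manifest = split_dataset(manifest, cfg.train_fraction, stage_seed(cfg.seed, "split"))
        manifest.save_csv(split_csv)
        stage.done(t0)
    manifest = DatasetManifest.load_csv(split_csv)

    # -- train -----------------------------------------------------------
    train_hash = _hash_obj(
        [split_hash, asdict(cfg.network_config()), asdict(cfg.training_config())]
    )
    model_path = run_dir / "model.npz"
    stage = _Stage(run_dir, "train", train_hash, [model_path])
    if not stage.cached:
        t0 = time.time()
        model = train_op(manifest, cfg.network_config(), cfg.training_config())
        model.save(model_path)
        pd.DataFrame(model.history_).to_csv(run_dir / "training_history.csv", index=False)
        stage.done(t0)
    model = SegNetSegmenter.load(model_path)

    # -- predict ---------------------------------------------------------
    pred_dir = run_dir / "pred"
    pred_paths = [pred_dir / f"{iid}.png" for iid in manifest.frame["image_id"]]
    stage = _Stage(run_dir, "predict", train_hash, pred_paths)
    if not stage.cached:
        t0 = time.time()
        pred_dir.mkdir(exist_ok=True)
        for iid in manifest.frame["image_id"]:
            write_mask(pred_dir / f"{iid}.png", predict_op(model, manifest.load_image(iid)))
        stage.done(t0)
    predicted = {iid: read_mask(pred_dir / f"{iid}.png") for iid in manifest.frame["image_id"]}

    # -- evaluate --------------------------------------------------------
    eval_outputs = [run_dir / f"eval_{s}.csv" for s in ("train", "test")] + [
        run_dir / "eval_summary.json"
    ]
    stage = _Stage(run_dir, "evaluate", train_hash, eval_outputs)
    if not stage.cached:
        t0 = time.time()
        summaries = []
        for split in ("train", "test"):
            rep = evaluate_split(model, manifest, split)
            rep.save(run_dir / f"eval_{split}.csv", run_dir / f"eval_{split}.json")
            summaries.append(rep.summary)
        (run_dir / "eval_summary.json").write_text(json.dumps(summaries, indent=2))
        plots.metric_bar_plot(summaries, run_dir / "fig_metrics.png")
        diff_dir = run_dir / "diff"
        diff_dir.mkdir(exist_ok=True)
        for iid in manifest.subset("test")["image_id"].head(4):
            rgb = difference_image(predicted[iid], manifest.load_mask(iid))
            plots.plt.imsave(diff_dir / f"{iid}.png", rgb)
        stage.done(t0)

    # -- score -----------------------------------------------------------
    score_outputs = [
        run_dir / "scores_ground_truth.csv",
        run_dir / "scores_predicted.csv",
        run_dir / "group_stats_ground_truth.json",
        run_dir / "group_stats_predicted.json",
    ]
    stage = _Stage(run_dir, "score", train_hash, score_outputs)
    if not stage.cached:
        t0 = time.time()
        for source in ("ground_truth", "predicted"):
            records, gstats = score_dataset(
                manifest, source, predicted_masks=predicted if source == "predicted" else None
            )
            records_frame(records).to_csv(run_dir / f"scores_{source}.csv", index=False)
            (run_dir / f"group_stats_{source}.json").write_text(
                json.dumps(gstats.to_dict(), indent=2)
            )
            plots.score_bar_plot(gstats, run_dir / f"fig_scores_{source}.png")
        stage.done(t0)

    # -- classify --------------------------------------------------------
    cls_cfg = dict(cfg.classification)
    source = cls_cfg.pop("source", "predicted")
    cls_hash = _hash_obj([train_hash, cls_cfg, source, stage_seed(cfg.seed, "classify")])
    cls_outputs = [run_dir / "features.csv", run_dir / "lda.json", run_dir / "classification.json"]
    stage = _Stage(run_dir, "classify", cls_hash, cls_outputs)
    if not stage.cached:
        t0 = time.time()
        block_px = cls_cfg.get("block_px", 128)
        if cfg.frame_size > block_px:
            points = build_block_features(
                manifest,
                masks_source=source,
                predicted_masks=predicted if source == "predicted" else None,
                block_px=block_px,
                n_per_class=cls_cfg.get("n_per_class", 500),
                rng_seed=stage_seed(cfg.seed, "classify"),
            )
        else:  # frames are block-sized already: use whole-image features
            records, _ = score_dataset(
                manifest, source, predicted_masks=predicted if source == "predicted" else None
            )
            points = image_features(records)
        model_lda = fit_lda(points)
        labeled, acc = classify(model_lda, points)
        labeled.to_csv(run_dir / "features.csv", index=False)
        (run_dir / "lda.json").write_text(
            json.dumps(
                {
                    "w": model_lda.w_.tolist(),
                    "b": model_lda.b_,
                    "class_means": model_lda.means_.tolist(),
                    "pooled_covariance": model_lda.cov_.tolist(),
                    "classes": model_lda.classes_.tolist(),
                    "standardized": model_lda.standardize,
                    "boundary_angle_to_shg_axis_deg": boundary_angle_to_shg_axis(model_lda),
                },
                indent=2,
            )
        )
        (run_dir / "classification.json").write_text(json.dumps(acc, indent=2))
        plots.scatter_plot(points, run_dir / "fig_scatter.png", model_lda)
        stage.done(t0)

    # -- artifact manifest ------------------------------------------------
    artifacts = sorted(
        p for p in run_dir.rglob("*")
        if p.is_file() and p.name != "run_manifest.json"
    )
    (run_dir / "run_manifest.json").write_text(
        json.dumps(
            {
                "seed": cfg.seed,
                "artifacts": {
                    str(p.relative_to(run_dir)): _sha256_file(p) for p in artifacts
                },
            },
            indent=2,
        )
    )
    return run_dir


def report(run_dir: str | Path) -> str:
    """Render a single human-readable summary from serialized artifacts only
    (nothing is recomputed). Missing stages are flagged as gaps."""
    run_dir = Path(run_dir)
    lines = ["# Pipeline run report", ""]

    eval_path = run_dir / "eval_summary.json"
    lines.append("## Segmentation performance")
    if eval_path.exists():
        for s in json.loads(eval_path.read_text()):
            lines.append(
                f"- {s['split']}: total accuracy {s['accuracy_mean']:.3f} "
                f"(SD {s['accuracy_sd']:.3f}), weighted IoU {s['weighted_iou_mean']:.3f} "
                f"(SD {s['weighted_iou_sd']:.3f}), n = {s['n_images']}"
            )
    else:
        lines.append("- MISSING: evaluation artifacts")
    lines.append("")

    lines.append("## Quantitative scores (mean +/- SD; KS test)")
    for source in ("ground_truth", "predicted"):
        path = run_dir / f"group_stats_{source}.json"
        if not path.exists():
            lines.append(f"- MISSING: group stats ({source})")
            continue
        g = json.loads(path.read_text())
        for score_name, key in (("area ratio", "area_ratio"), ("stromal SHG", "shg_stroma_mean")):
            mm, ss = g[key]["mean"], g[key]["sd"]
            p = g["ks"][key]["p"]
            star = " *" if p < 0.05 else ""
            lines.append(
                f"- {source}, {score_name}: "
                + ", ".join(f"{l} {mm[l]:.3f} +/- {ss[l]:.3f}" for l in sorted(mm))
                + f"; KS p = {p:.2e}{star}"
            )
    lines.append("")

    lines.append("## Linear discriminant analysis")
    lda_path, acc_path = run_dir / "lda.json", run_dir / "classification.json"
    if lda_path.exists() and acc_path.exists():
        lda = json.loads(lda_path.read_text())
        acc = json.loads(acc_path.read_text())
        lines.append(
            f"- overall accuracy {acc['overall']:.3f}; boundary angle to SHG axis "
            f"{lda['boundary_angle_to_shg_axis_deg']:.1f} deg"
        )
        for k, v in acc.items():
            if k != "overall":
                lines.append(f"- {k}: {v:.3f}")
    else:
        lines.append("- MISSING: classification artifacts")
    lines.append("")

    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
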