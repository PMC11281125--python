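"""End-to-end orchestration: phantom data -> preprocessing -> structure
extraction -> classifier training -> evaluation.

Every run is driven by a `PipelineConfig`, is reproducible from (config,
seed) alone, and writes its resolved config next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifier import (BranchSpec, ClassifierTrainConfig, FusionMode, GlaucomaModel,
                         HeadSpec, build_glaucoma_model, train_classifier)
from .disc import DiscParams, extract_disc_region
from .evaluation import EvalReport, evaluate_model
from .images import write_image, write_label_table
from .phantom import PhantomParams, PhantomSample, generate_dataset, vessel_patch_pairs
from .preprocess import (PreprocessParams, preprocess_fundus, rotate_raster,
                         to_classifier_input)
from .vessels import (ResUNet, ResUNetSpec, VesselTrainConfig, build_resunet,
                      segment_vessels, train_vessel_model)

log = logging.getLogger("fundustruct")


@dataclass
class PipelineConfig:
    """Fully resolved parameters of one end-to-end run."""

    seed: int = 0
    n_per_class: int = 16
    n_val_per_class: int = 4
    rotation_step_deg: float = 360.0   # 360 = no augmentation; 10 = paper-scale
    phantom: PhantomParams = field(default_factory=PhantomParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    disc: DiscParams = field(default_factory=DiscParams)
    resunet: ResUNetSpec = field(default_factory=ResUNetSpec)
    branch: BranchSpec = field(default_factory=BranchSpec)
    head: HeadSpec = field(default_factory=HeadSpec)
    vessel_train: VesselTrainConfig = field(default_factory=VesselTrainConfig)
    classifier_train: ClassifierTrainConfig = field(default_factory=ClassifierTrainConfig)
    n_vessel_patches: int = 64
    fusion_modes: tuple = ("attention", "concat-ablation")
    use_true_vessel_masks: bool = False   # skip ResU-Net inference, use ground truth

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        nested = {
            "phantom": PhantomParams, "preprocess": PreprocessParams, "disc": DiscParams,
            "resunet": ResUNetSpec, "branch": BranchSpec, "head": HeadSpec,
            "vessel_train": VesselTrainConfig, "classifier_train": ClassifierTrainConfig,
        }
        for key, cls in nested.items():
            if key in d and isinstance(d[key], dict):
                kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()}
                d[key] = cls(**kwargs)
        for key in ("fusion_modes",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return PipelineConfig(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @staticmethod
    def load(path: str | Path) -> "PipelineConfig":
        return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def sample_to_triple(sample: PhantomSample, vessel_model: ResUNet | None,
                     cfg: PipelineConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(preprocessed image, vessel map, disc crop), each 64x64 in [0,1].

    Vessels are segmented from the preprocessed image; the disc is
    extracted from the original photograph, whose color distribution the
    bright-pixel percentile rule assumes.
    """
    enhanced, _ = preprocess_fundus(sample.image, cfg.preprocess)
    img64 = to_classifier_input(enhanced, cfg.preprocess).pixels.astype(np.float32) / 255.0
    if vessel_model is not None and not cfg.use_true_vessel_masks:
        vessel64 = segment_vessels(enhanced, vessel_model, cfg.preprocess.classifier_size)
    else:
        from skimage import transform
        vessel64 = transform.resize(sample.vessel_mask.pixels.astype(float),
                                    (cfg.preprocess.classifier_size,) * 2, order=1,
                                    anti_aliasing=False, preserve_range=True).astype(np.float32)
    disc64 = extract_disc_region(sample.image, cfg.disc, cfg.preprocess).pixels.astype(np.float32) / 255.0
    return img64, vessel64, disc64


def _augment_triples(triples: list[tuple[tuple, str]], step_deg: float) -> list[tuple[tuple, str]]:
    if step_deg >= 360:
        return list(triples)
    out = []
    for (img, ves, dsc), label in triples:
        for angle in np.arange(0, 360, step_deg):
            if angle == 0:
                out.append(((img, ves, dsc), label))
                continue
            rot = tuple(_rotate_float(a, float(angle)) for a in (img, ves, dsc))
            out.append((rot, label))
    return out


def _rotate_float(arr: np.ndarray, angle: float) -> np.ndarray:
    from skimage import transform
    if angle % 90 == 0:
        return np.ascontiguousarray(np.rot90(arr, k=int(angle // 90) % 4))
    return transform.rotate(arr.astype(np.float64), angle, resize=False, order=1,
                            mode="constant", cval=0.0, preserve_range=True).astype(np.float32)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full flow and return the run directory.

    Stages: phantom synthesis -> per-class train/val split -> vessel-model
    training -> triple construction (preprocess, vessel map, disc crop) ->
    optional rotation augmentation -> classifier training for each
    configured fusion mode -> evaluation reports.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.save(run_dir / "config.yaml")
    handler = logging.FileHandler(run_dir / "run.log")
    log.addHandler(handler)
    try:
        return _run(cfg, run_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, run_dir: Path) -> Path:
    log.info("stage synth: %d phantoms per class", cfg.n_per_class)
    samples, labels = generate_dataset(cfg.n_per_class, cfg.phantom, cfg.seed)
    data_dir = run_dir / "data"
    (data_dir / "images").mkdir(parents=True, exist_ok=True)
    (data_dir / "vessel_masks").mkdir(exist_ok=True)
    for s in samples:
        image_id = s.image.meta["image_id"]
        write_image(s.image, data_dir / "images" / f"{image_id}.png")
        write_image(s.vessel_mask, data_dir / "vessel_masks" / f"{image_id}.png")
    write_label_table(labels, data_dir / "labels.csv")

    rng = np.random.default_rng(cfg.seed + 1)
    by_class: dict[str, list[PhantomSample]] = {"glaucoma": [], "normal": []}
    for s in samples:
        by_class[s.label].append(s)
    train_samples, val_samples = [], []
    for cls, group in by_class.items():
        idx = rng.permutation(len(group))
        val_idx = set(idx[:cfg.n_val_per_class].tolist())
        for i, s in enumerate(group):
            (val_samples if i in val_idx else train_samples).append(s)

    log.info("stage train-vessels: %d patches", cfg.n_vessel_patches)
    pairs = vessel_patch_pairs(train_samples, cfg.n_vessel_patches, seed=cfg.seed + 2)
    vessel_model, vessel_history = train_vessel_model(pairs, cfg.vessel_train, cfg.resunet)
    np.savez(run_dir / "vessel_model.npz", *vessel_model.state_arrays())
    (run_dir / "vessel_history.json").write_text(json.dumps(vessel_history))

    log.info("stage triples: preprocessing + structure extraction")
    train_triples = [(sample_to_triple(s, vessel_model, cfg), s.label) for s in train_samples]
    val_triples = [(sample_to_triple(s, vessel_model, cfg), s.label) for s in val_samples]
    train_triples = _augment_triples(train_triples, cfg.rotation_step_deg)
    val_triples = _augment_triples(val_triples, cfg.rotation_step_deg)

    reports: dict[str, EvalReport] = {}
    for mode in cfg.fusion_modes:
        log.info("stage train classifier: fusion=%s", mode)
        model, history = train_classifier(train_triples, cfg.classifier_train,
                                          FusionMode(mode), val_set=val_triples,
                                          branch_spec=cfg.branch, head_spec=cfg.head)
        np.savez(run_dir / f"classifier_{mode}.npz", *model.state_arrays())
        (run_dir / f"history_{mode}.json").write_text(json.dumps(history))
        report = evaluate_model(model, val_triples)
        reports[mode] = report
        (run_dir / f"report_{mode}.json").write_text(report.to_json())
    log.info("run complete: %s", run_dir)
    return run_dir


# -- model serialization helpers (CLI) ---------------------------------------

def save_vessel_model(model: ResUNet, path: str | Path) -> None:
    path = Path(path)
    np.savez(path, *model.state_arrays())
    path.with_suffix(".yaml").write_text(yaml.safe_dump(dataclasses.asdict(model.spec)))


def load_vessel_model(path: str | Path) -> ResUNet:
    path = Path(path)
    spec_dict = yaml.safe_load(path.with_suffix(".yaml").read_text())
    spec_dict = {k: tuple(v) if isinstance(v, list) else v for k, v in spec_dict.items()}
    model = build_resunet(ResUNetSpec(**spec_dict))
    with np.load(path) as data:
        model.load_state_arrays([data[k] for k in data.files])
    return model


def save_classifier(model: GlaucomaModel, path: str | Path) -> None:
    path = Path(path)
    np.savez(path, *model.state_arrays())
    meta = {"branch": dataclasses.asdict(model.branch_spec),
            "head": dataclasses.asdict(model.head_spec),
            "fusion": model.fusion.mode}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_classifier(path: str | Path) -> GlaucomaModel:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    tup = lambda d: {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    model = build_glaucoma_model(BranchSpec(**tup(meta["branch"])),
                                 HeadSpec(**tup(meta["head"])), FusionMode(meta["fusion"]))
    with np.load(path) as data:
        model.load_state_arrays([data[k] for k in data.files])
    return model
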