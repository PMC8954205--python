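"""End-to-end experiment orchestration.

Runs the full experiment matrix — restoration condition x {whole-brain,
cropped} — over a synthetic cohort: generate (or load) the cohort, restore
every volume slice-wise, optionally crop to the limbic slab, normalize each
volume by its mean in-brain intensity, train and evaluate the 3-D CNN with
stratified cross-validation, and summarize explainability with averaged
class activation maps.  All randomness flows from one master seed expanded
per stage with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize

from . import evaluation
from .cam import ActivationMap, average_maps, cam, region_importance, to_whole_grid
from .cropping import LIMBIC_REGIONS, CropBox, crop, limbic_crop_box
from .nn.network import ModelConfig, build_model, predict, train
from .phantoms import CohortSpec, ScannerProfile, generate_cohort
from .restoration import MMWFConfig, RestorationConfig, TVDeblurConfig, restore_volume
from .volume import AtlasVolume, Volume

log = logging.getLogger("limbicnet")

__all__ = [
    "Condition", "EvalConfig", "ExperimentConfig", "default_conditions",
    "validate_config", "load_config", "prepare_condition", "run_condition",
    "run_experiment", "benchmark_cohort_spec", "benchmark_model_config",
    "run_benchmark",
]


@dataclass(frozen=True)
class Condition:
    """One cell of the experiment matrix."""

    name: str
    restoration: RestorationConfig = field(default_factory=RestorationConfig)
    cropped: bool = False


@dataclass(frozen=True)
class EvalConfig:
    cv_k: int = 3
    mode: str = "cv"  # cv | split
    frac_train: float = 0.7


@dataclass
class ExperimentConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    conditions: list[Condition] = field(default_factory=lambda: default_conditions())
    model: ModelConfig = field(default_factory=ModelConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    crop_regions: tuple[str, ...] = LIMBIC_REGIONS
    crop_margin: int = 2
    seed: int = 0
    output_dir: str = "runs/experiment"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("at least one condition is required")
        names = [c.name for c in self.conditions]
        if len(names) != len(set(names)):
            raise ValueError("condition names must be unique")


def default_conditions() -> list[Condition]:
    """The 10-cell matrix: {raw, deblur sigma 1/2, denoise window 3/5} x
    {whole, cropped}."""
    base = [
        ("raw", RestorationConfig(method="none")),
        ("deblur_sigma1", RestorationConfig(method="deblur", sigma_b=1.0)),
        ("deblur_sigma2", RestorationConfig(method="deblur", sigma_b=2.0)),
        ("denoise_w3", RestorationConfig(method="denoise",
                                         mmwf=MMWFConfig(window=3))),
        ("denoise_w5", RestorationConfig(method="denoise",
                                         mmwf=MMWFConfig(window=5))),
    ]
    out = []
    for name, rest in base:
        out.append(Condition(name=f"{name}_whole", restoration=rest, cropped=False))
        out.append(Condition(name=f"{name}_crop", restoration=rest, cropped=True))
    return out


# ---------------------------------------------------------------------------
# config file parsing

def _build_config(doc: dict, errors: list[str]) -> ExperimentConfig | None:
    def take(d, key, default):
        return d.get(key, default) if isinstance(d, dict) else default

    try:
        cdoc = doc.get("cohort", {}) or {}
        scanners = cdoc.pop("scanner_profiles", None)
        if scanners is not None:
            profs = []
            for s in scanners:
                weight = float(s.pop("weight", 1.0))
                profs.append((ScannerProfile(**s), weight))
            cdoc["scanner_profiles"] = tuple(profs)
        if "dims" in cdoc:
            cdoc["dims"] = tuple(cdoc["dims"])
        cohort = CohortSpec(**cdoc)
    except (TypeError, ValueError, KeyError) as exc:
        errors.append(f"cohort: {exc}")
        cohort = None

    conditions: list[Condition] = []
    cond_docs = doc.get("conditions")
    if cond_docs is None:
        conditions = default_conditions()
    else:
        for i, cd in enumerate(cond_docs):
            try:
                rdoc = dict(cd.get("restoration", {}) or {})
                tv = TVDeblurConfig(**(rdoc.pop("tv", {}) or {}))
                mm = MMWFConfig(**(rdoc.pop("mmwf", {}) or {}))
                rest = RestorationConfig(tv=tv, mmwf=mm, **rdoc)
                conditions.append(Condition(name=cd["name"], restoration=rest,
                                            cropped=bool(cd.get("cropped", False))))
            except (TypeError, ValueError, KeyError) as exc:
                errors.append(f"conditions[{i}]: {exc}")

    try:
        mdoc = dict(doc.get("model", {}) or {})
        for key in ("input_shape", "stage_channels"):
            if key in mdoc:
                mdoc[key] = tuple(mdoc[key])
        model = ModelConfig(**mdoc)
    except (TypeError, ValueError) as exc:
        errors.append(f"model: {exc}")
        model = None

    try:
        ev = EvalConfig(**(doc.get("eval", {}) or {}))
        if ev.mode not in ("cv", "split"):
            errors.append(f"eval.mode must be 'cv' or 'split', got {ev.mode!r}")
    except (TypeError, ValueError) as exc:
        errors.append(f"eval: {exc}")
        ev = None

    if errors:
        return None
    try:
        return ExperimentConfig(
            cohort=cohort, conditions=conditions, model=model, eval=ev,
            crop_regions=tuple(doc.get("crop_regions", LIMBIC_REGIONS)),
            crop_margin=int(doc.get("crop_margin", 2)),
            seed=int(doc.get("seed", 0)),
            output_dir=str(doc.get("output_dir", "runs/experiment")))
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
        return None


def validate_config(path: str | Path) -> tuple[ExperimentConfig | None, list[str]]:
    """Parse and invariant-check a YAML experiment config.

    Returns ``(config, [])`` on success or ``(None, errors)`` with one entry
    per violation.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    errors: list[str] = []
    cfg = _build_config(doc, errors)
    return cfg, errors


def load_config(path: str | Path) -> ExperimentConfig:
    cfg, errors = validate_config(path)
    if cfg is None:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    return cfg


# ---------------------------------------------------------------------------
# data preparation

def conform(vol: Volume, dims: tuple[int, int, int]) -> Volume:
    """Trilinear resample to the reference grid (undoes slice decimation)."""
    if vol.dims == tuple(dims):
        return vol
    data = resize(vol.data, dims, order=1, mode="edge", preserve_range=True,
                  anti_aliasing=False)
    return Volume(data=np.clip(data, 0.0, None), voxel_size=vol.voxel_size)


def prepare_condition(volumes: list[Volume], atlas: AtlasVolume,
                      condition: Condition,
                      crop_regions: tuple[str, ...] = LIMBIC_REGIONS,
                      crop_margin: int = 2,
                      ) -> tuple[np.ndarray, CropBox]:
    """Restore, optionally crop, and mean-normalize a list of volumes.

    Returns a float32 array ``(N, 1, x, y, z)`` ready for the network and the
    crop box used (the whole grid when uncropped).
    """
    if condition.cropped:
        box = limbic_crop_box(atlas, regions=crop_regions, margin=crop_margin)
    else:
        box = CropBox.whole(atlas.dims)
    brain = atlas.brain_mask[box.slices]
    arrays = []
    for vol in volumes:
        v = conform(vol, atlas.dims)
        # restoration is per-axial-slice and the box keeps the full in-plane
        # extent, so restore-then-crop equals crop-then-restore; cropping
        # first avoids restoring slices that are discarded anyway
        v, _ = crop(v, box)
        v = restore_volume(v, condition.restoration)
        data = v.data
        denom = float(data[brain].mean()) if brain.any() else float(data.mean())
        if denom > 0:
            data = data / denom
        arrays.append(data.astype(np.float32))
    return np.stack(arrays)[:, None], box


# ---------------------------------------------------------------------------
# running conditions

def run_condition(x: np.ndarray, y: np.ndarray, ids: list[str],
                  model_cfg: ModelConfig, eval_cfg: EvalConfig, seed: int,
                  box: CropBox, atlas: AtlasVolume,
                  ) -> dict:
    """Cross-validated training/evaluation of one prepared condition.

    Returns per-fold metrics, the mean/sd aggregate, per-fold loss curves,
    and the averaged AD activation map (each subject contributes the map
    from the fold in which it was held out) with its regional summary.
    """
    manifest = pd.DataFrame({"id": ids, "label": y})
    model_cfg = replace(model_cfg, input_shape=x.shape[2:])
    id_to_idx = {s: i for i, s in enumerate(ids)}
    fold_curves: list[dict] = []
    maps: list[ActivationMap] = []

    def fit_predict(train_ids, test_ids, fold):
        tr = np.array([id_to_idx[s] for s in train_ids])
        te = np.array([id_to_idx[s] for s in test_ids])
        cfg = replace(model_cfg, seed=int((seed + 1000 * fold) & 0x7FFFFFFF))
        model = build_model(cfg)
        trained = train(model, (x[tr], y[tr]), (x[te], y[te]), cfg)
        fold_curves.append({"fold": fold,
                            "train_loss": trained.train_loss_curve,
                            "test_loss": trained.test_loss_curve})
        _, pred = predict(trained, x[te])
        for i in te:
            maps.append(cam(trained, x[i, 0], crop_box=box))
        return pred, y[te]

    if eval_cfg.mode == "split":
        train_ids, test_ids = evaluation.split_train_test(
            manifest, frac_train=eval_cfg.frac_train, seed=seed)
        pred, true = fit_predict(train_ids, test_ids, 0)
        fold_metrics = [evaluation.metrics(evaluation.confusion(pred, true))]
        aggregate = evaluation.aggregate_metrics(fold_metrics)
    else:
        fold_metrics, aggregate = evaluation.cross_validate(
            manifest, fit_predict, k=eval_cfg.cv_k, seed=seed)

    mean_map = average_maps(maps)
    importance = region_importance(mean_map, atlas)
    return {
        "fold_metrics": fold_metrics,
        "aggregate": aggregate,
        "loss_curves": fold_curves,
        "mean_map": mean_map,
        "importance": importance,
    }


def _metrics_table(rows: dict[str, dict[str, tuple[float, float]]]) -> pd.DataFrame:
    records = []
    for cond, agg in rows.items():
        rec: dict[str, object] = {"condition": cond}
        for m in evaluation.METRIC_NAMES:
            rec[f"{m}_mean"], rec[f"{m}_sd"] = agg[m]
        records.append(rec)
    return pd.DataFrame(records)


def _render_table(df: pd.DataFrame) -> str:
    lines = [f"{'Condition':<22}" + "".join(f"{m:>16}" for m in evaluation.METRIC_NAMES)]
    for _, row in df.iterrows():
        cells = "".join(
            f"{row[f'{m}_mean']:.2f} ± {row[f'{m}_sd']:.2f}".rjust(16)
            for m in evaluation.METRIC_NAMES)
        lines.append(f"{row['condition']:<22}" + cells)
    return "\n".join(lines)


def _save_montage(map_whole: np.ndarray, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nz = map_whole.shape[2]
    picks = np.linspace(0, nz - 1, min(8, nz)).astype(int)
    fig, axes = plt.subplots(1, len(picks), figsize=(2 * len(picks), 2.2))
    vmax = np.abs(map_whole).max() or 1.0
    for ax, z in zip(np.atleast_1d(axes), picks):
        ax.imshow(map_whole[:, :, z].T, origin="lower", cmap="hot",
                  vmin=0, vmax=vmax)
        ax.set_title(f"z={z}", fontsize=8)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=90)
    plt.close(fig)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run every condition of the experiment matrix and write the report bundle.

    Per condition: restored (optionally cropped) cohort -> cross-validated
    training/evaluation -> metrics row -> averaged activation map + region
    table.  A failing condition is logged and skipped; the rest continue.
    """
    out = Path(cfg.output_dir)
    (out / "cams").mkdir(parents=True, exist_ok=True)
    (out / "loss_curves").mkdir(exist_ok=True)

    ss = np.random.SeedSequence(cfg.seed & 0x7FFFFFFF)
    cohort_seed, eval_seed = [int(s.generate_state(1)[0] & 0x7FFFFFFF)
                              for s in ss.spawn(2)]

    t0 = time.time()
    cohort_dir = out / "cohort"
    spec = replace(cfg.cohort, seed=cohort_seed)
    manifest = generate_cohort(spec, cohort_dir)
    atlas = AtlasVolume.from_nifti(cohort_dir / "atlas.nii.gz",
                                   cohort_dir / "atlas_labels.tsv")
    volumes = [Volume.from_nifti(cohort_dir / p) for p in manifest["volume"]]
    y = np.array([evaluation.LABEL_CODES[l] for l in manifest["label"]])
    ids = manifest["id"].tolist()
    log.info("cohort generated: %d subjects in %.1fs", len(ids), time.time() - t0)

    rows: dict[str, dict] = {}
    results: dict[str, dict] = {}
    for cond in cfg.conditions:
        t0 = time.time()
        try:
            x, box = prepare_condition(volumes, atlas, cond,
                                       cfg.crop_regions, cfg.crop_margin)
            res = run_condition(x, y, ids, cfg.model, cfg.eval, eval_seed,
                                box, atlas)
        except Exception:
            log.exception("condition %s failed; continuing", cond.name)
            continue
        rows[cond.name] = res["aggregate"]
        results[cond.name] = res
        log.info("condition %s done in %.1fs (MCC %.3f)", cond.name,
                 time.time() - t0, res["aggregate"]["mcc"][0])

        for fc in res["loss_curves"]:
            pd.DataFrame({"epoch": np.arange(1, len(fc["train_loss"]) + 1),
                          "train_loss": fc["train_loss"],
                          "test_loss": fc["test_loss"]}).to_csv(
                out / "loss_curves" / f"{cond.name}_fold{fc['fold']}.csv",
                index=False)
        whole = to_whole_grid(res["mean_map"], atlas.dims)
        Volume(np.clip(whole, 0, None)).to_nifti(
            out / "cams" / f"{cond.name}_mean.nii.gz")
        imp = res["importance"]
        pd.DataFrame({
            "region": list(imp.mean_weight),
            "mean_weight": [imp.mean_weight[r] for r in imp.mean_weight],
            "rank": [imp.ranking.index(r) + 1 if r in imp.ranking else -1
                     for r in imp.mean_weight],
        }).sort_values("mean_weight", ascending=False).to_csv(
            out / "cams" / f"{cond.name}_regions.csv", index=False)
        _save_montage(np.clip(whole, 0, None),
                      out / "cams" / f"{cond.name}_montage.png")

    table = _metrics_table(rows)
    table.to_csv(out / "metrics.csv", index=False)
    (out / "metrics.txt").write_text(_render_table(table) + "\n")
    import nibabel
    import sklearn

    from . import __version__
    run_manifest = {
        "versions": {"limbicnet": __version__, "numpy": np.__version__,
                     "nibabel": nibabel.__version__,
                     "scikit-learn": sklearn.__version__},
        "seed": cfg.seed,
        "eval_mode": cfg.eval.mode,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_subjects": len(ids),
        "conditions": [c.name for c in cfg.conditions],
        "completed": list(rows),
        "non_brain_fraction": {k: results[k]["importance"].non_brain_fraction
                               for k in results},
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    return results


# ---------------------------------------------------------------------------
# benchmark: the desk-scale analogue of the headline comparison

def benchmark_cohort_spec(seed: int) -> CohortSpec:
    """The benchmark cohort: 60 subjects (40 control / 20 AD), 64x64x40,
    0.25 hypometabolism in hippocampus + middle temporal gyrus, one scanner
    with sigma_b=2 blur and 10% noise."""
    scanner = ScannerProfile("bench", blur_sigma=2.0, noise_sd=0.10, n_slices=40)
    return CohortSpec(
        n_control=40, n_ad=20, dims=(64, 64, 40),
        effect_map={"hippocampus": 0.25, "middle_temporal": 0.25},
        scanner_profiles=((scanner, 1.0),),
        seed=seed & 0x7FFFFFFF)


def benchmark_model_config() -> ModelConfig:
    """Desk-scale network: reduced widths and epochs so 3-fold CV over two
    conditions runs in CPU minutes; architecture is otherwise unchanged."""
    return ModelConfig(input_shape=(64, 64, 40), base_channels=8,
                       stage_channels=(8, 16), fc_hidden=32,
                       lr=2e-3, weight_decay=1e-3, batch_size=4, epochs=15)


def run_benchmark(master_seed: int,
                  conditions: tuple[Condition, ...] = (
                      Condition("raw_whole", RestorationConfig("none"), False),
                      Condition("deblur_sigma2_crop",
                                RestorationConfig("deblur", sigma_b=2.0), True),
                  )) -> dict[str, dict]:
    """Generate the benchmark cohort in memory and evaluate the given
    conditions with 3-fold CV; returns per-condition aggregates and CAM
    non-brain fractions."""
    from .phantoms import build_atlas, degrade, make_phantom

    spec = benchmark_cohort_spec(master_seed)
    atlas = build_atlas(spec.dims)
    rng = np.random.default_rng(spec.seed)
    scanner = spec.scanner_profiles[0][0]
    volumes, labels = [], []
    for label in ["control"] * spec.n_control + ["ad"] * spec.n_ad:
        clean = make_phantom(atlas, label, spec.effect_map, rng,
                             subject_sd=spec.subject_sd)
        volumes.append(degrade(clean, scanner, rng))
        labels.append(label)
    y = np.array([evaluation.LABEL_CODES[l] for l in labels])
    ids = [f"sub-{i:04d}" for i in range(len(labels))]

    model_cfg = benchmark_model_config()
    out: dict[str, dict] = {}
    for cond in conditions:
        x, box = prepare_condition(volumes, atlas, cond)
        res = run_condition(x, y, ids, model_cfg,
                            EvalConfig(cv_k=3, mode="cv"),
                            seed=(master_seed + 7) & 0x7FFFFFFF,
                            box=box, atlas=atlas)
        out[cond.name] = {
            "aggregate": res["aggregate"],
            "non_brain_fraction": res["importance"].non_brain_fraction,
            "ranking": res["importance"].ranking,
            "fold_metrics": res["fold_metrics"],
        }
    return out
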