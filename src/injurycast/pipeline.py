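"""End-to-end orchestration: staged artifacts, config, and run manifests.

Stages (in method order): ``simulate`` writes a synthetic day-approach CSV;
``windows`` normalizes, pads and splits it by athlete; ``encode`` produces
image stacks; ``resample`` applies the three-step rebalancing; ``train``
fits the DCAE and the focal-loss classifier once; ``evaluate`` runs the
repeated hold-out protocol end to end; ``explain`` computes Shapley
attributions for the trained models.  Every stage writes a JSON manifest
(config echo, seeds, counts, version) so a run is reconstructible from its
artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import attribution, encoders, evaluation, models, resampling, synthetic_data, windowing

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Invalid configuration or stage ordering."""


@dataclass
class CohortConfig:
    n_athletes: int = 74
    n_days: int = 400
    prevalence_target: float = 0.013
    risk_coefficients: tuple[float, float] = synthetic_data.DEFAULT_RISK_COEFFICIENTS
    susceptibility_sd: float = 0.25


@dataclass
class EvaluationConfig:
    repeats: int = 5
    subset_fraction: float = 0.9
    sequence: str = "golden"
    threshold: float = 0.5
    test_fraction: float = 0.135  # ~10 of 74 athletes
    explain_samples: int = 20
    explain_background: int = 8


@dataclass
class RunConfig:
    """Single structured config for the whole pipeline; every default is
    recorded in the emitted manifests."""

    workdir: str = "runs/default"
    seed: int = 0
    method: str = "gasf"
    mtf_bins: int = encoders.DEFAULT_MTF_BINS
    pad_mode: str = "edge"
    focal_alpha: float | str = "auto"
    focal_gamma: float = 3.5
    cohort: CohortConfig = field(default_factory=CohortConfig)
    plan: resampling.ResamplingPlan = field(default_factory=resampling.ResamplingPlan)
    autoencoder: models.AutoencoderSpec = field(default_factory=models.AutoencoderSpec)
    classifier: models.ClassifierSpec = field(default_factory=models.ClassifierSpec)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        sections = {
            "cohort": (cfg.cohort, CohortConfig),
            "resampling": (cfg.plan, resampling.ResamplingPlan),
            "autoencoder": (cfg.autoencoder, models.AutoencoderSpec),
            "classifier": (cfg.classifier, models.ClassifierSpec),
            "evaluation": (cfg.evaluation, EvaluationConfig),
        }
        bad_keys = []
        for key, value in (data or {}).items():
            if key in sections:
                target, target_cls = sections[key]
                names = {f.name for f in dataclasses.fields(target_cls)}
                for sub_key, sub_value in (value or {}).items():
                    if sub_key not in names:
                        bad_keys.append(f"{key}.{sub_key}")
                    else:
                        setattr(target, sub_key, sub_value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                bad_keys.append(key)
        if bad_keys:
            raise PipelineError(f"unknown config keys: {', '.join(sorted(bad_keys))}")
        if cfg.method not in encoders.ENCODING_METHODS:
            raise PipelineError(
                f"unknown encoding method {cfg.method!r}; valid: {encoders.ENCODING_METHODS}")
        if isinstance(cfg.cohort.risk_coefficients, (list, tuple)):
            cfg.cohort.risk_coefficients = tuple(cfg.cohort.risk_coefficients)
        cfg.classifier.focal = models.FocalLossParams(
            alpha=0.986 if cfg.focal_alpha == "auto" else float(cfg.focal_alpha),
            gamma=cfg.focal_gamma)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _workdir(config: RunConfig) -> Path:
    path = Path(config.workdir)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(f"missing artifact {path.name}: run the {producer!r} stage first")
    return path


def _write_manifest(config: RunConfig, stage: str, info: dict) -> Path:
    payload = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        **info,
    }
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload["config"], sort_keys=True).encode()).hexdigest()[:16]
    out = _workdir(config) / f"manifest_{stage}.json"
    out.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> Path:
    records = synthetic_data.generate_cohort(
        n_athletes=config.cohort.n_athletes,
        n_days=config.cohort.n_days,
        prevalence_target=config.cohort.prevalence_target,
        risk_coefficients=config.cohort.risk_coefficients,
        seed=config.seed,
        susceptibility_sd=config.cohort.susceptibility_sd,
    )
    out = _workdir(config) / "cohort.csv"
    n_rows = synthetic_data.write_day_approach_csv(records, out)
    _write_manifest(config, "simulate", {"rows": n_rows})
    return out


def _split_athletes(athlete_ids: list[str], test_fraction: float, seed: int):
    aids = sorted(set(athlete_ids))
    n_test = max(1, int(round(test_fraction * len(aids))))
    rng = np.random.default_rng(seed)
    test = set(rng.choice(aids, size=n_test, replace=False).tolist())
    return [a for a in aids if a not in test], sorted(test)


def stage_windows(config: RunConfig) -> tuple[Path, Path]:
    src = _require(_workdir(config) / "cohort.csv", "simulate")
    raw = synthetic_data.read_day_approach_csv(src)
    normalized, _ = windowing.normalize_windows(raw)
    padded = windowing.pad_windows(normalized, mode=config.pad_mode)
    train_aids, test_aids = _split_athletes([w.athlete_id for w in padded],
                                            config.evaluation.test_fraction, config.seed)
    train = [w for w in padded if w.athlete_id in set(train_aids)]
    test = [w for w in padded if w.athlete_id in set(test_aids)]
    out_train = _workdir(config) / "windows_train.npz"
    out_test = _workdir(config) / "windows_test.npz"
    windowing.save_windows(out_train, train)
    windowing.save_windows(out_test, test)
    _write_manifest(config, "windows", {
        "n_train_windows": len(train), "n_test_windows": len(test),
        "train_athletes": train_aids, "test_athletes": test_aids,
    })
    return out_train, out_test


def _encode_windows(config: RunConfig, matrices: np.ndarray) -> np.ndarray:
    kwargs = {"q": config.mtf_bins} if config.method == "mtf" else {}
    stacks = encoders.encode_dataset(matrices, config.method, **kwargs)
    return models.scale_stack(stacks, config.method)


def stage_encode(config: RunConfig) -> tuple[Path, Path]:
    work = _workdir(config)
    outs = []
    for split in ("train", "test"):
        ws = windowing.load_windows(_require(work / f"windows_{split}.npz", "windows"))
        X, y, aids, days = windowing.windows_to_arrays(ws)
        stacks = _encode_windows(config, X)
        out = work / f"images_{split}.npz"
        np.savez(out, stacks=stacks, labels=y, athlete_ids=aids, day_indices=days)
        outs.append(out)
    _write_manifest(config, "encode", {"method": config.method,
                                       "shape": list(stacks.shape[1:])})
    return tuple(outs)


def stage_resample(config: RunConfig) -> Path:
    work = _workdir(config)
    ws = windowing.load_windows(_require(work / "windows_train.npz", "windows"))
    X, y, aids, _ = windowing.windows_to_arrays(ws)
    plan = dataclasses.replace(config.plan, seed=config.seed)
    result = resampling.multiple_resample(X.reshape(len(X), -1), y, aids, plan)
    out = work / "resampled.npz"
    np.savez(out, X=result.X, y=result.y)
    (work / "resample_provenance.json").write_text(
        json.dumps(result.provenance, indent=2, default=str))
    _write_manifest(config, "resample", {"counts": result.provenance["steps"]})
    return out


def _resolve_alpha(config: RunConfig, y_train: np.ndarray) -> models.FocalLossParams:
    if config.focal_alpha == "auto":
        alpha = models.compute_alpha(int((y_train == 1).sum()), int(y_train.size))
    else:
        alpha = float(config.focal_alpha)
    return models.FocalLossParams(alpha=alpha, gamma=config.focal_gamma)


def stage_train(config: RunConfig) -> tuple[Path, Path]:
    work = _workdir(config)
    with np.load(_require(work / "resampled.npz", "resample")) as archive:
        X_res, y_res = archive["X"], archive["y"]
    ws = windowing.load_windows(_require(work / "windows_train.npz", "windows"))
    _, y_all, _, _ = windowing.windows_to_arrays(ws)
    mats = np.clip(X_res.reshape(-1, windowing.PADDED_DAYS, windowing.N_VARIABLES), 0.0, 1.0)
    stacks = _encode_windows(config, mats)
    dcae = models.dcae_fit(stacks, config.autoencoder, seed=config.seed)
    latents = dcae.encode(stacks)
    clf_spec = dataclasses.replace(config.classifier, focal=_resolve_alpha(config, y_all))
    clf = models.dnn_fit(latents, y_res, clf_spec, seed=config.seed)

    dcae_path, clf_path = work / "dcae.npz", work / "classifier.npz"
    np.savez(dcae_path, *dcae.get_weights())
    np.savez(clf_path, *clf.get_weights())
    np.savetxt(work / "dcae_loss.csv", np.asarray(dcae.loss_history),
               header="reconstruction_mse", comments="")
    np.savetxt(work / "classifier_loss.csv", np.asarray(clf.loss_history),
               header="focal_loss", comments="")
    (work / "architecture.json").write_text(json.dumps({
        "autoencoder": dataclasses.asdict(config.autoencoder),
        "classifier": dataclasses.asdict(clf_spec),
    }, indent=2))
    _write_manifest(config, "train", {
        "final_reconstruction_loss": dcae.loss_history[-1],
        "final_classifier_loss": clf.loss_history[-1],
        "focal_alpha": clf_spec.focal.alpha,
    })
    return dcae_path, clf_path


def load_models(config: RunConfig) -> tuple[models.DCAE, models.DNNClassifier]:
    work = _workdir(config)
    arch = json.loads(_require(work / "architecture.json", "train").read_text())
    ae_spec = models.AutoencoderSpec(**{**arch["autoencoder"],
                                        "conv_channels": tuple(arch["autoencoder"]["conv_channels"])})
    clf_kwargs = dict(arch["classifier"])
    clf_kwargs["hidden_units"] = tuple(clf_kwargs["hidden_units"])
    clf_kwargs["focal"] = models.FocalLossParams(**clf_kwargs["focal"])
    clf_spec = models.ClassifierSpec(**clf_kwargs)
    dcae = models.DCAE(ae_spec, seed=config.seed)
    with np.load(work / "dcae.npz") as archive:
        dcae.set_weights([archive[k] for k in archive.files])
    clf = models.DNNClassifier(ae_spec.latent_dim, clf_spec, seed=config.seed)
    with np.load(_require(work / "classifier.npz", "train")) as archive:
        clf.set_weights([archive[k] for k in archive.files])
    return dcae, clf


def stage_evaluate(config: RunConfig) -> Path:
    work = _workdir(config)
    train = windowing.load_windows(_require(work / "windows_train.npz", "windows"))
    test = windowing.load_windows(_require(work / "windows_test.npz", "windows"))
    _, y_all, _, _ = windowing.windows_to_arrays(train)
    clf_spec = dataclasses.replace(config.classifier, focal=_resolve_alpha(config, y_all))
    hcfg = evaluation.HoldoutConfig(
        method=config.method, plan=config.plan, autoencoder=config.autoencoder,
        classifier=clf_spec, subset_fraction=config.evaluation.subset_fraction,
        repeats=config.evaluation.repeats, sequence=config.evaluation.sequence,
        threshold=config.evaluation.threshold, seed=config.seed,
        mtf_bins=config.mtf_bins,
    )
    report = evaluation.holdout_protocol(train, test, hcfg)
    out = work / "report.json"
    out.write_text(json.dumps({
        "summary": report.summary,
        "validation": [dataclasses.asdict(m) for m in report.validation],
        "test": [dataclasses.asdict(m) for m in report.test],
        "seeds": report.seeds,
    }, indent=2))
    rows = ["surface,repeat,auc,sensitivity,specificity,gmean"]
    for surface, sets in (("validation", report.validation), ("test", report.test)):
        for r, m in enumerate(sets):
            rows.append(f"{surface},{r},{m.auc:.6f},{m.sensitivity:.6f},"
                        f"{m.specificity:.6f},{m.gmean:.6f}")
    (work / "report.csv").write_text("\n".join(rows) + "\n")
    _write_manifest(config, "evaluate", {"summary": report.summary})
    return out


def stage_explain(config: RunConfig, n_samples: int | None = None,
                  n_background: int | None = None) -> Path:
    n_samples = n_samples if n_samples is not None else config.evaluation.explain_samples
    n_background = (n_background if n_background is not None
                    else config.evaluation.explain_background)
    work = _workdir(config)
    dcae, clf = load_models(config)
    ws = windowing.load_windows(_require(work / "windows_train.npz", "windows"))
    X, y, _, _ = windowing.windows_to_arrays(ws)
    stacks = _encode_windows(config, X)
    rng = np.random.default_rng(config.seed)
    # explain a label-balanced subset against a random background
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    half = max(1, n_samples // 2)
    picks = np.concatenate([
        rng.choice(pos, size=min(half, pos.size), replace=False) if pos.size else [],
        rng.choice(neg, size=min(n_samples - min(half, pos.size), neg.size), replace=False),
    ]).astype(int)
    background = stacks[rng.choice(len(stacks), size=min(n_background, len(stacks)),
                                   replace=False)]
    surface_a, surface_b = attribution.latent_variable_importance(
        dcae, clf, stacks[picks], background,
        variable_names=windowing.DEFAULT_VARIABLE_NAMES)
    heat = attribution.heatmap_matrix(surface_a)
    header = "latent," + ",".join(windowing.DEFAULT_VARIABLE_NAMES)
    lines = [header] + [
        f"latent_{i + 1}," + ",".join(f"{v:.6f}" for v in heat[i])
        for i in range(heat.shape[0])
    ]
    (work / "variable_importance.csv").write_text("\n".join(lines) + "\n")
    out = work / "latent_importance.json"
    out.write_text(json.dumps({
        "relative_importance": dict(zip(surface_b.feature_names,
                                        surface_b.relative_importance.round(6).tolist())),
        "importance": dict(zip(surface_b.feature_names,
                               surface_b.importance.round(6).tolist())),
    }, indent=2))
    _write_manifest(config, "explain", {
        "n_samples": int(len(picks)), "n_background": int(len(background)),
        "top_latent": surface_b.feature_names[int(np.argmax(surface_b.relative_importance))],
    })
    return out


STAGES = {
    "simulate": stage_simulate,
    "windows": stage_windows,
    "encode": stage_encode,
    "resample": stage_resample,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "explain": stage_explain,
}


def run(stage: str, config: RunConfig):
    """Execute one named stage (see :data:`STAGES` for the valid order)."""
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; valid: {list(STAGES)}")
    logger.info("running stage %s in %s", stage, config.workdir)
    return STAGES[stage](config)
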