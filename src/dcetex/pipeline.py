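"""End-to-end orchestration of the CAD pipeline.

One run executes: simulate (or ingest) -> pharmacokinetic fit ->
texture pseudoimages -> balanced set construction + network training ->
voxelwise scoring -> threshold sweep -> TPF/FPF evaluation and the
paired reader-comparison t-test.  Everything is seeded; re-running with
an identical configuration reproduces identical metrics.  Artifacts
(parameter volumes, the 4D texture stack + key manifest, scores, masks,
metric tables, the serialized model and a provenance log) are written
to a run directory when one is given.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .classifier import (
    ClassifierConfig,
    NNModel,
    build_training_and_verification_sets,
    predict_scores,
    train_nn,
)
from .evaluation import (
    EvaluationResult,
    TTestResult,
    confusion_counts,
    evaluate_thresholds,
    paired_difference_ttest,
    scatter_table,
    tpf_fpf,
)
from .phantom import PhantomSpec, generate_phantom, simulate_second_reader
from .pk import ParameterPseudoImages, compute_body_mask, fit_volume
from .texture import TextureConfig, texture_stage

__all__ = ["RunConfig", "SubjectResult", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run.

    ``subjects`` may list file-based inputs (dicts with ``series``,
    ``malignant_mask`` and optional ``benign_mask`` paths); when empty,
    ``n_subjects`` phantoms are simulated with per-subject seeds derived
    from ``seed``.
    """

    seed: int = 0
    n_subjects: int = 1
    training_subjects: tuple[int, ...] = (0,)
    phantom: dict = field(default_factory=dict)       # PhantomSpec overrides
    texture: dict = field(default_factory=dict)       # TextureConfig overrides
    classifier: dict = field(default_factory=dict)    # ClassifierConfig overrides
    subjects: list = field(default_factory=list)      # file-based subject manifest
    universe: str = "body"                            # "body" or "all"
    include_benign_negatives: bool = True

    def __post_init__(self) -> None:
        if self.universe not in ("body", "all"):
            raise ValueError("universe must be 'body' or 'all'")
        if not self.subjects and self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for entry in self.subjects:
            for key in ("series", "malignant_mask"):
                if key not in entry:
                    raise ValueError(f"subject manifest entry missing '{key}'")
                if not Path(entry[key]).exists():
                    raise FileNotFoundError(entry[key])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "training_subjects" in d:
            d["training_subjects"] = tuple(d["training_subjects"])
        return cls(**d)


@dataclass
class SubjectResult:
    subject: int
    scores: np.ndarray
    malignant: np.ndarray
    benign: np.ndarray
    body_mask: np.ndarray
    validity_mask: np.ndarray
    exclusion_mask: np.ndarray
    reader2_mask: np.ndarray
    pseudo: ParameterPseudoImages


@dataclass
class PipelineResult:
    config: RunConfig
    model: NNModel
    subjects: dict
    evaluation: EvaluationResult
    reader2: dict                    # subject -> (TPF, FPF)
    ttests: dict                     # (metric, threshold) -> TTestResult
    scatter: pd.DataFrame
    confusion_table: pd.DataFrame


def _load_subject(i: int, config: RunConfig):
    if config.subjects:
        entry = config.subjects[i]
        series, _ = dio.load_series(entry["series"])
        malignant, _ = dio.read_mask(entry["malignant_mask"])
        if "benign_mask" in entry:
            benign, _ = dio.read_mask(entry["benign_mask"])
        else:
            benign = np.zeros(malignant.shape, bool)
        return series, malignant, benign
    spec = PhantomSpec(**{**config.phantom, "seed": config.seed + 101 * i})
    series, malignant, benign, _ = generate_phantom(spec)
    return series, malignant, benign


def run_pipeline(config: RunConfig | dict | None = None, out_dir=None) -> PipelineResult:
    """Execute the full pipeline and (optionally) persist the run directory."""
    if config is None:
        config = RunConfig()
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    tex_cfg = TextureConfig(**{k: tuple(map(tuple, v)) if k == "directions" else tuple(v) if isinstance(v, list) else v for k, v in config.texture.items()})
    cls_cfg = ClassifierConfig(**{**config.classifier, "seed": config.classifier.get("seed", config.seed)})
    n_subjects = len(config.subjects) or config.n_subjects

    subjects: dict[int, SubjectResult] = {}
    feature_stacks: dict[int, np.ndarray] = {}
    feature_keys = None
    train_sets, verify_sets = [], []
    for i in range(n_subjects):
        series, malignant, benign, = _load_subject(i, config)
        body = compute_body_mask(series.baseline)
        pseudo = fit_volume(series, body)
        tex = texture_stage(pseudo, tex_cfg)
        stack, keys = tex.feature_stack()
        feature_keys = keys
        exclusion = np.zeros(body.shape, bool)
        if i in config.training_subjects:
            tr, ver = build_training_and_verification_sets(
                malignant,
                body,
                tex.validity_mask,
                stack,
                seed=config.seed + 977 * i,
                benign_mask=benign if config.include_benign_negatives else None,
            )
            train_sets.append(tr)
            verify_sets.append(ver)
            for s in (tr, ver):
                exclusion[s.coords[:, 0], s.coords[:, 1], s.coords[:, 2]] = True
        reader2 = simulate_second_reader(
            malignant, PhantomSpec(**config.phantom).reader2_error
            if not config.subjects
            else (1, 0.0),
            seed=config.seed + 13 * i,
        )
        subjects[i] = SubjectResult(
            i, np.zeros(body.shape), malignant, benign, body,
            tex.validity_mask, exclusion, reader2, pseudo,
        )
        feature_stacks[i] = stack

    if not train_sets:
        raise ValueError("no training subject produced a training set")

    def concat(sets):
        coords = np.concatenate([s.coords for s in sets])
        feats = np.concatenate([s.features for s in sets])
        labels = np.concatenate([s.labels for s in sets])
        # per-subject sets are balanced to +-1; pooling can stack the odd
        # voxels, so trim trailing majority-class voxels back to balance
        while abs(2 * labels.sum() - labels.size) > 1:
            majority = 1.0 if labels.sum() * 2 > labels.size else 0.0
            drop = np.flatnonzero(labels == majority)[-1]
            keep = np.arange(labels.size) != drop
            coords, feats, labels = coords[keep], feats[keep], labels[keep]
        return type(sets[0])(coords, feats, labels, sets[0].seed)

    names = [f"{p}/{s}/{d}" for p, s, d in feature_keys]
    model = train_nn(concat(train_sets), concat(verify_sets), cls_cfg, feature_names=names)

    per_subject: dict[int, dict] = {}
    pooled_counts: dict[float, list] = {t: None for t in cls_cfg.thresholds}
    reader2_perf: dict[int, tuple] = {}
    excluded_total = 0
    conf_rows = []
    for i, sub in subjects.items():
        sub.scores = predict_scores(model, feature_stacks[i], sub.body_mask, sub.validity_mask)
        universe = (
            sub.body_mask & sub.validity_mask if config.universe == "body" else None
        )
        counts = evaluate_thresholds(
            sub.scores, sub.malignant, cls_cfg.thresholds, sub.exclusion_mask, universe
        )
        per_subject[i] = {}
        for thr, c in counts.items():
            per_subject[i][thr] = tpf_fpf(c)
            prev = pooled_counts[thr]
            pooled_counts[thr] = c if prev is None else type(c)(
                prev.TP + c.TP, prev.FP + c.FP, prev.TN + c.TN, prev.FN + c.FN
            )
            conf_rows.append(
                (i, "classifier", thr, c.TP, c.FP, c.TN, c.FN, *per_subject[i][thr])
            )
        rc = confusion_counts(sub.reader2_mask, sub.malignant, sub.exclusion_mask, universe)
        reader2_perf[i] = tpf_fpf(rc)
        conf_rows.append((i, "reader2", np.nan, rc.TP, rc.FP, rc.TN, rc.FN, *reader2_perf[i]))
        excluded_total += int(sub.exclusion_mask.sum())
        del feature_stacks[i]

    pooled = {thr: tpf_fpf(c) for thr, c in pooled_counts.items()}
    evaluation = EvaluationResult(per_subject, pooled, excluded_total)
    table = scatter_table(evaluation, reader2_perf)

    ttests: dict[tuple[str, float], TTestResult] = {}
    if n_subjects >= 2:
        for mi, metric in enumerate(("TPF", "FPF")):
            reader_vec = np.array([reader2_perf[i][mi] for i in subjects])
            for thr in cls_cfg.thresholds:
                cls_vec = np.array([per_subject[i][thr][mi] for i in subjects])
                if np.any([v is None for v in cls_vec]) or np.any(
                    [v is None for v in reader_vec]
                ):
                    continue
                ttests[(metric, thr)] = paired_difference_ttest(
                    cls_vec.astype(float), reader_vec.astype(float)
                )

    confusion_table = pd.DataFrame(
        conf_rows,
        columns=["subject", "source", "threshold", "TP", "FP", "TN", "FN", "TPF", "FPF"],
    )
    result = PipelineResult(
        config, model, subjects, evaluation, reader2_perf, ttests, table, confusion_table
    )

    if out_dir is not None:
        _write_run(Path(out_dir), result, tex_cfg, cls_cfg, feature_keys)
    return result


def _write_run(out: Path, result: PipelineResult, tex_cfg, cls_cfg, feature_keys) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = result.config.to_dict()
    for i, sub in result.subjects.items():
        sdir = out / f"subject_{i:02d}"
        sdir.mkdir(exist_ok=True)
        for name, vol in result.subjects[i].pseudo.volumes().items():
            dio.write_volume(sdir / f"pk_{name}.nii.gz", vol.astype(np.float32))
        dio.write_volume(sdir / "scores.nii.gz", sub.scores.astype(np.float32))
        dio.write_mask(sdir / "malignant_truth.nii.gz", sub.malignant)
        dio.write_mask(sdir / "reader2.nii.gz", sub.reader2_mask)
        dio.write_mask(sdir / "validity.nii.gz", sub.validity_mask)
        for thr in cls_cfg.thresholds:
            dio.write_mask(
                sdir / f"pred_thr{int(round(thr * 100)):02d}.nii.gz",
                sub.scores >= thr,
            )
    (out / "model.json").write_text(result.model.to_json())
    result.confusion_table.to_csv(out / "confusion.csv", index=False)
    result.scatter.to_csv(out / "scatter.csv", index=False)
    tt_rows = [
        (m, thr, t.mean_diff, t.t_statistic, t.df, t.p_value, t.alpha, t.reject, t.degenerate_variance)
        for (m, thr), t in result.ttests.items()
    ]
    pd.DataFrame(
        tt_rows,
        columns=["metric", "threshold", "mean_diff", "t", "df", "p", "alpha", "reject", "degenerate"],
    ).to_csv(out / "ttest.csv", index=False)
    log = {
        "seed": result.config.seed,
        "config": cfg_dict,
        "config_hash": dio.config_hash(cfg_dict),
        "texture_config": asdict(tex_cfg),
        "classifier_config": asdict(cls_cfg),
        "n_feature_maps": len(feature_keys),
        "feature_keys": [f"{p}/{s}/{'{}{}{}'.format(*d)}" for p, s, d in feature_keys],
        "dropped_features": result.model.dropped_features.tolist(),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
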