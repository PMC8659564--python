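"""Metrics, model selection and leave-one-subject-out evaluation.

Accuracy is reported as root-mean-square error in degrees,

    RMSE = sqrt( sum_i (theta_hat_i - theta_i)^2 / N ),

and the Pearson correlation coefficient r between the predicted and
measured angle series, both computed after the network output is returned
to its real range with the inverse min-max transform.

Leave-one-subject-out (LOSO) cross-validation holds out each subject in
turn: the amplitude scalers, the per-channel alignment lags and the model
are fitted on the remaining subjects only, then applied unchanged to the
held-out subject — the held-out extrema and lags are never consulted, which
is what makes the per-subject scores a measure of inter-subject
generalizability.  Per-subject metrics pool all loading conditions; the
roll-up reports best / worst / average +- sd across subjects per joint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import (
    apply_lag_profile,
    dwt_approximation,
    estimate_lag_profile,
    LagProfile,
)
from .preprocessing import (
    CycleSet,
    ScalerParams,
    build_cycle_set,
    denormalize,
    fit_scaler,
    normalize,
)
from .regressors import (
    DivergenceError,
    ModelConfig,
    from_sequences,
    to_sequences,
    train_lstm,
    train_mlp,
)
from .synthetic import Recording

__all__ = [
    "rmse",
    "pearson_r",
    "EvalReport",
    "PreparedDataset",
    "extract_envelopes",
    "prepare_dataset",
    "loso_cv",
    "kfold_select",
    "cc_ablation",
]


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Root-mean-square error between two equal-length series (degrees)."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.size != truth.size or pred.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    d = pred - truth
    return float(np.sqrt(np.mean(d * d)))


def pearson_r(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation coefficient between prediction and truth."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.size != truth.size or pred.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    pc = pred - pred.mean()
    tc = truth - truth.mean()
    denom = np.sqrt(np.mean(pc * pc)) * np.sqrt(np.mean(tc * tc))
    if denom == 0.0:
        raise ValueError("constant series: correlation undefined")
    return float(np.mean(pc * tc) / denom)


@dataclass
class EvalReport:
    """Per-subject and rolled-up accuracy of one evaluated configuration."""

    joints: tuple[str, ...]
    per_subject: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    lag_profiles: dict[str, LagProfile] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.errors

    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.per_subject})

    def metric_values(self, joint: str, metric: str) -> np.ndarray:
        return np.array(
            [
                self.per_subject[(s, joint)][metric]
                for s in self.subjects()
                if (s, joint) in self.per_subject
            ]
        )

    def mean_r(self, joint: str) -> float:
        return float(self.metric_values(joint, "r").mean())

    def mean_rmse(self, joint: str) -> float:
        return float(self.metric_values(joint, "rmse").mean())

    def rollup(self) -> dict[str, dict[str, dict[str, float]]]:
        """Best / worst / average +- sd per joint, for RMSE and r."""
        out: dict[str, dict[str, dict[str, float]]] = {}
        for joint in self.joints:
            e = self.metric_values(joint, "rmse")
            r = self.metric_values(joint, "r")
            out[joint] = {
                "rmse": {
                    "best": float(e.min()),
                    "worst": float(e.max()),
                    "average": float(e.mean()),
                    "sd": float(e.std(ddof=1)) if e.size > 1 else 0.0,
                },
                "r": {
                    "best": float(r.max()),
                    "worst": float(r.min()),
                    "average": float(r.mean()),
                    "sd": float(r.std(ddof=1)) if r.size > 1 else 0.0,
                },
            }
        return out

    def to_frame(self) -> pd.DataFrame:
        """Best/Worse/Average table per joint and metric."""
        roll = self.rollup()
        rows = []
        for row in ("best", "worst", "average"):
            entry: dict[str, object] = {"Subject": row.capitalize()}
            for joint in self.joints:
                for metric in ("rmse", "r"):
                    val = roll[joint][metric][row]
                    if row == "average":
                        sd = roll[joint][metric]["sd"]
                        entry[f"{joint} {metric}"] = f"{val:.3f} +- {sd:.3f}"
                    else:
                        entry[f"{joint} {metric}"] = f"{val:.3f}"
            rows.append(entry)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "per_subject": {
                f"{s}/{j}": m for (s, j), m in sorted(self.per_subject.items())
            },
            "rollup": self.rollup(),
            "errors": dict(self.errors),
        }


def extract_envelopes(
    cycle_set: CycleSet, wavelet_name: str = "sym8", level: int = 8
) -> np.ndarray:
    """Wavelet-approximation envelope of every feature channel of a cycle set."""
    return np.vstack(
        [
            dwt_approximation(row, wavelet_name=wavelet_name, level=level)
            for row in cycle_set.features_raw
        ]
    )


@dataclass
class PreparedDataset:
    """Fold-independent artefacts: cycle sets plus envelope features."""

    sets: list[tuple[CycleSet, np.ndarray]]
    channels: tuple[str, ...]
    joints: tuple[str, ...]
    n_points: int

    def subjects(self) -> list[str]:
        return sorted({cs.subject_id for cs, _ in self.sets})


def prepare_dataset(
    dataset: list[Recording],
    n_points: int = 1000,
    wavelet_name: str = "sym8",
    level: int = 8,
    prep_kwargs: dict | None = None,
) -> PreparedDataset:
    """Segment every recording and attach its envelope features.

    Preprocessing and wavelet extraction do not depend on the train/test
    split, so the result can be shared across folds and evaluation arms.
    """
    kw = prep_kwargs or {}
    sets = []
    for rec in dataset:
        cs = build_cycle_set(rec, n_points=n_points, **kw)
        sets.append((cs, extract_envelopes(cs, wavelet_name, level)))
    return PreparedDataset(
        sets=sets,
        channels=tuple(dataset[0].channels),
        joints=tuple(dataset[0].joints),
        n_points=n_points,
    )


def _as_prepared(
    dataset: list[Recording] | PreparedDataset,
    n_points: int,
    wavelet_name: str,
    level: int,
    prep_kwargs: dict | None,
) -> PreparedDataset:
    if isinstance(dataset, PreparedDataset):
        return dataset
    return prepare_dataset(dataset, n_points, wavelet_name, level, prep_kwargs)


def _stride_matrix(m: np.ndarray, seq_len: int, stride: int) -> np.ndarray:
    if stride == 1:
        return m
    return from_sequences(to_sequences(m, seq_len, stride))


def _fit_and_score(
    train: list[tuple[CycleSet, np.ndarray]],
    test: list[tuple[CycleSet, np.ndarray]],
    cfg: ModelConfig,
    use_cc: bool,
    channels: tuple[str, ...],
    joints: tuple[str, ...],
    k_max: int,
    channel_joint_map: dict[str, str] | None,
) -> tuple[dict[str, dict[str, float]], LagProfile | None, np.ndarray, np.ndarray]:
    """Train on ``train`` cycle sets, score per subject on ``test``.

    Returns per-(subject, joint) metrics, the training lag profile, and the
    concatenated (denormalized) test predictions and truths.
    """
    n_points = train[0][0].n_points
    cfg = replace(cfg, seq_len=n_points)
    feat_train = np.hstack([env for _, env in train])
    targ_train = np.hstack([cs.targets for cs, _ in train])
    feat_scaler = fit_scaler(feat_train)
    targ_scaler = fit_scaler(targ_train)
    fn_blocks = [normalize(env, feat_scaler) for _, env in train]
    tn_train = normalize(targ_train, targ_scaler)
    profile: LagProfile | None = None
    if use_cc:
        profile = estimate_lag_profile(
            np.hstack(fn_blocks),
            tn_train,
            channels,
            joints,
            k_max=k_max,
            channel_joint_map=channel_joint_map,
        )
        fn_blocks = [apply_lag_profile(b, profile) for b in fn_blocks]
    fn_train = np.hstack(fn_blocks)

    if cfg.arch == "lstm":
        model, _ = train_lstm(fn_train, tn_train, cfg)
    elif cfg.arch == "mlp":
        strided = _stride_matrix(fn_train, n_points, cfg.seq_stride)
        strided_t = _stride_matrix(tn_train, n_points, cfg.seq_stride)
        model, _ = train_mlp(strided, strided_t, cfg)
    else:
        raise ValueError(f"unknown architecture {cfg.arch!r}")

    metrics: dict[str, dict[str, float]] = {}
    preds_by_subject: dict[str, list[np.ndarray]] = {}
    truth_by_subject: dict[str, list[np.ndarray]] = {}
    for cs, env in test:
        fn = normalize(env, feat_scaler)
        if profile is not None:
            fn = apply_lag_profile(fn, profile)
        if cfg.arch == "lstm":
            pred_n = model.predict_matrix(fn)
        else:
            pred_n = model.predict_matrix(_stride_matrix(fn, n_points, cfg.seq_stride))
        pred = denormalize(pred_n, targ_scaler)
        truth = _stride_matrix(cs.targets, n_points, cfg.seq_stride)
        preds_by_subject.setdefault(cs.subject_id, []).append(pred)
        truth_by_subject.setdefault(cs.subject_id, []).append(truth)
    all_pred, all_truth = [], []
    for subject in sorted(preds_by_subject):
        pred = np.hstack(preds_by_subject[subject])
        truth = np.hstack(truth_by_subject[subject])
        all_pred.append(pred)
        all_truth.append(truth)
        for j, joint in enumerate(joints):
            metrics[f"{subject}/{joint}"] = {
                "rmse": rmse(pred[j], truth[j]),
                "r": pearson_r(pred[j], truth[j]),
            }
    return metrics, profile, np.hstack(all_pred), np.hstack(all_truth)


def loso_cv(
    dataset: "list[Recording] | PreparedDataset",
    cfg: ModelConfig,
    use_cc: bool = True,
    n_points: int = 1000,
    wavelet_name: str = "sym8",
    level: int = 8,
    k_max: int = 300,
    channel_joint_map: dict[str, str] | None = None,
    prep_kwargs: dict | None = None,
) -> tuple[EvalReport, dict[str, np.ndarray]]:
    """Leave-one-subject-out evaluation of one model configuration.

    For every held-out subject, scalers, lag profile and model are fitted on
    the remaining subjects and applied unchanged to the held-out data; the
    per-fold predictions are denormalized and concatenated in subject order.
    Returns the report and ``{"pred", "truth"}`` concatenated matrices.
    ``dataset`` may be raw recordings or an already :func:`prepare_dataset`
    result (shared across evaluation arms).
    """
    prep = _as_prepared(dataset, n_points, wavelet_name, level, prep_kwargs)
    subjects = prep.subjects()
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    channels = prep.channels
    joints = prep.joints
    report = EvalReport(joints=tuple(joints))
    preds, truths = [], []
    for fold_idx, held_out in enumerate(subjects):
        train = [p for p in prep.sets if p[0].subject_id != held_out]
        test = [p for p in prep.sets if p[0].subject_id == held_out]
        fold_cfg = replace(cfg, seed=cfg.seed + fold_idx)
        try:
            metrics, profile, pred, truth = _fit_and_score(
                train, test, fold_cfg, use_cc, channels, joints, k_max,
                channel_joint_map,
            )
        except DivergenceError as exc:
            report.errors[held_out] = str(exc)
            continue
        for key, m in metrics.items():
            subject, joint = key.split("/")
            report.per_subject[(subject, joint)] = m
        if profile is not None:
            report.lag_profiles[held_out] = profile
        preds.append(pred)
        truths.append(truth)
    concatenated = {
        "pred": np.hstack(preds) if preds else np.empty((len(joints), 0)),
        "truth": np.hstack(truths) if truths else np.empty((len(joints), 0)),
    }
    return report, concatenated


def kfold_select(
    dataset: "list[Recording] | PreparedDataset",
    candidate_configs: list[ModelConfig],
    K: int = 5,
    seed: int = 0,
    use_cc: bool = True,
    n_points: int = 1000,
    **pipeline_kwargs,
) -> ModelConfig:
    """Choose the candidate maximizing mean validation r over subject folds.

    Folds partition subjects (never time points).  Ties break toward lower
    mean RMSE, then toward the first-listed candidate.
    """
    prep = _as_prepared(
        dataset,
        n_points,
        pipeline_kwargs.get("wavelet_name", "sym8"),
        pipeline_kwargs.get("level", 8),
        pipeline_kwargs.get("prep_kwargs"),
    )
    subjects = prep.subjects()
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > len(subjects):
        raise ValueError(f"K={K} exceeds the {len(subjects)} subjects")
    if not candidate_configs:
        raise ValueError("no candidate configurations")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(subjects))
    folds = [order[i::K] for i in range(K)]
    channels = prep.channels
    joints = prep.joints
    k_max = pipeline_kwargs.get("k_max", 300)
    cmap = pipeline_kwargs.get("channel_joint_map")
    scores = []
    for cfg in candidate_configs:
        rs, es = [], []
        for fold in folds:
            train = [p for p in prep.sets if p[0].subject_id not in fold]
            test = [p for p in prep.sets if p[0].subject_id in fold]
            metrics, _, _, _ = _fit_and_score(
                train, test, cfg, use_cc, channels, joints, k_max, cmap
            )
            rs.extend(m["r"] for m in metrics.values())
            es.extend(m["rmse"] for m in metrics.values())
        scores.append((float(np.mean(rs)), -float(np.mean(es))))
    best = max(range(len(candidate_configs)), key=lambda i: scores[i])
    return candidate_configs[best]


def cc_ablation(
    dataset: "list[Recording] | PreparedDataset",
    cfg: ModelConfig,
    **pipeline_kwargs,
) -> dict[str, object]:
    """Paired LOSO runs with and without cross-correlation alignment.

    Both arms share seeds and fold memberships; the result carries both
    reports plus the per-joint deltas in mean r and mean RMSE
    (with-CC minus without-CC).
    """
    with_cc, _ = loso_cv(dataset, cfg, use_cc=True, **pipeline_kwargs)
    without_cc, _ = loso_cv(dataset, cfg, use_cc=False, **pipeline_kwargs)
    joints = with_cc.joints
    return {
        "with_cc": with_cc,
        "without_cc": without_cc,
        "delta_r": {
            j: with_cc.mean_r(j) - without_cc.mean_r(j) for j in joints
        },
        "delta_rmse": {
            j: with_cc.mean_rmse(j) - without_cc.mean_rmse(j) for j in joints
        },
    }
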