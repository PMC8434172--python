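"""End-to-end experiment orchestration on phantom cohorts.

The flow mirrors a confidence-aware classification study: for each
cross-validation fold — segment (or load ground-truth) epidermis masks,
build skin layer maps, extract the chosen ROI variant, train a 4-class
CNN with the chosen augmentation mode, predict on the held-out patients,
compute a Grad-CAM map for each prediction (targeting the predicted
class), score it against the skin layer map to get the per-sample CCL,
and finally run the dataset-level percentile sweep yielding the
multicriteria measure ``m`` with its optimal cutoff ``p_opt``.

Cross-validation is patient-wise: all images of one patient fall on one
side of every train/test split, and the non-test patients are further
split 8:1 into training and validation patients.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .confidence import compute_ccl
from .gradcam import align_map, gradcam_raw, normalize_map
from .model_eval import ModelEvalResult, evaluate_model
from .phantom import PhantomSample
from .roi import RoiResult, RoiSpec, extract_roi
from .slm import build_slm
from .types import CLASS_NAMES, CLASS_TO_INDEX

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, mode: str, rng: np.random.Generator) -> np.ndarray:
    """One random geometric transform draw.

    ``Aug0``: random horizontal (lateral) reflection plus ±10-pixel
    translation in both directions, zero fill. ``Aug1``: additionally a
    random rotation uniform in ±20°, bilinear resampling with zero fill.
    """
    if mode not in ("Aug0", "Aug1"):
        raise ValueError(f"unknown augmentation mode {mode!r}")
    out = image
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if mode == "Aug1":
        angle = rng.uniform(-20.0, 20.0)
        out = ndimage.rotate(out, angle, reshape=False, order=1, cval=0.0)
    dy, dx = rng.integers(-10, 11, size=2)
    out = ndimage.shift(out, (dy, dx), order=0, cval=0.0)
    return out


# ---------------------------------------------------------------------------
# Patient-wise cross-validation
# ---------------------------------------------------------------------------

def patientwise_kfold(manifest: pd.DataFrame, k: int, seed: int = 0) -> pd.DataFrame:
    """Assign every patient to exactly one test fold, class-balanced.

    ``manifest`` needs ``patient_id`` and ``label`` columns. Within each
    class, patients are shuffled and dealt round-robin to folds, so fold
    class composition is balanced to within one patient. Non-test patients
    are split 8:1 (by patient) into train and validation roles per fold.

    Returns the manifest with an added integer ``fold`` column (the test
    fold of each image) and a ``role_in_fold0..k-1`` encoding handled by
    :func:`fold_roles`.
    """
    if "patient_id" not in manifest.columns:
        raise ValueError("manifest must have a patient_id column")
    pat = manifest[["patient_id", "label"]].drop_duplicates("patient_id")
    if len(pat) < k:
        raise ValueError(f"only {len(pat)} patients for {k} folds")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    offset = 0
    for label in sorted(pat["label"].unique()):
        ids = pat.loc[pat["label"] == label, "patient_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        for i, pid in enumerate(ids):
            fold_of[pid] = (i + offset) % k
        offset += len(ids)  # stagger classes across folds
    out = manifest.copy()
    out["fold"] = out["patient_id"].map(fold_of).astype(int)
    return out


def fold_roles(manifest: pd.DataFrame, fold: int, seed: int = 0
               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(train, val, test) frames for one fold; 8:1 patient-wise train/val."""
    test = manifest[manifest["fold"] == fold]
    rest = manifest[manifest["fold"] != fold]
    patients = np.sort(rest["patient_id"].unique())
    rng = np.random.default_rng(seed * 1000 + fold)
    patients = patients[rng.permutation(len(patients))]
    n_val = max(len(patients) // 9, 1)
    val_patients = set(patients[:n_val])
    val = rest[rest["patient_id"].isin(val_patients)]
    train = rest[~rest["patient_id"].isin(val_patients)]
    return train, val, test


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Knobs of one end-to-end phantom experiment."""

    roi_mode: int = 4
    augmentation: str = "Aug0"
    folds: int = 10
    batch_size: int = 8
    max_epochs: int = 50
    learning_rate: float = 0.02
    momentum: float = 0.9
    input_size: int = 32          # classifier input (square, bilinear resize)
    base_channels: int = 8
    use_ground_truth_masks: bool = True
    gel_band_px: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.augmentation not in ("Aug0", "Aug1"):
            raise ValueError("augmentation must be Aug0 or Aug1")
        RoiSpec(self.roi_mode)  # validates


def build_classifier(input_size: int = 32, base_channels: int = 8,
                     n_classes: int = 4, rng=None) -> nn.Sequential:
    """A small 4-class CNN: three conv/ReLU blocks (two pooled), global
    average pooling, linear head. The last ReLU output is the default
    Grad-CAM feature-map layer."""
    rng = rng or np.random.default_rng()
    c = base_channels
    return nn.Sequential([
        nn.Conv2D(1, c, 3, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(c, 2 * c, 3, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(2 * c, 4 * c, 3, rng), nn.ReLU(),
        nn.GlobalAvgPool(), nn.Linear(4 * c, n_classes, rng),
    ])


def standardize_roi(roi_image: np.ndarray, input_size: int) -> np.ndarray:
    """Classifier input standardization: bilinear (aspect-distorting)
    resize to the fixed square input, then zero-mean shift."""
    out = resize(roi_image, (input_size, input_size), order=1, anti_aliasing=True)
    return out - 0.5


def train_classifier(inputs: np.ndarray, labels: np.ndarray,
                     config: ExperimentConfig, rng: np.random.Generator,
                     ) -> tuple[nn.Sequential, list[float]]:
    """Train the small CNN on pre-standardized ROI inputs.

    ``inputs``: (N, H, W) standardized images; ``labels``: (N,) class
    indices. Augmentation (per the config mode) is drawn per epoch and
    sample. All four classes must be present.
    """
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("training data must contain at least two classes")
    model = build_classifier(config.input_size, config.base_channels, rng=rng)
    opt = nn.SGDMomentum(model.parameters(), lr=config.learning_rate,
                         momentum=config.momentum)
    n = len(inputs)
    log: list[float] = []
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            xb = np.stack([augment(inputs[i], config.augmentation, rng)
                           for i in idx])[:, None]
            logits = model.forward(xb)
            loss, grad = nn.cross_entropy_grad(logits, labels[idx])
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        log.append(epoch_loss / n)
    return model, log


def confusion_and_accuracy(preds, truths) -> tuple[np.ndarray, float]:
    """4x4 confusion matrix in fixed class order and its accuracy.

    Rows are true classes, columns predicted, order
    (AD, psoriasis, tumor, control). Labels may be names or indices.
    """
    def to_idx(x):
        if isinstance(x, str):
            if x not in CLASS_TO_INDEX:
                raise ValueError(f"unknown class label {x!r}")
            return CLASS_TO_INDEX[x]
        x = int(x)
        if not 0 <= x < len(CLASS_NAMES):
            raise ValueError(f"class index {x} out of range")
        return x

    preds = [to_idx(p) for p in preds]
    truths = [to_idx(t) for t in truths]
    if len(preds) != len(truths):
        raise ValueError("prediction/truth lengths differ")
    cm = np.zeros((4, 4), dtype=int)
    for p, t in zip(preds, truths):
        cm[t, p] += 1
    acc = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return cm, acc


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    """Everything the end-to-end run computes."""

    per_sample: pd.DataFrame           # file,fold,label,pred,correct,ccl,M
    fold_accuracies: list[float]
    accuracy: float
    mean_ccl: float
    eval_result: ModelEvalResult
    confusion_full: np.ndarray
    confusion_popt: np.ndarray
    accuracy_popt: float
    n_skipped: int = 0
    timings: dict = field(default_factory=dict)

    def summary(self) -> dict:
        opt = self.eval_result.at_opt()
        return {
            "accuracy": self.accuracy,
            "mean_ccl": self.mean_ccl,
            "m": self.eval_result.m,
            "p_opt": self.eval_result.p_opt,
            "a_popt": opt.a_p,
            "coverage_popt": opt.n_p / self.eval_result.N,
            "t_popt": opt.t_p,
            "N": self.eval_result.N,
            "n_skipped": self.n_skipped,
        }


def _prepare_sample(sample: PhantomSample, mask, config: ExperimentConfig
                    ) -> tuple[np.ndarray, np.ndarray, RoiResult]:
    """SLM + ROI + standardized classifier input for one sample."""
    H = build_slm(mask, sample.image.axial_res, gel_band_px=config.gel_band_px)
    roi = extract_roi(sample.image, mask, H, RoiSpec(config.roi_mode))
    x = standardize_roi(roi.image_roi, config.input_size)
    return x, H, roi


def run_experiment(samples: list[PhantomSample], config: ExperimentConfig,
                   segmenter=None, out_dir: str | Path | None = None
                   ) -> ExperimentReport:
    """Run the full patient-wise cross-validated experiment.

    With ``config.use_ground_truth_masks`` the stored phantom masks drive
    the SLM/ROI stages; otherwise ``segmenter`` (a trained
    :class:`~usconf.segmentation.SegmenterModel`) is applied first.
    Per-sample failures (e.g. empty predicted masks) are skipped with a
    logged reason; the experiment fails if more than 10% are skipped.
    """
    from .segmentation import segment  # local import to avoid cycle

    t0 = time.time()
    manifest = pd.DataFrame({
        "index": np.arange(len(samples)),
        "label": [s.label for s in samples],
        "patient_id": [s.patient_id for s in samples],
    })
    manifest = patientwise_kfold(manifest, config.folds, seed=config.seed)

    # Stage 1: masks -> SLM -> ROI -> standardized inputs.
    prepared: dict[int, tuple] = {}
    skipped: list[tuple[int, str]] = []
    for i, s in enumerate(samples):
        try:
            if config.use_ground_truth_masks or segmenter is None:
                mask = s.mask
            else:
                mask = segment(segmenter, s.image)
            prepared[i] = _prepare_sample(s, mask, config)
        except ValueError as exc:
            logger.warning("sample %d skipped: %s", i, exc)
            skipped.append((i, str(exc)))
    if len(skipped) > 0.1 * len(samples):
        raise RuntimeError(
            f"{len(skipped)}/{len(samples)} samples failed preparation"
        )
    t_prep = time.time() - t0

    labels_idx = np.array([CLASS_TO_INDEX[s.label] for s in samples])
    rows = []
    fold_accs: list[float] = []
    t_train = 0.0
    for fold in range(config.folds):
        train_df, val_df, test_df = fold_roles(manifest, fold, seed=config.seed)
        train_ids = [i for i in train_df["index"] if i in prepared]
        val_ids = [i for i in val_df["index"] if i in prepared]
        test_ids = [i for i in test_df["index"] if i in prepared]
        fit_ids = train_ids + val_ids  # small nets: no early stopping, val folded in

        rng = np.random.default_rng(config.seed * 100 + fold)
        x_fit = np.array([prepared[i][0] for i in fit_ids])
        y_fit = labels_idx[fit_ids]
        tt = time.time()
        model, _ = train_classifier(x_fit, y_fit, config, rng)
        t_train += time.time() - tt

        correct_fold = 0
        for i in test_ids:
            x, H, roi = prepared[i]
            logits = model.forward(x[None, None])
            pred = int(np.argmax(logits[0]))
            cam = gradcam_raw(model, x[None], target_class=pred)
            L = normalize_map(cam.raw)
            L_full = align_map(L, samples[i].image.shape, roi)
            res = compute_ccl(L_full, H, sample_id=str(i))
            correct = pred == labels_idx[i]
            correct_fold += int(correct)
            rows.append({
                "index": i, "fold": fold, "label": samples[i].label,
                "patient_id": samples[i].patient_id,
                "pred": CLASS_NAMES[pred], "correct": bool(correct),
                "ccl": res.t, "M": res.M,
            })
        fold_accs.append(correct_fold / max(len(test_ids), 1))

    per_sample = pd.DataFrame(rows)
    accuracy = float(per_sample["correct"].mean())
    mean_ccl = float(per_sample["ccl"].mean())
    eval_result = evaluate_model(per_sample["ccl"].to_numpy(),
                                 per_sample["correct"].to_numpy())
    cm_full, _ = confusion_and_accuracy(per_sample["pred"], per_sample["label"])
    opt = eval_result.at_opt()
    keep = per_sample["ccl"].to_numpy() > opt.t_p
    sub = per_sample[keep]
    if len(sub):
        cm_popt, acc_popt = confusion_and_accuracy(sub["pred"], sub["label"])
    else:
        cm_popt, acc_popt = np.zeros((4, 4), dtype=int), 0.0

    report = ExperimentReport(
        per_sample=per_sample, fold_accuracies=fold_accs, accuracy=accuracy,
        mean_ccl=mean_ccl, eval_result=eval_result, confusion_full=cm_full,
        confusion_popt=cm_popt, accuracy_popt=acc_popt,
        n_skipped=len(skipped),
        timings={"prepare_s": t_prep, "train_s": t_train,
                 "total_s": time.time() - t0},
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: ExperimentReport, out_dir: str | Path) -> None:
    """Persist the report tables: per-sample CSV, sweep CSV, summary JSON,
    confusion matrices, and the sweep chart."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_sample.to_csv(out / "per_sample.csv", index=False)
    report.eval_result.to_frame().to_csv(out / "sweep.csv", index=False)
    for name, cm in (("confusion_full", report.confusion_full),
                     ("confusion_popt", report.confusion_popt)):
        pd.DataFrame(cm, index=CLASS_NAMES, columns=CLASS_NAMES).to_csv(
            out / f"{name}.csv")
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2)
    from .model_eval import plot_sweep

    plot_sweep(report.eval_result, out / "sweep.png")
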