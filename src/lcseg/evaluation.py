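"""Segmentation metrics, post-processing, and cross-validation harnesses.

Conventions chosen where the field leaves them open: connected components
use 26-connectivity; the Dice of two empty masks is defined as 1 (with a
warning); component-size ties break toward the component containing the
smallest flat voxel index, so post-processing is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import clone

from .io_core import BinaryMask, SoftMask, Volume, _check_same_grid


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Both masks empty is degenerate and returns 1 with a warning.
    """
    _check_same_grid(a, b)
    da = np.asarray(a.data, dtype=bool)
    db = np.asarray(b.data, dtype=bool)
    denom = int(da.sum()) + int(db.sum())
    if denom == 0:
        warnings.warn("Dice of two empty masks; returning 1 by convention")
        return 1.0
    return 2.0 * int((da & db).sum()) / denom


def sensitivity(pred: BinaryMask, truth: BinaryMask) -> float:
    """Fraction of truth voxels covered by the prediction."""
    _check_same_grid(pred, truth)
    dt = np.asarray(truth.data, dtype=bool)
    n_truth = int(dt.sum())
    if n_truth == 0:
        raise ValueError("sensitivity undefined for an empty truth mask")
    return int((np.asarray(pred.data, dtype=bool) & dt).sum()) / n_truth


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def binarize_lcc(s: Volume, threshold: float = 0.5) -> BinaryMask:
    """Threshold a soft mask and keep the largest 26-connected component.

    An empty post-threshold mask yields an empty output (callers treat it
    as a failure case).  Size ties break toward the component holding the
    smallest flat voxel index.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    binary = np.asarray(s.data) > threshold
    if not binary.any():
        return BinaryMask(np.zeros(s.shape, dtype=np.uint8), s.affine.copy())
    labels, n = ndimage.label(binary, structure=_STRUCT26)
    counts = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(counts == counts.max()) + 1
    if len(best) > 1:
        flat = labels.ravel()
        first = [np.argmax(flat == lab) for lab in best]
        keep = best[int(np.argmin(first))]
    else:
        keep = best[0]
    return BinaryMask((labels == keep).astype(np.uint8), s.affine.copy())


def combine_soft(a: SoftMask, b: SoftMask, threshold: float = 0.5
                 ) -> BinaryMask:
    """Combine two localizers by multiplying their soft masks, then
    binarize + largest component."""
    _check_same_grid(a, b)
    prod = np.asarray(a.data, dtype=float) * np.asarray(b.data, dtype=float)
    return binarize_lcc(SoftMask(prod, a.affine.copy()), threshold)


@dataclass
class EvalReport:
    """Per-case metrics plus per-method summary statistics."""

    per_case: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            self.per_case.to_csv(fh, sep="\t", index=False,
                                 float_format="%.6g")
            fh.write("# summary\n")
            for k, v in self.summary.items():
                fh.write(f"# {k}\t{v:.6g}\n")


def _summarize(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    n = len(values)
    sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {
        "median": float(np.median(values)),
        "mean": float(np.mean(values)),
        "sem": sem,
    }


def evaluate_predictions(preds: List[SoftMask], truths: List[BinaryMask],
                         subject_ids: Optional[List[str]] = None,
                         side: str = "", threshold: float = 0.5,
                         flags: Optional[List[bool]] = None) -> EvalReport:
    """Binarize soft predictions and score them against truth masks."""
    rows = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        sid = subject_ids[i] if subject_ids else f"case{i:03d}"
        flag = bool(flags[i]) if flags else False
        if p is None:
            rows.append(dict(subject_id=sid, side=side, dice=0.0,
                             sensitivity=0.0, volume_mm3=0.0,
                             failure_flag=True))
            continue
        pb = binarize_lcc(p, threshold) if not isinstance(p, BinaryMask) \
            else p
        empty = pb.data.sum() == 0
        rows.append(dict(
            subject_id=sid, side=side,
            dice=dice(pb, t) if not empty else 0.0,
            sensitivity=sensitivity(pb, t),
            volume_mm3=float(pb.data.sum() * np.prod(pb.voxel_size)),
            failure_flag=flag or empty,
        ))
    df = pd.DataFrame(rows)
    summary = {}
    for metric in ("dice", "sensitivity", "volume_mm3"):
        for k, v in _summarize(df[metric].to_numpy()).items():
            summary[f"{metric}_{k}"] = v
    return EvalReport(df, summary)


def loocv(cases, estimator, side: str = "left", threshold: float = 0.5,
          target: str = "mask") -> EvalReport:
    """Leave-one-out cross-validation of a localizer estimator.

    For each held-out case the estimator is cloned, fitted on the remaining
    cases, and its binarized prediction scored against the held-out case's
    enlarged presumptive mask (``target='mask'``) or truth label
    (``target='truth'``).  A method failure on a fold is recorded with
    Dice 0 and a failure flag; the run continues.
    """
    cases = list(cases)
    if len(cases) < 2:
        raise ValueError("LOOCV requires at least 2 cases")
    rows = []
    for i, held in enumerate(cases):
        train = cases[:i] + cases[i + 1:]
        ref = held.mask(side) if target == "mask" else held.truth(side)
        try:
            est = clone(estimator)
            if "side" in est.get_params():
                est.set_params(side=side)
            est.fit(train)
            soft = est.predict(held.image)
            pred = binarize_lcc(soft, threshold)
            failed = pred.data.sum() == 0
            flag = bool(getattr(est, "failure_flag_", False)) or failed
        except Exception as exc:  # fold failure, not a run failure
            warnings.warn(f"fold {i} failed: {exc}")
            pred, failed, flag = None, True, True
        if pred is None or failed:
            rows.append(dict(subject_id=held.subject_id, side=side,
                             dice=0.0, sensitivity=0.0, volume_mm3=0.0,
                             failure_flag=True))
        else:
            rows.append(dict(
                subject_id=held.subject_id, side=side,
                dice=dice(pred, ref),
                sensitivity=sensitivity(pred, ref),
                volume_mm3=float(pred.data.sum() * np.prod(pred.voxel_size)),
                failure_flag=flag,
            ))
    df = pd.DataFrame(rows)
    summary = {}
    for metric in ("dice", "sensitivity", "volume_mm3"):
        for k, v in _summarize(df[metric].to_numpy()).items():
            summary[f"{metric}_{k}"] = v
    return EvalReport(df, summary)


def cohort_stats(volumes_left, volumes_right, dices_left=None,
                 dices_right=None) -> dict:
    """Left/right summary statistics: paired t-test on volumes, Pearson
    correlation between left and right Dice scores, means with SEM."""
    vl = np.asarray(volumes_left, dtype=float)
    vr = np.asarray(volumes_right, dtype=float)
    if vl.shape != vr.shape:
        raise ValueError("left/right volume arrays must have equal length")
    if len(vl) < 3:
        raise ValueError("need at least 3 paired observations")
    out = {
        "volume_left_mean": float(vl.mean()),
        "volume_left_sem": float(vl.std(ddof=1) / np.sqrt(len(vl))),
        "volume_right_mean": float(vr.mean()),
        "volume_right_sem": float(vr.std(ddof=1) / np.sqrt(len(vr))),
    }
    diff = vl - vr
    if np.all(diff == diff[0]) and diff[0] == 0:
        out["volume_t"], out["volume_p"] = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(vl, vr)
        out["volume_t"], out["volume_p"] = float(t), float(p)
    if dices_left is not None and dices_right is not None:
        dl = np.asarray(dices_left, dtype=float)
        dr = np.asarray(dices_right, dtype=float)
        if dl.shape != dr.shape:
            raise ValueError("left/right dice arrays must have equal length")
        if np.std(dl) == 0 or np.std(dr) == 0:
            out["dice_r"], out["dice_r_p"] = float("nan"), float("nan")
            out["dice_r_flag"] = True
        else:
            r, p = stats.pearsonr(dl, dr)
            out["dice_r"], out["dice_r_p"] = float(r), float(p)
            out["dice_r_flag"] = False
    return out
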