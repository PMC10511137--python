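"""Sorting-performance metrics for discriminant seed sorting.

A discriminant model assigns each seed a continuous score; a sorter
recovers every seed whose score is at or above a lower score threshold
(LST).  Given ground-truth eligibility labels (+1 eligible, -1
ineligible) this module evaluates the whole family of operating points:

* the **sorting curve** -- precision ``P``, recall ``R``, accuracy ``A``
  and seed recovery as functions of the LST;
* the **standard condition** -- the operating point where the fraction
  of seeds recovered equals the batch's initial eligibility rate ``iP``
  (there precision and recall coincide, ``sP = sR``); its threshold is
  the standard LST (``sLST``);
* **relative precision** ``rP = (P - iP) / (1 - iP)`` for ``P > iP``
  (else 0), which rescales precision so 0 means "no better than random"
  and 1 means a pure recovered fraction, making model comparisons
  across batches with different ``iP`` meaningful;
* areas under the PR and rPR curves (trapezoidal, over recall 0..1) and
  the maximum achievable accuracy ``Amax``;
* two-model extensions: the successive-sorting P/rP **surfaces** over a
  grid of threshold pairs, and score **standardization/unification**
  (``z = (y - sLST)/s``; ``u = min_i z_i``) for multi-trait sorting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError

__all__ = [
    "ScoredBatch",
    "SortingCurve",
    "StandardSummary",
    "StandardizedScorer",
    "RPRSurface",
    "sorting_curve",
    "standard_condition",
    "relative_precision",
    "pr_rpr_curves",
    "auc",
    "accuracy_max",
    "standard_summary",
    "successive_surface",
    "fit_standardizer",
    "standardize_scores",
    "unify_scores",
    "summary_frame",
    "curve_frame",
]


@dataclass
class ScoredBatch:
    """Discriminant scores for a batch of seeds, optionally labeled."""

    scores: np.ndarray
    labels: np.ndarray | None = None
    seed_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if self.scores.size == 0:
            raise DegenerateDataError("empty scored batch")
        if not np.all(np.isfinite(self.scores)):
            raise InputError("scores must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).ravel().astype(int)
            if self.labels.shape != self.scores.shape:
                raise InputError("labels do not align with scores")
            if not np.all(np.isin(self.labels, (-1, 1))):
                raise InputError("labels must be +1 or -1")

    @property
    def n(self) -> int:
        return self.scores.size

    @property
    def iP(self) -> float:
        """Initial precision: eligible fraction before sorting."""
        self._require_labels()
        return float(np.mean(self.labels == 1))

    def _require_labels(self) -> None:
        if self.labels is None:
            raise InputError("operation requires eligibility labels")


@dataclass
class SortingCurve:
    """Metrics at every distinct score threshold, descending-score order.

    ``thresholds[i]`` recovers all seeds with ``score >= thresholds[i]``;
    arrays share that indexing, so recovery/recall grow along the curve.
    """

    thresholds: np.ndarray
    recovery: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    accuracy: np.ndarray
    rel_precision: np.ndarray
    iP: float
    n: int


@dataclass
class StandardSummary:
    """The standard-condition and overall metrics of one scored batch."""

    iP: float
    n: int
    slst: float
    sp: float
    sa: float
    amax: float
    auc_pr: float
    auc_rpr: float
    n_recovered: int

    def as_dict(self) -> dict:
        return {
            "iP": self.iP,
            "n": self.n,
            "sLST": self.slst,
            "sP": self.sp,
            "sA": self.sa,
            "Amax": self.amax,
            "AUC_PR": self.auc_pr,
            "AUC_rPR": self.auc_rpr,
        }

    def __str__(self) -> str:  # table-style: percents to 1 dp, AUCs to 4 dp
        return (
            f"iP={self.iP:.1%} sLST={self.slst:+.4f} sP={self.sp:.1%} "
            f"sA={self.sa:.1%} Amax={self.amax:.1%} "
            f"AUC-PR={self.auc_pr:.4f} AUC-rPR={self.auc_rpr:.4f}"
        )


def relative_precision(precision, iP: float):
    """Eligibility-rate gain rescaled to [0, 1]; 0 below ``iP``."""
    if not 0.0 < iP < 1.0:
        raise DegenerateDataError(f"iP must lie in (0, 1), got {iP}")
    precision = np.asarray(precision, dtype=float)
    out = np.where(precision > iP, (precision - iP) / (1.0 - iP), 0.0)
    return float(out) if out.ndim == 0 else out


def sorting_curve(batch: ScoredBatch) -> SortingCurve:
    """Evaluate P/R/A/rP at every distinct score threshold.

    Thresholds are the distinct observed scores in descending order;
    tied scores collapse to a single operating point (a physical sorter
    cannot separate them).
    """
    batch._require_labels()
    iP = batch.iP
    if iP in (0.0, 1.0):
        raise DegenerateDataError("need at least one seed per class")
    order = np.argsort(-batch.scores, kind="stable")
    s = batch.scores[order]
    ok = batch.labels[order] == 1
    n = s.size
    tp = np.cumsum(ok)
    k = np.arange(1, n + 1)
    last = np.r_[s[1:] != s[:-1], True]  # last index of each tie group
    tp, k, thr = tp[last], k[last], s[last]
    n_ok = int(ok.sum())
    precision = tp / k
    recall = tp / n_ok
    tn = (n - k) - (n_ok - tp)
    return SortingCurve(
        thresholds=thr,
        recovery=k / n,
        precision=precision,
        recall=recall,
        accuracy=(tp + tn) / n,
        rel_precision=relative_precision(precision, iP),
        iP=iP,
        n=n,
    )


def standard_condition(batch: ScoredBatch) -> tuple[float, float, float]:
    """Locate the standard condition and return ``(sLST, sP, sA)``.

    The sorter recovers the top ``k = round(iP * N)`` seeds by score;
    ``sLST`` is the k-th highest score (ties at ``sLST`` are all
    recovered, so the realized recovery can exceed ``k``).  At this
    operating point precision equals recall whenever ``iP * N`` is an
    integer.
    """
    batch._require_labels()
    n = batch.n
    k = int(round(batch.iP * n))
    if k <= 0 or k >= n:
        raise DegenerateDataError(
            f"standard condition degenerate: k={k} of n={n} seeds recovered"
        )
    s_desc = np.sort(batch.scores)[::-1]
    slst = float(s_desc[k - 1])
    recovered = batch.scores >= slst
    n_rec = int(recovered.sum())
    tp = int(np.sum(batch.labels[recovered] == 1))
    tn = int(np.sum(batch.labels[~recovered] == -1))
    return slst, tp / n_rec, (tp + tn) / n


def pr_rpr_curves(curve: SortingCurve):
    """Return ``(R, P)`` and ``(R, rP)`` point lists, recall ascending."""
    return (
        (curve.recall.copy(), curve.precision.copy()),
        (curve.recall.copy(), curve.rel_precision.copy()),
    )


def auc(x, y) -> float:
    """Trapezoidal area under ``y(x)`` over [0, 1].

    Points are sorted by ``x``; the curve is extended to ``x = 0`` and
    ``x = 1`` by carrying the nearest achieved value (constant
    extrapolation), the least-assumption closure for empirical PR/rPR
    curves.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size == 0:
        raise InputError("auc needs equal-length, non-empty x and y")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x[0] > 0.0:
        x, y = np.r_[0.0, x], np.r_[y[0], y]
    if x[-1] < 1.0:
        x, y = np.r_[x, 1.0], np.r_[y, y[-1]]
    return float(np.trapezoid(y, x))


def accuracy_max(curve: SortingCurve) -> float:
    """Maximum accuracy over all thresholds (incl. recover-none)."""
    none = max(1.0 - curve.iP, 0.0)  # reject everything
    return float(max(curve.accuracy.max(), none))


def standard_summary(batch: ScoredBatch) -> StandardSummary:
    """All Table-style metrics of one labeled scored batch."""
    curve = sorting_curve(batch)
    slst, sp, sa = standard_condition(batch)
    (r, p), (_, rp) = pr_rpr_curves(curve)
    return StandardSummary(
        iP=curve.iP,
        n=curve.n,
        slst=slst,
        sp=sp,
        sa=sa,
        amax=accuracy_max(curve),
        auc_pr=auc(r, p),
        auc_rpr=auc(r, rp),
        n_recovered=int(np.sum(batch.scores >= slst)),
    )


# ---------------------------------------------------------------------------
# Successive (two-threshold) sorting surfaces


@dataclass
class RPRSurface:
    """P/R/rP of two-threshold sorting over an (LST1, LST2) grid.

    ``precision[i, j]`` etc. refer to the seeds scoring at or above
    ``lst1[i]`` under model 1 **and** at or above ``lst2[j]`` under
    model 2, judged against the joint (fully-eligible) labels.
    ``recall1``/``recall2`` are the per-model marginal recalls used as
    the integration axes for the PR/rPR volumes.
    """

    lst1: np.ndarray
    lst2: np.ndarray
    recall1: np.ndarray
    recall2: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    rel_precision: np.ndarray
    volume_pr: float
    volume_rpr: float
    iP: float


def _marginal_recall(scores: np.ndarray, labels: np.ndarray, thresholds: np.ndarray):
    ok = labels == 1
    n_ok = ok.sum()
    return np.array([(scores[ok] >= t).sum() / n_ok for t in thresholds])


def successive_surface(
    batch1: ScoredBatch,
    batch2: ScoredBatch,
    joint_labels: np.ndarray,
    grid: int = 201,
) -> RPRSurface:
    """Evaluate successive two-model sorting on a threshold grid.

    ``batch1``/``batch2`` carry per-trait scores (and per-trait labels
    for the marginal recall axes); ``joint_labels`` mark seeds meeting
    *all* requirements.  Grid thresholds are evenly spaced over each
    model's achieved score range.  Cells whose intersection recovers no
    seed inherit precision from the nearest stricter non-empty cell.
    """
    if batch1.n != batch2.n:
        raise InputError("batches are not aligned")
    if batch1.seed_ids is not None and batch2.seed_ids is not None:
        if not np.array_equal(batch1.seed_ids, batch2.seed_ids):
            raise InputError("batches carry different seeds")
    joint = np.asarray(joint_labels).ravel().astype(int)
    if joint.size != batch1.n or not np.all(np.isin(joint, (-1, 1))):
        raise InputError("joint labels must align and be +1/-1")
    iP = float(np.mean(joint == 1))
    if not 0.0 < iP < 1.0:
        raise DegenerateDataError("joint labels contain a single class")

    lst1 = np.linspace(batch1.scores.min(), batch1.scores.max(), grid)[::-1]
    lst2 = np.linspace(batch2.scores.min(), batch2.scores.max(), grid)[::-1]
    above1 = batch1.scores[None, :] >= lst1[:, None]  # grid x seeds
    above2 = batch2.scores[None, :] >= lst2[:, None]
    ok = joint == 1
    n_ok = ok.sum()

    # recovered counts and true positives via boolean matmuls
    a1 = above1.astype(np.float64)
    a2 = above2.astype(np.float64)
    rec = a1 @ a2.T
    tp = a1[:, ok] @ a2[:, ok].T

    precision = np.where(rec > 0, tp / np.maximum(rec, 1.0), np.nan)
    recall = tp / n_ok

    # empty-intersection cells (strict corner) inherit from the nearest
    # less-strict non-empty cell, mirroring the R->0 closure of `auc`
    if np.isnan(precision).any():
        for i in range(grid - 1, -1, -1):
            for j in range(grid - 1, -1, -1):
                if np.isnan(precision[i, j]):
                    if i + 1 < grid and not np.isnan(precision[i + 1, j]):
                        precision[i, j] = precision[i + 1, j]
                    elif j + 1 < grid and not np.isnan(precision[i, j + 1]):
                        precision[i, j] = precision[i, j + 1]
                    else:
                        precision[i, j] = iP
    rel = relative_precision(precision, iP)

    r1 = _marginal_recall(
        batch1.scores,
        batch1.labels if batch1.labels is not None else joint,
        lst1,
    )
    r2 = _marginal_recall(
        batch2.scores,
        batch2.labels if batch2.labels is not None else joint,
        lst2,
    )
    vol_pr = _square_volume(r1, r2, precision)
    vol_rpr = _square_volume(r1, r2, rel)
    return RPRSurface(
        lst1=lst1,
        lst2=lst2,
        recall1=r1,
        recall2=r2,
        precision=precision,
        recall=recall,
        rel_precision=rel,
        volume_pr=vol_pr,
        volume_rpr=vol_rpr,
        iP=iP,
    )


def _square_volume(r1: np.ndarray, r2: np.ndarray, z: np.ndarray) -> float:
    """2-D trapezoidal integral of ``z`` over the (r1, r2) unit square.

    The marginal recall axes may not span [0, 1] exactly; the surface is
    extended by constant extrapolation the same way :func:`auc` closes a
    curve.
    """
    o1 = np.argsort(r1, kind="stable")
    o2 = np.argsort(r2, kind="stable")
    r1s, r2s, zs = r1[o1], r2[o2], z[np.ix_(o1, o2)]
    # de-duplicate repeated axis values (keep last = strictest equivalent)
    keep1 = np.r_[r1s[1:] != r1s[:-1], True]
    keep2 = np.r_[r2s[1:] != r2s[:-1], True]
    r1s, r2s, zs = r1s[keep1], r2s[keep2], zs[np.ix_(keep1, keep2)]
    if r1s[0] > 0:
        r1s = np.r_[0.0, r1s]
        zs = np.vstack([zs[:1, :], zs])
    if r1s[-1] < 1:
        r1s = np.r_[r1s, 1.0]
        zs = np.vstack([zs, zs[-1:, :]])
    if r2s[0] > 0:
        r2s = np.r_[0.0, r2s]
        zs = np.hstack([zs[:, :1], zs])
    if r2s[-1] < 1:
        r2s = np.r_[r2s, 1.0]
        zs = np.hstack([zs, zs[:, -1:]])
    inner = np.trapezoid(zs, r2s, axis=1)
    return float(np.trapezoid(inner, r1s))


# ---------------------------------------------------------------------------
# Score standardization and unification (multi-trait sorting)


@dataclass
class StandardizedScorer:
    """Affine map ``z = (y - slst_hat) / s_hat`` fitted on calibration scores.

    ``z = 0`` marks the estimated standard condition; a seed with
    ``z >= 0`` would be recovered under standard-condition sorting.
    """

    s_hat: float
    slst_hat: float

    def transform(self, scores) -> np.ndarray:
        return (np.asarray(scores, dtype=float) - self.slst_hat) / self.s_hat


def fit_standardizer(calib: ScoredBatch, ddof: int = 1) -> StandardizedScorer:
    """Estimate sd and sLST of the score scale from a labeled subset."""
    if np.unique(calib.scores).size < 2:
        raise DegenerateDataError("calibration scores are constant")
    s = float(np.std(calib.scores, ddof=ddof))
    if s == 0:
        raise DegenerateDataError("zero score standard deviation")
    slst, _, _ = standard_condition(calib)
    return StandardizedScorer(s_hat=s, slst_hat=slst)


def standardize_scores(scores, calib: ScoredBatch) -> np.ndarray:
    """Convert raw scores to standardized scores via a calibration batch."""
    return fit_standardizer(calib).transform(scores)


def unify_scores(z_list) -> np.ndarray:
    """Unified multi-trait score: elementwise minimum of standardized scores.

    Taking the lowest per-trait rating is the conservative choice --
    rejection is preferred over acceptance when any requirement is in
    doubt.  The result can be treated like any other discriminant score.
    """
    z_list = [np.asarray(z, dtype=float).ravel() for z in z_list]
    if not z_list:
        raise InputError("need at least one score vector")
    length = z_list[0].size
    if any(z.size != length for z in z_list):
        raise InputError("score vectors differ in length")
    return np.min(np.vstack(z_list), axis=0)


# ---------------------------------------------------------------------------
# Reporting


def summary_frame(named_summaries) -> pd.DataFrame:
    """Stack ``(name, StandardSummary)`` pairs into a report table."""
    rows = []
    for name, s in named_summaries:
        d = s.as_dict()
        d["model"] = name
        rows.append(d)
    cols = ["model", "iP", "sLST", "sP", "sA", "Amax", "AUC_PR", "AUC_rPR", "n"]
    return pd.DataFrame(rows)[cols]


def curve_frame(curve: SortingCurve) -> pd.DataFrame:
    """Sorting curve as a table (LST, recovery, P, R, A, rP)."""
    return pd.DataFrame(
        {
            "LST": curve.thresholds,
            "recovery": curve.recovery,
            "P": curve.precision,
            "R": curve.recall,
            "A": curve.accuracy,
            "rP": curve.rel_precision,
        }
    )
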