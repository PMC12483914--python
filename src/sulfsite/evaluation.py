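"""Evaluation harness: confusion metrics, threshold-free curves, repeated
stratified cross-validation and position-specific enrichment statistics.

Metrics follow the standard definitions — Sn = TP/(TP+FN), Sp = TN/(TN+FP),
ACC = (TP+TN)/n (all reported as percentages) and the Matthews correlation
coefficient — with undefined ratios reported as ``None`` rather than silent
zeros.  auROC uses the rank-statistic (Mann–Whitney) formulation with
midrank tie handling; auPRC is the step integration Σ (R_i − R_{i−1})·P_i.

``two_sample_logo`` compares per-position residue frequencies between a
positive and a negative window set with a two-proportion z-test, the
numerical core of a two-sample sequence logo (rendering is out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .seqdata import AMINO_ACIDS, PeptideWindow

__all__ = [
    "ConfusionCounts", "MetricsReport", "CVConfig", "LogoCell", "LogoResult",
    "confusion", "metrics", "auroc", "auprc", "evaluate_scores",
    "repeated_cv", "two_sample_logo",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    sn: float | None = None    # percent
    sp: float | None = None    # percent
    acc: float | None = None   # percent
    mcc: float | None = None   # [-1, 1]
    auroc: float | None = None
    auprc: float | None = None
    n: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("sn", "sp", "acc", "mcc", "auroc", "auprc", "n")}


@dataclass
class CVConfig:
    folds: int = 10
    repeats: int = 10
    validation_fraction: float = 0.10
    stratified: bool = True
    resample_inside_folds: bool = True
    base_seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")


def confusion(y_true, y_score, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold scores at ``threshold``; ties classify positive."""
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=np.float64)
    if y_true.shape != y_score.shape:
        raise ValueError("y_true and y_score must have equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    pred = y_score >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y_true == 1))),
        tn=int(np.sum(~pred & (y_true == 0))),
        fp=int(np.sum(pred & (y_true == 0))),
        fn=int(np.sum(~pred & (y_true == 1))),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sn/Sp/ACC (percent) and MCC from a confusion table; None when undefined."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    rep = MetricsReport(n=counts.n)
    if tp + fn > 0:
        rep.sn = 100.0 * tp / (tp + fn)
    if tn + fp > 0:
        rep.sp = 100.0 * tn / (tn + fp)
    if counts.n > 0:
        rep.acc = 100.0 * (tp + tn) / counts.n
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        rep.mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return rep


def auroc(y_true, y_score) -> float:
    """Area under the ROC curve via the Mann–Whitney U statistic (midranks)."""
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=np.float64)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for auROC")
    ranks = rankdata(y_score, method="average")
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auprc(y_true, y_score) -> float:
    """Area under the precision-recall curve by step integration.

    AP = Σ_i (R_i − R_{i−1}) · P_i over thresholds at each distinct score,
    descending.
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=np.float64)
    n_pos = int((y_true == 1).sum())
    if n_pos == 0 or (y_true == 0).sum() == 0:
        raise ValueError("both classes required for auPRC")
    order = np.argsort(-y_score, kind="stable")
    y_sorted = y_true[order]
    s_sorted = y_score[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep only the last index of each tied-score block
    distinct = np.flatnonzero(np.r_[np.diff(s_sorted) != 0, True])
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def evaluate_scores(y_true, y_score, threshold: float = 0.5) -> MetricsReport:
    """Full report from labels and scores (thresholded + threshold-free)."""
    rep = metrics(confusion(y_true, y_score, threshold))
    y_true = np.asarray(y_true).astype(int)
    if 0 < y_true.sum() < len(y_true):
        rep.auroc = auroc(y_true, y_score)
        rep.auprc = auprc(y_true, y_score)
    return rep


# ---------------------------------------------------------------------------
# repeated stratified cross-validation
# ---------------------------------------------------------------------------

def repeated_cv(samples, labels, model_factory, config: CVConfig | None = None,
                resample_fn=None):
    """Repeated stratified k-fold evaluation.

    ``model_factory(seed) -> model`` must expose ``fit(samples, labels)`` and
    ``predict_scores(samples) -> array``; per fold the model sees only the
    training folds (any embedding/resampling it performs internally therefore
    stays leakage-free).  ``resample_fn(X, y, seed) -> (X', y')`` is applied
    to the training folds when given and ``config.resample_inside_folds`` is
    on; it requires array-like samples.

    Returns ``(fold_reports, summary)`` where summary maps each metric to
    (mean, std) over folds × repeats.
    """
    config = config or CVConfig()
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < config.folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]} has {counts.min()} samples, "
            f"fewer than {config.folds} folds")
    indexable = np.asarray(samples) if not isinstance(samples, np.ndarray) else samples

    reports: list[MetricsReport] = []
    for r in range(config.repeats):
        seed = config.base_seed + r
        splitter = StratifiedKFold(n_splits=config.folds, shuffle=True,
                                   random_state=seed)
        for fold, (tr, te) in enumerate(splitter.split(np.zeros(n), labels)):
            s_tr, y_tr = indexable[tr], labels[tr]
            if resample_fn is not None and config.resample_inside_folds:
                s_tr, y_tr = resample_fn(s_tr, y_tr, seed * 1000 + fold)
            model = model_factory(seed * 1000 + fold)
            model.fit(s_tr, y_tr)
            scores = np.asarray(model.predict_scores(indexable[te]))
            reports.append(evaluate_scores(labels[te], scores))

    summary = {}
    for key in ("sn", "sp", "acc", "mcc", "auroc", "auprc"):
        vals = [getattr(rep, key) for rep in reports if getattr(rep, key) is not None]
        if vals:
            summary[key] = (float(np.mean(vals)), float(np.std(vals)))
    return reports, summary


def validation_split(y, fraction: float = 0.10, seed: int = 0):
    """Stratified train/validation index split (for early stopping)."""
    idx = np.arange(len(y))
    tr, va = train_test_split(idx, test_size=fraction, stratify=y,
                              random_state=seed)
    return np.sort(tr), np.sort(va)


# ---------------------------------------------------------------------------
# two-sample logo statistic
# ---------------------------------------------------------------------------

@dataclass
class LogoCell:
    position: int          # 1-based window position (center = 11)
    residue: str
    freq_pos: float
    freq_neg: float
    diff: float
    z: float
    p_value: float
    call: str              # enriched | depleted | neutral


@dataclass
class LogoResult:
    cells: list[LogoCell] = field(default_factory=list)
    alpha: float = 0.05

    def calls(self, call: str) -> list[LogoCell]:
        return [c for c in self.cells if c.call == call]

    def cell(self, position: int, residue: str) -> LogoCell:
        for c in self.cells:
            if c.position == position and c.residue == residue:
                return c
        raise KeyError((position, residue))


def _bh_correct(cells: list[LogoCell]) -> None:
    m = len(cells)
    order = sorted(range(m), key=lambda i: cells[i].p_value)
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, cells[i].p_value * m / rank)
        adj[i] = prev
    for c, p in zip(cells, adj):
        c.p_value = p


def two_sample_logo(pos_windows: list[PeptideWindow],
                    neg_windows: list[PeptideWindow],
                    alpha: float = 0.05,
                    correction: str | None = None) -> LogoResult:
    """Per-(position, residue) enrichment of positives over negatives.

    For each window position and standard residue the frequency difference
    (over non-X observations) is tested with a pooled two-proportion z-test;
    cells with p < alpha are called enriched (positive difference) or
    depleted.  ``correction='bh'`` applies Benjamini–Hochberg across the
    21 × 20 cells; the default is uncorrected.
    """
    if not pos_windows or not neg_windows:
        raise ValueError("both window sets must be non-empty")
    length = len(pos_windows[0].sequence if hasattr(pos_windows[0], "sequence")
                 else pos_windows[0])

    def seqs(ws):
        return [(w.sequence if hasattr(w, "sequence") else str(w)) for w in ws]

    pos_s, neg_s = seqs(pos_windows), seqs(neg_windows)
    cells: list[LogoCell] = []
    for p in range(length):
        col_pos = [s[p] for s in pos_s if s[p] != "X"]
        col_neg = [s[p] for s in neg_s if s[p] != "X"]
        n1, n2 = len(col_pos), len(col_neg)
        for res in AMINO_ACIDS:
            x1 = sum(c == res for c in col_pos)
            x2 = sum(c == res for c in col_neg)
            f1 = x1 / n1 if n1 else 0.0
            f2 = x2 / n2 if n2 else 0.0
            diff = f1 - f2
            if n1 and n2:
                pool = (x1 + x2) / (n1 + n2)
                se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
                z = diff / se if se > 0 else 0.0
            else:
                z = 0.0
            pval = 2.0 * float(norm.sf(abs(z)))
            cells.append(LogoCell(p + 1, res, f1, f2, diff, z, min(pval, 1.0),
                                  "neutral"))
    if correction == "bh":
        _bh_correct(cells)
    for c in cells:
        if c.p_value < alpha and c.diff > 0:
            c.call = "enriched"
        elif c.p_value < alpha and c.diff < 0:
            c.call = "depleted"
    return LogoResult(cells, alpha)
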