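"""Precision/recall/F-score/FDR evaluation against simulation ground truth.

Evaluation is set-based by default: the labels (orthologs, families or
subsystems) recovered by a workflow are compared with the set of labels truly
expressed in the simulated community. TP are recovered labels present in the
truth, FP recovered labels absent from it, FN truth labels never recovered:

    precision = TP / (TP + FP)      recall = TP / (TP + FN)
    F = 2 * precision * recall / (precision + recall)
    FDR% = 100 * FP / (TP + FP)

A feature-resolved mode (per-feature correctness) is available for
diagnostics. The module also hosts the 15-point confidence-threshold sweep
(low/medium/high categories, five thresholds each) with best-threshold
selection by F-score, and segmented cross-validation, which re-annotates
against a database with one functional subsystem removed at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

from .homology import Threshold
from .synthetic_data import ReferenceDB

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ThresholdGrid",
    "default_grid",
    "confusion",
    "harmonic_f",
    "metrics",
    "threshold_sweep",
    "segmented_cross_validation",
    "evaluate_de",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    level: str = "ortholog"
    threshold: Threshold | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricsReport:
    confusion: ConfusionCounts
    precision: float
    recall: float
    f_score: float
    fdr_percent: float
    precision_undefined: bool = False
    recall_undefined: bool = False


def confusion(
    predicted,
    truth,
    level: str = "ortholog",
    threshold: Threshold | None = None,
    mode: str = "labels",
    truth_level: str | None = None,
) -> ConfusionCounts:
    """Confusion counts in label-set mode (default) or feature-resolved mode.

    Label-set mode takes two label sets. Feature-resolved mode takes two
    feature->label mappings; a feature predicted with the wrong label counts
    as both FP and FN.
    """
    if truth_level is not None and truth_level != level:
        raise ValueError(f"level mismatch: predicted at {level}, truth at {truth_level}")
    if mode == "labels":
        pred = set(predicted)
        tru = set(truth)
        tp = len(pred & tru)
        fp = len(pred - tru)
        fn = len(tru - pred)
    elif mode == "features":
        tp = sum(1 for f, lab in predicted.items() if truth.get(f) == lab)
        fp = sum(1 for f, lab in predicted.items() if truth.get(f) != lab)
        fn = sum(1 for f in truth if predicted.get(f) != truth[f])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, level=level, threshold=threshold)


def harmonic_f(precision: float, recall: float) -> float:
    """F-score: the harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(conf: ConfusionCounts) -> MetricsReport:
    """Precision, recall, harmonic-mean F and FDR% with 0-guarded flags."""
    denom_p = conf.tp + conf.fp
    denom_r = conf.tp + conf.fn
    p_undef = denom_p == 0
    r_undef = denom_r == 0
    precision = 0.0 if p_undef else conf.tp / denom_p
    recall = 0.0 if r_undef else conf.tp / denom_r
    f = harmonic_f(precision, recall)
    fdr = 0.0 if p_undef else 100.0 * conf.fp / denom_p
    return MetricsReport(
        confusion=conf,
        precision=precision,
        recall=recall,
        f_score=f,
        fdr_percent=fdr,
        precision_undefined=p_undef,
        recall_undefined=r_undef,
    )


# --------------------------------------------------------------------------- #
# threshold grid + sweep
# --------------------------------------------------------------------------- #

CATEGORIES = ("T_L", "T_M", "T_H")


@dataclass
class ThresholdGrid:
    entries: list[Threshold] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.entries) != 15:
            raise ValueError("grid must contain exactly 15 thresholds")
        modes = {t.mode for t in self.entries}
        if len(modes) != 1:
            raise ValueError("grid thresholds must share one mode")
        for cat in CATEGORIES:
            if sum(1 for t in self.entries if t.category == cat) != 5:
                raise ValueError("each category must contain exactly 5 thresholds")
        mode = self.entries[0].mode
        if mode == "evalue":
            vals = [t.max_evalue for t in self.entries]
            ok = all(a > b for a, b in zip(vals, vals[1:]))
        else:
            vals = [t.min_bitscore for t in self.entries]
            ok = all(a < b for a, b in zip(vals, vals[1:]))
        if not ok:
            raise ValueError("grid must be strictly ordered from inclusive to stringent")

    @property
    def mode(self) -> str:
        return self.entries[0].mode

    @property
    def loosest(self) -> Threshold:
        return self.entries[0]

    def __iter__(self):
        return iter(self.entries)


_BITSCORE_GRID = (40, 50, 60, 70, 80, 85, 90, 95, 100, 105, 110, 120, 130, 140, 150)


def default_grid(mode: str, min_aln_length: int = 15) -> ThresholdGrid:
    """The 15-threshold gradient: five low (T_L), five medium (T_M), five
    high (T_H) confidence thresholds per search mode."""
    entries: list[Threshold] = []
    if mode == "evalue":
        for i, exp in enumerate(range(3, 18)):
            cat = CATEGORIES[i // 5]
            entries.append(Threshold.evalue(10.0 ** -exp, min_aln_length, category=cat))
    elif mode == "bitscore":
        for i, bts in enumerate(_BITSCORE_GRID):
            entries.append(Threshold.bitscore(float(bts), category=CATEGORIES[i // 5]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ThresholdGrid(entries)


def threshold_sweep(
    annotate_at: Callable[[Threshold], Iterable[str]],
    grid: ThresholdGrid,
    truth_labels: Iterable[str],
    level: str = "ortholog",
) -> tuple[list[tuple[Threshold, MetricsReport]], Threshold, MetricsReport]:
    """One MetricsReport per grid entry plus the F-optimal threshold.

    ``annotate_at`` maps a threshold to the recovered label set (workflows
    implement it by re-filtering their stored hit set, exploiting hit-set
    nestedness). Ties on F-score resolve to the more stringent threshold.
    """
    truth = set(truth_labels)
    reports: list[tuple[Threshold, MetricsReport]] = []
    best_i = -1
    best_f = -1.0
    for i, thr in enumerate(grid):
        predicted = set(annotate_at(thr))
        rep = metrics(confusion(predicted, truth, level=level, threshold=thr))
        reports.append((thr, rep))
        if rep.f_score >= best_f:  # >= : later (more stringent) wins ties
            best_f = rep.f_score
            best_i = i
    return reports, reports[best_i][0], reports[best_i][1]


# --------------------------------------------------------------------------- #
# segmented cross-validation
# --------------------------------------------------------------------------- #


def labels_in_subsystem(db: ReferenceDB, subsystem: str, level: str) -> set[str]:
    if level == "subsystem":
        return {subsystem}
    if level == "family":
        return {fam for (fam, ss) in db.hierarchy.values() if ss == subsystem}
    if level == "ortholog":
        return {og for og, (_, ss) in db.hierarchy.items() if ss == subsystem}
    raise ValueError(f"unknown level {level!r}")


def segmented_cross_validation(
    db: ReferenceDB,
    subsystems_to_remove: list[str],
    annotators: dict[str, Callable[[ReferenceDB], Iterable[str]]],
    truth_labels: Iterable[str],
    level: str = "ortholog",
) -> dict[str, dict[str, MetricsReport]]:
    """Re-annotate against a cropped database, one subsystem removal at a
    time.

    ``annotators`` maps workflow name -> callable(cropped_db) -> recovered
    label set. Truth positives are restricted to labels outside the removed
    subsystem; any label recovered for a gene whose true subsystem was
    removed necessarily falls outside the restricted truth and counts FP.
    """
    all_subsystems = set(db.subsystems)
    unknown = set(subsystems_to_remove) - all_subsystems
    if unknown:
        raise ValueError(f"unknown subsystems: {sorted(unknown)}")
    if set(subsystems_to_remove) == all_subsystems:
        raise ValueError("cannot remove every subsystem (empty reference)")
    truth = set(truth_labels)
    out: dict[str, dict[str, MetricsReport]] = {}
    for ss in subsystems_to_remove:
        cropped = db.cropped({ss})
        truth_r = truth - labels_in_subsystem(db, ss, level)
        per_wf: dict[str, MetricsReport] = {}
        for name, annotate in annotators.items():
            predicted = set(annotate(cropped))
            per_wf[name] = metrics(confusion(predicted, truth_r, level=level))
        out[ss] = per_wf
    return out


# --------------------------------------------------------------------------- #
# differential-expression evaluation
# --------------------------------------------------------------------------- #


def evaluate_de(
    predicted_up: Iterable[str],
    predicted_down: Iterable[str],
    truth_up: Iterable[str],
    truth_down: Iterable[str],
    level: str = "ortholog",
) -> dict[str, MetricsReport]:
    """Per-direction label-set evaluation of differential-expression calls."""
    up = set(predicted_up)
    down = set(predicted_down)
    if up & down:
        raise ValueError("predicted up and down sets overlap")
    return {
        "up": metrics(confusion(up, set(truth_up), level=level)),
        "down": metrics(confusion(down, set(truth_down), level=level)),
    }
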