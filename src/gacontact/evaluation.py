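"""Confusion counts, accuracy/coverage, and top-L/k selection reports."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from gacontact.contacts import ContactMap

#: Fractions of L evaluated by default: 2L, L, L/2, L/5, L/10, L/20.
DEFAULT_FRACTIONS = (2.0, 1.0, 0.5, 0.2, 0.1, 0.05)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class TopKEntry:
    fraction: float
    K: int
    tp_in_top_k: int
    accuracy: float
    truncated: bool = False  # fewer scored pairs than K


@dataclass
class TopKReport:
    chain_id: str
    length: int
    entries: dict[float, TopKEntry]


def confusion_counts(predicted: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Standard 2x2 tally of 0/1 label sequences."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth lengths differ")
    return ConfusionCounts(
        TP=int(((predicted == 1) & (truth == 1)).sum()),
        FP=int(((predicted == 1) & (truth == 0)).sum()),
        FN=int(((predicted == 0) & (truth == 1)).sum()),
        TN=int(((predicted == 0) & (truth == 0)).sum()),
    )


def accuracy_coverage(cc: ConfusionCounts) -> tuple[float | None, float | None]:
    """(Acc, Cov) = (TP/(TP+FP), TP/(TP+FN)); a 0/0 ratio is returned
    as None (undefined), never silently as 0."""
    acc = cc.TP / (cc.TP + cc.FP) if cc.TP + cc.FP > 0 else None
    cov = cc.TP / (cc.TP + cc.FN) if cc.TP + cc.FN > 0 else None
    return acc, cov


def top_k_size(L: int, fraction: float) -> int:
    """K = floor(L * fraction), minimum 1."""
    return max(1, int(np.floor(L * fraction)))


def select_top_k(
    scored_pairs: Sequence[tuple[int, int, float]],
    L: int,
    fraction: float,
) -> list[tuple[int, int, float]]:
    """The K most contact-like (lowest-score) pairs, ties broken by
    (i, j) order; if fewer than K pairs exist, all are returned."""
    K = top_k_size(L, fraction)
    ranked = sorted(scored_pairs, key=lambda r: (r[2], r[0], r[1]))
    return ranked[:K]


def topk_accuracy_levels(
    scored_pairs: Sequence[tuple[int, int, float]],
    cm: ContactMap,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> TopKReport:
    """Per-level accuracy = (true contacts among the top K)/K."""
    entries = {}
    for frac in fractions:
        K = top_k_size(cm.length, frac)
        selected = select_top_k(scored_pairs, cm.length, frac)
        tp = sum(1 for i, j, _ in selected if (i, j) in cm.contact_pairs)
        denom = len(selected) if selected else K
        entries[frac] = TopKEntry(
            fraction=frac,
            K=K,
            tp_in_top_k=tp,
            accuracy=tp / denom if denom else 0.0,
            truncated=len(selected) < K,
        )
    return TopKReport(chain_id=cm.chain_id, length=cm.length, entries=entries)


@dataclass
class GroupSummary:
    group: str
    n_chains: int
    mean_accuracy: dict[float, float | None]  # None when all entries undefined
    skipped: dict[float, int]


def grouped_summary(
    reports: Sequence[TopKReport],
    groups: Mapping[str, str],
) -> list[GroupSummary]:
    """Mean per-level accuracy within each user-supplied chain group.

    Undefined per-chain entries are skipped from the mean and counted
    in ``skipped``.
    """
    by_group: dict[str, list[TopKReport]] = {}
    for rep in reports:
        if rep.chain_id not in groups:
            raise KeyError(f"missing group label for chain {rep.chain_id}")
        by_group.setdefault(groups[rep.chain_id], []).append(rep)
    out = []
    for group in sorted(by_group):
        reps = by_group[group]
        fractions = sorted({f for r in reps for f in r.entries}, reverse=True)
        means: dict[float, float | None] = {}
        skipped: dict[float, int] = {}
        for frac in fractions:
            vals = [
                r.entries[frac].accuracy
                for r in reps
                if frac in r.entries and r.entries[frac].accuracy is not None
            ]
            skipped[frac] = len(reps) - len(vals)
            means[frac] = float(np.mean(vals)) if vals else None
        out.append(
            GroupSummary(group=group, n_chains=len(reps), mean_accuracy=means, skipped=skipped)
        )
    return out


def report_to_tsv_lines(report: TopKReport) -> list[str]:
    """Flatten a TopKReport into TSV lines (header + one row per level)."""
    lines = ["chain\tL\tfraction\tK\ttp\taccuracy"]
    for frac in sorted(report.entries, reverse=True):
        e = report.entries[frac]
        lines.append(
            f"{report.chain_id}\t{report.length}\t{frac:g}\t{e.K}\t{e.tp_in_top_k}\t{e.accuracy:.4f}"
        )
    return lines
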