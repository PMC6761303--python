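"""Binning performance against truth labels.

Rates are reported twice: from contig counts and from summed nucleotide
lengths. The length-weighted block answers the question the count-based
one distorts — misclassifying a 100 kb contig is a much larger error than
misclassifying a 2 kb one, yet both cost exactly one count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

TARGET = "target"
OTHER = "other"


@dataclass
class Block:
    """One confusion block (counts or nucleotide lengths)."""

    tp: float
    fp: float
    tn: float
    fn: float

    def _rate(self, num: float, den: float) -> float | None:
        return num / den if den else None

    @property
    def sensitivity(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def precision(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def accuracy(self) -> float | None:
        return self._rate(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def f1(self) -> float | None:
        p, s = self.precision, self.sensitivity
        if p is None or s is None or (p + s) == 0:
            return None
        return 2 * p * s / (p + s)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "precision": self.precision,
            "accuracy": self.accuracy, "f1": self.f1,
        }


@dataclass
class PerformanceReport:
    """Count- and length-weighted confusion statistics from one partition."""

    counts: Block
    lengths: Block

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"weighting": "contig_count", **self.counts.as_dict()},
            {"weighting": "nucleotide_length", **self.lengths.as_dict()},
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        def fmt(v):
            return "undefined" if v is None else f"{v:.4f}"

        lines = []
        for name, blk in (("contig counts", self.counts), ("nucleotide lengths", self.lengths)):
            lines.append(
                f"{name}: TP={blk.tp:g} FP={blk.fp:g} TN={blk.tn:g} FN={blk.fn:g} | "
                f"sensitivity={fmt(blk.sensitivity)} precision={fmt(blk.precision)} "
                f"accuracy={fmt(blk.accuracy)} F1={fmt(blk.f1)}"
            )
        return "\n".join(lines)


def score(
    predicted_target: set[str],
    truth: Mapping[str, str],
    lengths: Mapping[str, int],
) -> PerformanceReport:
    """Score a predicted target-contig set against truth labels.

    ``truth`` maps every evaluated contig to "target" or "other"; the
    evaluated universe is exactly its key set, so contigs the pipeline
    dropped (e.g. below the length filter and never recovered) count as
    FN/TN rather than vanishing. A predicted contig missing from truth is
    a hard error. Undefined rates (zero denominators) are None, not 0.
    """
    missing = set(predicted_target) - set(truth)
    if missing:
        raise KeyError(f"predicted contigs missing from truth: {sorted(missing)[:5]}")
    bad = {c: v for c, v in truth.items() if v not in (TARGET, OTHER)}
    if bad:
        raise ValueError(f"truth labels must be 'target'/'other'; got {list(bad.items())[:3]}")

    cnt = Block(0, 0, 0, 0)
    ln = Block(0, 0, 0, 0)
    for contig, cls in truth.items():
        length = lengths[contig]
        pred = contig in predicted_target
        if cls == TARGET and pred:
            cnt.tp += 1; ln.tp += length
        elif cls == TARGET:
            cnt.fn += 1; ln.fn += length
        elif pred:
            cnt.fp += 1; ln.fp += length
        else:
            cnt.tn += 1; ln.tn += length
    return PerformanceReport(counts=cnt, lengths=ln)


def comparison_table(reports: Mapping[str, PerformanceReport], weighting: str = "nucleotide_length") -> pd.DataFrame:
    """Side-by-side metric table for several methods (one column each)."""
    rows = {}
    for name, rep in reports.items():
        blk = rep.lengths if weighting == "nucleotide_length" else rep.counts
        rows[name] = {
            "Sensitivity": blk.sensitivity,
            "Precision": blk.precision,
            "Accuracy": blk.accuracy,
            "F1 score": blk.f1,
        }
    return pd.DataFrame(rows)
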