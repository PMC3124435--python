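"""Evaluating a predicted epitope patch against a known epitope.

Residue-level confusion counts over a universe of residues (by default the
surface residues of the analysed chain, since the method never predicts
buried residues) yield sensitivity Se = TP/(TP+FN), precision
Pr = TP/(TP+FP), and the Matthews correlation coefficient.  A metric whose
denominator vanishes is reported as 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .structure import ResidueKey

__all__ = ["ConfusionCounts", "Metrics", "confusion_counts", "metrics", "read_truth_set"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def pe(self) -> int:
        """Number of predicted epitopic residues (TP + FP)."""
        return self.tp + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    se: float
    pr: float
    mcc: float
    zero_denominator: bool = False


def confusion_counts(
    predicted: set[ResidueKey], truth: set[ResidueKey], universe: set[ResidueKey]
) -> ConfusionCounts:
    predicted, truth, universe = set(predicted), set(truth), set(universe)
    if not predicted <= universe:
        raise ValueError("predicted residues must lie within the universe")
    if not truth <= universe:
        raise ValueError("truth residues must lie within the universe")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> Metrics:
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    flagged = False

    if tp + fn > 0:
        se = tp / (tp + fn)
    else:
        se, flagged = 0.0, True
    if tp + fp > 0:
        pr = tp / (tp + fp)
    else:
        pr, flagged = 0.0, True
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc, flagged = 0.0, True
    return Metrics(se=se, pr=pr, mcc=mcc, zero_denominator=flagged)


def read_truth_set(source: str | Path | Iterable[str]) -> set[ResidueKey]:
    """Read a known-epitope residue list: one "chain resnum[icode]" per line."""
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    out: set[ResidueKey] = set()
    for ln in lines:
        ln = ln.split("#")[0].strip()
        if not ln:
            continue
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"expected 'chain resnum[icode]', got {ln!r}")
        chain, res = parts
        icode = ""
        num = res
        if res and res[-1].isalpha():
            num, icode = res[:-1], res[-1]
        out.add((chain, int(num), icode))
    return out
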