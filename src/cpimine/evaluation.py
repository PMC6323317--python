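"""Scoring: micro-averaged P/R/F1 over the evaluated CPR groups.

Relation identity is abstract-level — a tuple (pmid, CPR group, chemical
term, protein term) — matching challenge scoring, so a relation stated in
several sentences counts once.  The confusion matrix is built at the
candidate level over the six-class space {3, 4, 5, 6, 9, other}; its
(other, other) cell is undefined and reported as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

EVALUATED_CPR = (3, 4, 5, 6, 9)
OTHER = "other"
CLASS_SPACE = (3, 4, 5, 6, 9, OTHER)

RelationKey = tuple[str, int, str, str]


def _key(rec) -> RelationKey:
    if isinstance(rec, tuple):
        return rec
    return (rec.pmid, rec.cpr, rec.arg1_term, rec.arg2_term)


def dedupe_relations(records: Iterable) -> set[RelationKey]:
    """Unique relation identities (pmid, cpr, arg1, arg2)."""
    return {_key(r) for r in records}


@dataclass
class PRFReport:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
        }


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean; 0 when both components vanish."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def micro_prf(
    gold: Iterable,
    pred: Iterable,
    eval_classes: Sequence[int] = EVALUATED_CPR,
) -> PRFReport:
    """Micro-averaged precision/recall/F1 from pooled TP/FP/FN counts.

    Both inputs are deduplicated to relation identities and restricted to
    the evaluated classes before counting.
    """
    classes = set(eval_classes)
    g = {k for k in dedupe_relations(gold) if k[1] in classes}
    p = {k for k in dedupe_relations(pred) if k[1] in classes}
    tp = len(g & p)
    notes = []
    if not g:
        notes.append("empty gold set: recall undefined, reported as 0")
        warnings.warn(notes[-1], stacklevel=2)
    precision = tp / len(p) if p else 0.0
    recall = tp / len(g) if g else 0.0
    return PRFReport(precision, recall, f1_score(precision, recall),
                     tp, len(p) - tp, len(g) - tp, notes)


def confusion(
    gold_labels: Sequence[int | str],
    pred_labels: Sequence[int | str],
) -> pd.DataFrame:
    """Candidate-level confusion matrix over {3, 4, 5, 6, 9, other}.

    Labels outside the evaluated groups fold into ``other``.  The
    (other, other) cell is set to NA: candidates that are neither annotated
    nor predicted as an interaction are not enumerable at the abstract level.
    """
    if len(gold_labels) != len(pred_labels):
        raise ValueError("gold and predicted label sequences differ in length")

    def fold(c) -> int | str:
        return c if c in EVALUATED_CPR else OTHER

    mat = pd.DataFrame(0, index=list(CLASS_SPACE), columns=list(CLASS_SPACE), dtype="Int64")
    for g, p in zip(gold_labels, pred_labels):
        mat.loc[fold(g), fold(p)] += 1
    mat.loc[OTHER, OTHER] = pd.NA
    mat.index.name = "gold"
    mat.columns.name = "pred"
    return mat


def relation_confusion(gold: Iterable, pred: Iterable) -> pd.DataFrame:
    """Confusion matrix aligned on abstract-level pair identities.

    Each (pmid, arg1, arg2) identity contributes one cell: its gold class
    (or ``other`` if unannotated) against its predicted class (or ``other``
    if not predicted).  When an identity carries several classes the lowest
    evaluated id wins, mirroring the conflict rule used for labeling.
    """
    def collapse(keys: Iterable[RelationKey]) -> dict[tuple[str, str, str], int]:
        by_id: dict[tuple[str, str, str], list[int]] = {}
        for pmid, cpr, a1, a2 in keys:
            by_id.setdefault((pmid, a1, a2), []).append(cpr)
        out = {}
        for ident, cprs in by_id.items():
            ev = sorted(c for c in cprs if c in EVALUATED_CPR)
            out[ident] = ev[0] if ev else min(cprs)
        return out

    g = collapse(dedupe_relations(gold))
    p = collapse(dedupe_relations(pred))
    idents = sorted(set(g) | set(p))
    gold_labels = [g.get(i, OTHER) for i in idents]
    pred_labels = [p.get(i, OTHER) for i in idents]
    return confusion(gold_labels, pred_labels)


def per_class_prf(conf: pd.DataFrame) -> pd.DataFrame:
    """Per-class precision/recall/F1 from a confusion matrix.

    recall(c) = diagonal / gold-row sum; precision(c) = diagonal /
    predicted-column sum.  Zero rows or columns give 0 with a ``degenerate``
    flag.
    """
    out = {}
    for c in EVALUATED_CPR:
        diag = int(conf.loc[c, c])
        row = int(conf.loc[c].sum())
        col = int(conf[c].sum())
        rec = diag / row if row else 0.0
        prec = diag / col if col else 0.0
        out[c] = {
            "precision": prec,
            "recall": rec,
            "f1": f1_score(prec, rec),
            "support": row,
            "degenerate": float(row == 0 or col == 0),
        }
    return pd.DataFrame(out).T


def format_report(conf: pd.DataFrame, per_class: pd.DataFrame, micro: PRFReport) -> str:
    """Human-readable confusion-and-metrics table."""
    lines = ["Confusion matrix (rows = gold, columns = predicted)", str(conf), ""]
    lines.append(per_class.to_string(float_format=lambda v: f"{v:.4f}"))
    lines.append("")
    lines.append(
        f"micro  P={micro.precision:.4f}  R={micro.recall:.4f}  F1={micro.f1:.4f}  "
        f"(TP={micro.tp} FP={micro.fp} FN={micro.fn})"
    )
    return "\n".join(lines)
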