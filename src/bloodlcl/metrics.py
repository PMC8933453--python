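"""Diagnostic-performance evaluation of tissue-of-origin calls.

Two views are provided. The binary view treats "blood" as the positive test
outcome and both "LCL" and "uncertain" as negative (abstaining on a true
blood sample costs sensitivity; abstaining on an LCL never costs
specificity — the convention under which the published per-assay and
combined sensitivity/specificity/PPV/NPV/accuracy are defined). The
concordance view cross-tabulates three-way calls against database
annotations (blood / LCL / unknown), reporting per-row and overall agreement
on annotated samples and the fraction of previously unannotated samples the
test resolves.

Display rounding follows the published convention: percentages to one
decimal place, accuracy as a proportion to three; full-precision values
remain available on the objects. Ratios with zero denominators are reported
as None (undefined), never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import BLOOD, LCL, UNCERTAIN

ANNOTATIONS = (BLOOD, LCL, "unknown")


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


@dataclass(frozen=True)
class BinaryEval:
    """Confusion counts and derived metrics under the blood-positive convention."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        """tp / (tp + fn), percent; None when no true positives exist."""
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return _pct(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float | None:
        """(tp + tn) / total, as a proportion in [0, 1]."""
        t = self.total
        return None if t == 0 else (self.tp + self.tn) / t

    def rounded(self) -> dict[str, float | None]:
        """Metrics at display precision: percentages 1 dp, accuracy 3 dp."""
        rnd = lambda v, nd: None if v is None else round(v, nd)
        return {
            "sensitivity_pct": rnd(self.sensitivity, 1),
            "specificity_pct": rnd(self.specificity, 1),
            "ppv_pct": rnd(self.ppv, 1),
            "npv_pct": rnd(self.npv, 1),
            "accuracy": rnd(self.accuracy, 3),
        }

    def summary(self, name: str = "assay") -> str:
        fmt = lambda v: "undefined" if v is None else f"{v:.1f}"
        acc = self.accuracy
        return (f"{name}: sensitivity {fmt(self.sensitivity)}% | "
                f"specificity {fmt(self.specificity)}% | PPV {fmt(self.ppv)}% | "
                f"NPV {fmt(self.npv)}% | accuracy "
                f"{'undefined' if acc is None else f'{acc:.3f}'} "
                f"(tp={self.tp} fp={self.fp} tn={self.tn} fn={self.fn})")


def evaluate_binary(calls, truth) -> BinaryEval:
    """Score three-way calls against blood/LCL ground truth.

    ``calls`` are labels in {blood, LCL, uncertain} (an OriginCall's
    ``combined`` field or any per-assay label); ``truth`` must be strictly
    binary. Positive = call of blood; negative = LCL or uncertain call.
    """
    calls = list(calls)
    truth = list(truth)
    if len(calls) != len(truth):
        raise ValueError(f"length mismatch: {len(calls)} calls vs {len(truth)} truth labels")
    tp = fp = tn = fn = 0
    for c, t in zip(calls, truth):
        if t not in (BLOOD, LCL):
            raise ValueError(f"truth labels must be blood or LCL, got {t!r}")
        if c not in (BLOOD, LCL, UNCERTAIN):
            raise ValueError(f"unknown call label {c!r}")
        positive = (c == BLOOD)
        if t == BLOOD:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return BinaryEval(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class ConcordanceTable:
    """Cross-tabulation of test calls against database annotations.

    ``table`` has annotation classes (blood, LCL, unknown) as rows and test
    outcomes (blood, LCL, uncertain) as columns. Concordance counts a sample
    when an annotated blood/LCL row receives the matching call; unknown rows
    contribute to the identified rate instead.
    """

    table: pd.DataFrame

    @property
    def n_total(self) -> int:
        return int(self.table.values.sum())

    @property
    def n_annotated(self) -> int:
        return int(self.table.loc[[BLOOD, LCL]].values.sum())

    @property
    def row_concordance_pct(self) -> dict[str, float | None]:
        """Per annotated class: fraction of its samples called concordantly."""
        out: dict[str, float | None] = {}
        for cls in (BLOOD, LCL):
            n = int(self.table.loc[cls].sum())
            out[cls] = _pct(int(self.table.loc[cls, cls]), n)
        return out

    @property
    def overall_concordance_pct(self) -> float | None:
        """Agreement on annotated rows; None when nothing is annotated."""
        agree = int(self.table.loc[BLOOD, BLOOD] + self.table.loc[LCL, LCL])
        return _pct(agree, self.n_annotated)

    @property
    def identified_rate_pct(self) -> float | None:
        """Fraction of unknown-annotation samples resolved to blood or LCL."""
        n_unknown = int(self.table.loc["unknown"].sum())
        identified = int(self.table.loc["unknown", BLOOD] + self.table.loc["unknown", LCL])
        return _pct(identified, n_unknown)

    @property
    def n_uncertain_calls(self) -> int:
        return int(self.table[UNCERTAIN].sum())

    @property
    def uncertain_call_pct(self) -> float | None:
        return _pct(self.n_uncertain_calls, self.n_total)

    def summary(self) -> str:
        fmt = lambda v: "undefined" if v is None else f"{v:.2f}%"
        lines = [self.table.to_string()]
        lines.append(f"overall concordance (annotated, n={self.n_annotated}): "
                     f"{fmt(self.overall_concordance_pct)}")
        lines.append(f"identified among unknown: {fmt(self.identified_rate_pct)}")
        lines.append(f"remaining uncertain: {self.n_uncertain_calls}/{self.n_total} "
                     f"({fmt(self.uncertain_call_pct)})")
        return "\n".join(lines)


def concordance(calls, annotations) -> ConcordanceTable:
    """Cross-tabulate three-way calls against blood/LCL/unknown annotations."""
    calls = list(calls)
    annotations = list(annotations)
    if len(calls) != len(annotations):
        raise ValueError(
            f"length mismatch: {len(calls)} calls vs {len(annotations)} annotations")
    for a in annotations:
        if a not in ANNOTATIONS:
            raise ValueError(f"annotations must be in {ANNOTATIONS}, got {a!r}")
    for c in calls:
        if c not in (BLOOD, LCL, UNCERTAIN):
            raise ValueError(f"unknown call label {c!r}")
    tab = pd.crosstab(pd.Series(annotations, name="annotation"),
                      pd.Series(calls, name="call"))
    tab = tab.reindex(index=list(ANNOTATIONS), columns=[BLOOD, LCL, UNCERTAIN],
                      fill_value=0).astype(int)
    return ConcordanceTable(table=tab)


def labels_from_counts(table: dict[str, dict[str, int]]) -> tuple[list[str], list[str]]:
    """Expand a {annotation: {call: count}} table into paired label lists.

    Convenience for re-evaluating published cross-tabulations through the
    same code path as per-sample data.
    """
    anns: list[str] = []
    calls: list[str] = []
    for ann, row in table.items():
        for call, n in row.items():
            anns.extend([ann] * n)
            calls.extend([call] * n)
    return calls, anns
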