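"""Venn set algebra, discriminant signatures and their evaluation.

A discriminant signature is the set difference between the case-shared and
control-shared detection sets: miRNAs detected in every case but not in
every control.  A sample "displays" a signature iff every member is called
present in it (conjunctive all-present rule); sensitivity and specificity
follow from tabulating displays against the annotated group.  An optional
k-of-n partial-match mode is provided for exploration but is off by
default — the canonical classifier is the strict conjunction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    DetectionCallMatrix,
    DetectionLevelMatrix,
    DetectomeError,
    MiRNASet,
    SampleAnnotation,
    VennPartition,
    annotations_frame,
)

log = logging.getLogger(__name__)


def venn_partition(a: MiRNASet, b: MiRNASet) -> VennPartition:
    """Exact two-set decomposition: (A\\B, A∩B, B\\A)."""
    return VennPartition(
        exclusive_a=MiRNASet(f"{a.name}_only", a.members - b.members),
        shared=MiRNASet(f"{a.name}_and_{b.name}", a.members & b.members),
        exclusive_b=MiRNASet(f"{b.name}_only", b.members - a.members),
    )


def derive_signature(
    case_shared: MiRNASet, control_shared: MiRNASet, name: str | None = None
) -> MiRNASet:
    """Case-exclusive block of the Venn: detected in all cases, not in all
    controls.  Disjoint from the control-shared set by construction."""
    venn = venn_partition(case_shared, control_shared)
    return MiRNASet(
        name or f"{case_shared.name}_exclusive_signature", venn.exclusive_a.members
    )


def reference_overlap(sig: MiRNASet, reference: MiRNASet) -> VennPartition:
    """Overlap of a signature with a reference set (e.g. a tumor-core list):
    exclusive_a = signature members absent from the reference."""
    return venn_partition(sig, reference)


def call_signature(
    calls: DetectionCallMatrix,
    sample: str,
    sig: MiRNASet,
    min_fraction: float = 1.0,
) -> bool:
    """Does the sample display the signature?

    True iff every member is called present (``min_fraction=1.0``, the
    canonical rule).  Lower fractions give the exploratory k-of-n mode.
    An empty signature is vacuously displayed by every sample.
    """
    if sample not in calls.calls.columns:
        raise DetectomeError(f"unknown sample id {sample!r}")
    missing = sorted(m for m in sig.members if m not in calls.calls.index)
    if missing:
        raise DetectomeError(f"signature member(s) missing from matrix: {missing}")
    if not sig.members:
        log.warning("empty signature %r: vacuously true for every sample", sig.name)
        return True
    col = calls.calls.loc[sorted(sig.members), sample]
    return bool(col.mean() >= min_fraction)


@dataclass(frozen=True)
class SignatureEvaluation:
    """Per-sample signature displays tabulated against the annotated group.

    Sensitivity/specificity are ``None`` (undefined, never 0) when the
    corresponding denominator is empty.  ``in_sample=True`` flags
    resubstitution: the signature was derived from the same samples it is
    being evaluated on, so sensitivity is 1.0 by construction.
    """

    signature: MiRNASet
    per_sample: dict[str, bool]
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    in_sample: bool = False


def evaluate_signature(
    calls: DetectionCallMatrix,
    annotations: Sequence[SampleAnnotation],
    sig: MiRNASet,
    case_label: str = "case",
    samples: Iterable[str] | None = None,
    in_sample: bool = False,
    min_fraction: float = 1.0,
) -> SignatureEvaluation:
    ann = annotations_frame(annotations)
    scope = list(samples) if samples is not None else calls.sample_ids
    missing = [s for s in scope if s not in ann.index]
    if missing:
        raise DetectomeError(f"unannotated sample(s): {missing}")
    displays = {s: call_signature(calls, s, sig, min_fraction) for s in scope}
    is_case = {s: ann.loc[s, "group"] == case_label for s in scope}
    tp = sum(1 for s in scope if is_case[s] and displays[s])
    fn = sum(1 for s in scope if is_case[s] and not displays[s])
    fp = sum(1 for s in scope if not is_case[s] and displays[s])
    tn = sum(1 for s in scope if not is_case[s] and not displays[s])
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return SignatureEvaluation(
        signature=sig,
        per_sample=displays,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        in_sample=in_sample,
    )


@dataclass(frozen=True)
class AbundanceReport:
    """Signature-member mean detection levels vs the global scope mean.
    ``above_average`` uses a strict '>' so a constant matrix flags nothing."""

    per_mirna_mean: pd.Series
    global_mean: float

    @property
    def above_average(self) -> pd.Series:
        return self.per_mirna_mean > self.global_mean

    @property
    def all_above(self) -> bool:
        return bool(self.above_average.all())


def abundance_check(
    levels: DetectionLevelMatrix,
    sig: MiRNASet,
    samples: Iterable[str] | None = None,
) -> AbundanceReport:
    """Mean log2 level of each signature member across the scope, against
    the grand mean over all miRNAs x scope samples."""
    scope = list(samples) if samples is not None else levels.sample_ids
    missing = [s for s in scope if s not in levels.levels.columns]
    if missing:
        raise DetectomeError(f"unknown sample id(s): {missing}")
    absent = sorted(m for m in sig.members if m not in levels.levels.index)
    if absent:
        raise DetectomeError(f"signature member(s) missing from levels: {absent}")
    sub = levels.levels.loc[sorted(sig.members), scope]
    return AbundanceReport(
        per_mirna_mean=sub.mean(axis=1),
        global_mean=float(levels.levels.loc[:, scope].to_numpy().mean()),
    )
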