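"""Endogenous-normalizer candidate screening.

A good endogenous reference for relative quantification in plasma should
be (i) detected in every sample regardless of group or compartment and
(ii) stable: low variance of its log2 detection level across samples,
ideally at a high level.  ``universal_candidates`` yields the pool that
satisfies (i); ``stability_report`` ranks any candidate list by ascending
variance (unbiased, n-1 denominator, log2-squared units), breaking ties by
higher mean level and then id.  ``candidate_comparison`` applies the same
statistics to user-nominated conventional normalizers (e.g. miR-16/miR-21)
that need not be universally detected, adding a per-compartment detection
breakdown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calls import group_shared_set
from .model import (
    DetectionCallMatrix,
    DetectionLevelMatrix,
    DetectomeError,
    MiRNASet,
    SampleAnnotation,
    annotations_frame,
)

log = logging.getLogger(__name__)


def universal_candidates(
    calls: DetectionCallMatrix, name: str = "universal"
) -> MiRNASet:
    """miRNAs detected in every sample of the matrix — the candidate pool."""
    return group_shared_set(calls, None, name=name)


def _stats_frame(
    levels: DetectionLevelMatrix, candidates: Sequence[str], scope: list[str]
) -> pd.DataFrame:
    sub = levels.levels.loc[candidates, scope]
    df = pd.DataFrame(
        {
            "variance": sub.var(axis=1, ddof=1),
            "mean": sub.mean(axis=1),
            "median": sub.median(axis=1),
        }
    )
    df.index.name = "mirna_id"
    return df


def _rank(df: pd.DataFrame) -> pd.DataFrame:
    # ascending variance; ties -> higher mean, then lexicographic id
    order = sorted(
        df.index, key=lambda m: (df.at[m, "variance"], -df.at[m, "mean"], m)
    )
    df = df.loc[order].copy()
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def stability_report(
    levels: DetectionLevelMatrix,
    candidates: MiRNASet,
    calls: DetectionCallMatrix | None = None,
    samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Rank candidates by level stability across the scope.

    Columns: variance (log2^2 units), mean, median, detected_in, n_samples,
    rank (1 = most stable).  Every candidate must exist in the level matrix.
    """
    scope = list(samples) if samples is not None else levels.sample_ids
    missing = sorted(m for m in candidates.members if m not in levels.levels.index)
    if missing:
        raise DetectomeError(f"candidate(s) missing from level matrix: {missing}")
    ids = candidates.sorted_members()
    df = _stats_frame(levels, ids, scope)
    if calls is not None:
        in_calls = [m for m in ids if m in calls.calls.index]
        detected = calls.calls.loc[in_calls, [s for s in scope if s in calls.calls.columns]]
        df["detected_in"] = detected.sum(axis=1).reindex(ids)
    else:
        df["detected_in"] = pd.NA
    df["n_samples"] = len(scope)
    return _rank(df)


@dataclass(frozen=True)
class CandidateComparison:
    """Stability statistics for user-nominated normalizers plus where (which
    compartment) each one is actually detected."""

    report: pd.DataFrame
    detection_by_compartment: pd.DataFrame
    missing: list[str]


def candidate_comparison(
    levels: DetectionLevelMatrix,
    calls: DetectionCallMatrix,
    user_candidates: MiRNASet,
    annotations: Sequence[SampleAnnotation] | None = None,
    samples: Iterable[str] | None = None,
) -> CandidateComparison:
    """Same statistics as ``stability_report`` for candidates that may be
    detected in only a few samples; absent ones are reported, not fatal."""
    scope = list(samples) if samples is not None else levels.sample_ids
    present = sorted(m for m in user_candidates.members if m in levels.levels.index)
    missing = sorted(m for m in user_candidates.members if m not in levels.levels.index)
    if missing:
        log.warning("candidate(s) not on the platform: %s", missing)
    if not present:
        log.warning("no user candidate overlaps the matrices; empty report")
        empty = pd.DataFrame(
            columns=["variance", "mean", "median", "detected_in", "n_samples", "rank"]
        )
        return CandidateComparison(empty, pd.DataFrame(), missing)
    df = _stats_frame(levels, present, scope)
    call_scope = [s for s in scope if s in calls.calls.columns]
    df["detected_in"] = calls.calls.loc[present, call_scope].sum(axis=1)
    df["n_samples"] = len(call_scope)
    df = _rank(df)

    if annotations is not None:
        ann = annotations_frame(annotations)
        comp = ann.loc[[s for s in call_scope if s in ann.index], "compartment"]
        by_comp = {
            c: calls.calls.loc[present, comp.index[comp == c]].sum(axis=1)
            for c in sorted(comp.unique())
        }
        breakdown = pd.DataFrame(by_comp)
    else:
        breakdown = pd.DataFrame(index=pd.Index(present, name="mirna_id"))
    return CandidateComparison(df, breakdown, missing)
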