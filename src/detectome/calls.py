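"""Core detection-score computations.

A detection call declares a miRNA 'present' in a sample when its
detection-above-background p-value falls strictly below alpha.  Everything
this module derives from the resulting boolean matrix is set algebra over
sample scopes:

* the uniform-detection partition of a scope (absent everywhere /
  variably detected / present everywhere),
* the group-shared set (present in 100% of a scope — the algebraic form of
  the "nested cluster shared by all samples" seen on detection maps), and
* miRNome-size summaries (how many miRNAs a sample detects, averaged per
  group).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    DetectionCallMatrix,
    ClusterPartition,
    DetectomeError,
    MiRNASet,
    SampleAnnotation,
    annotations_frame,
)


def binarize(p_values: pd.DataFrame, alpha: float = 0.05) -> DetectionCallMatrix:
    """Threshold detection p-values at strict ``p < alpha``.

    The boundary is exclusive: p == alpha is 'absent'.  The alpha used is
    recorded in the matrix provenance so the binarization is reproducible.
    """
    if not 0 < alpha < 1:
        raise DetectomeError(f"alpha must lie in (0, 1), got {alpha}")
    vals = p_values.to_numpy(float)
    if np.isnan(vals).any():
        raise DetectomeError("missing detection p-values are not allowed")
    if (vals < 0).any() or (vals > 1).any():
        raise DetectomeError("detection p-values must lie in [0, 1]")
    return DetectionCallMatrix(
        calls=p_values < alpha,
        p_values=p_values,
        alpha=alpha,
        provenance={"alpha": alpha, "rule": "p < alpha (strict)"},
    )


def _scope(calls: DetectionCallMatrix, samples: Iterable[str] | None) -> pd.DataFrame:
    if samples is None:
        return calls.calls
    samples = list(samples)
    if not samples:
        raise DetectomeError("sample scope must be non-empty")
    missing = [s for s in samples if s not in calls.calls.columns]
    if missing:
        raise DetectomeError(f"unknown sample id(s): {missing}")
    return calls.calls.loc[:, samples]


def partition_mirnome(
    calls: DetectionCallMatrix,
    samples: Iterable[str] | None = None,
    scope_name: str = "scope",
) -> ClusterPartition:
    """Partition all miRNAs by uniformity of detection over a sample scope.

    ``uniformly_absent`` are never detected in the scope, ``uniformly_present``
    are detected in every scoped sample, and ``variable`` is the remainder;
    the three blocks always partition the full miRNA list.
    """
    sub = _scope(calls, samples)
    n_present = sub.sum(axis=1)
    n = sub.shape[1]
    absent = sub.index[n_present == 0]
    present = sub.index[n_present == n]
    variable = sub.index[(n_present > 0) & (n_present < n)]
    return ClusterPartition(
        uniformly_absent=MiRNASet(f"{scope_name}_uniformly_absent", absent),
        variable=MiRNASet(f"{scope_name}_variable", variable),
        uniformly_present=MiRNASet(f"{scope_name}_uniformly_present", present),
    )


def group_shared_set(
    calls: DetectionCallMatrix,
    samples: Iterable[str] | None = None,
    name: str = "shared",
) -> MiRNASet:
    """miRNAs called present in every sample of the scope."""
    part = partition_mirnome(calls, samples, scope_name=name)
    return MiRNASet(name, part.uniformly_present.members)


@dataclass(frozen=True)
class MiRNomeSizeSummary:
    """Detected-miRNA counts for one scope: per-sample counts plus their
    mean/min/max (units: miRNAs).  ``mean_1dp`` is the mean rounded to one
    decimal for report formatting; ``mean`` keeps full precision."""

    scope: str
    per_sample_counts: dict[str, int]
    mean: float
    minimum: int
    maximum: int

    @property
    def mean_1dp(self) -> float:
        return round(self.mean, 1)

    @property
    def n_samples(self) -> int:
        return len(self.per_sample_counts)


def mirnome_size(
    calls: DetectionCallMatrix,
    annotations: Sequence[SampleAnnotation],
    group_by: Sequence[str] = (),
) -> list[MiRNomeSizeSummary]:
    """Summarize detected-miRNA counts per annotation group.

    Each sample's count is its call-matrix column sum.  Group means weight
    samples equally (they are means of per-sample counts, never pooled
    counts).  With an empty ``group_by`` a single summary labelled 'all'
    covers every sample.
    """
    ann = annotations_frame(annotations)
    missing = [s for s in calls.sample_ids if s not in ann.index]
    if missing:
        raise DetectomeError(f"unannotated sample(s): {missing}")
    counts = calls.calls.sum(axis=0)

    def summarize(scope: str, sample_ids: list[str]) -> MiRNomeSizeSummary:
        c = counts.loc[sample_ids]
        return MiRNomeSizeSummary(
            scope=scope,
            per_sample_counts={s: int(c[s]) for s in sample_ids},
            mean=float(c.mean()),
            minimum=int(c.min()),
            maximum=int(c.max()),
        )

    if not group_by:
        return [summarize("all", calls.sample_ids)]
    for field in group_by:
        if field not in ann.columns:
            raise DetectomeError(f"unknown annotation field {field!r}")
    sub = ann.loc[calls.sample_ids, list(group_by)]
    out: list[MiRNomeSizeSummary] = []
    for key, grp in sub.groupby(list(group_by), sort=True):
        key_t = key if isinstance(key, tuple) else (key,)
        label = "/".join(str(k) for k in key_t)
        out.append(summarize(label, list(grp.index)))
    return out
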