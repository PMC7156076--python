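"""Domain types for detection-call miRNome analysis.

The study design this package serves measures a complete miRNome (a few
thousand probesets) per sample and records, for every probeset, a detection
call ('present'/'absent' with an associated p-value from a
detection-above-background test) and a detection level (log2 fluorescence
intensity).  All downstream analyses — uniform-detection partitioning,
binary clustering maps, Venn set algebra, signature classification,
normalizer ranking and the differential contrast — operate on the two
matrices plus a per-sample annotation table.

Matrices are stored miRNAs x samples as pandas DataFrames; miRNA and sample
identifiers are opaque, whitespace-trimmed, case-preserved strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("case", "control")
COMPARTMENTS = ("plasma", "EV", "tumor")
SEXES = ("F", "M", "unknown")

DEFAULT_ALPHA = 0.05


class DetectomeError(ValueError):
    """Base class for input-contract violations."""


def normalize_id(raw: str) -> str:
    """Trim surrounding whitespace; case and the 'hsa-' prefix are preserved
    verbatim (mature miRNA names are case-sensitive by miRBase convention)."""
    return str(raw).strip()


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DetectomeError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class DetectionCallMatrix:
    """Boolean present/absent calls per miRNA x sample.

    ``calls`` is a boolean DataFrame (index = miRNA ids, columns = sample
    ids, True = 'present').  When the underlying detection p-values are
    known they ride along in ``p_values`` and must be consistent with the
    calls at the recorded ``alpha`` (strict ``p < alpha``).
    """

    calls: pd.DataFrame
    p_values: pd.DataFrame | None = None
    alpha: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls.index = [normalize_id(i) for i in self.calls.index]
        self.calls.columns = [normalize_id(c) for c in self.calls.columns]
        _check_unique(list(self.calls.index), "miRNA")
        _check_unique(list(self.calls.columns), "sample")
        if self.calls.dtypes.apply(lambda d: d != bool).any():
            self.calls = self.calls.astype(bool)
        if self.p_values is not None:
            p = self.p_values
            if p.shape != self.calls.shape:
                raise DetectomeError(
                    f"p_values shape {p.shape} != calls shape {self.calls.shape}"
                )
            p.index = [normalize_id(i) for i in p.index]
            p.columns = [normalize_id(c) for c in p.columns]
            if list(p.index) != list(self.calls.index) or list(p.columns) != list(
                self.calls.columns
            ):
                raise DetectomeError("p_values ids do not match calls ids")
            vals = p.to_numpy(float)
            if np.isnan(vals).any():
                raise DetectomeError("missing detection p-values are not allowed")
            if (vals < 0).any() or (vals > 1).any():
                raise DetectomeError("detection p-values must lie in [0, 1]")
            if self.alpha is not None:
                expected = vals < self.alpha
                if not np.array_equal(expected, self.calls.to_numpy(bool)):
                    raise DetectomeError(
                        "calls are inconsistent with p_values at alpha="
                        f"{self.alpha}"
                    )

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    def subset_samples(self, samples: Iterable[str]) -> "DetectionCallMatrix":
        samples = [normalize_id(s) for s in samples]
        missing = [s for s in samples if s not in self.calls.columns]
        if missing:
            raise DetectomeError(f"unknown sample id(s): {missing}")
        return DetectionCallMatrix(
            calls=self.calls.loc[:, samples].copy(),
            p_values=None if self.p_values is None else self.p_values.loc[:, samples].copy(),
            alpha=self.alpha,
            provenance=dict(self.provenance),
        )


@dataclass
class DetectionLevelMatrix:
    """log2 intensity ('detection level') values per miRNA x sample."""

    levels: pd.DataFrame

    def __post_init__(self) -> None:
        self.levels.index = [normalize_id(i) for i in self.levels.index]
        self.levels.columns = [normalize_id(c) for c in self.levels.columns]
        _check_unique(list(self.levels.index), "miRNA")
        _check_unique(list(self.levels.columns), "sample")
        vals = self.levels.to_numpy(float)
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise DetectomeError(
                "non-finite detection level at row "
                f"{self.levels.index[bad[0]]!r}, column {self.levels.columns[bad[1]]!r}"
            )

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.levels.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.levels.columns)


@dataclass(frozen=True)
class SampleAnnotation:
    """One sample's metadata; drives every subsetting operation."""

    sample_id: str
    group: str
    compartment: str
    sex: str = "unknown"
    age_months: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_id", normalize_id(self.sample_id))
        if self.group not in GROUPS:
            raise DetectomeError(
                f"unknown group token {self.group!r} (expected one of {GROUPS})"
            )
        if self.compartment not in COMPARTMENTS:
            raise DetectomeError(
                f"unknown compartment token {self.compartment!r} "
                f"(expected one of {COMPARTMENTS})"
            )
        if self.sex not in SEXES:
            raise DetectomeError(
                f"unknown sex token {self.sex!r} (expected one of {SEXES})"
            )
        if self.age_months is not None and not (
            isinstance(self.age_months, (int, float)) and self.age_months >= 0
        ):
            raise DetectomeError(f"age_months must be non-negative, got {self.age_months!r}")


def annotations_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Tabular view of annotations, indexed by sample_id."""
    _check_unique([a.sample_id for a in annotations], "sample")
    return pd.DataFrame(
        {
            "group": [a.group for a in annotations],
            "compartment": [a.compartment for a in annotations],
            "sex": [a.sex for a in annotations],
            "age_months": [a.age_months for a in annotations],
        },
        index=pd.Index([a.sample_id for a in annotations], name="sample_id"),
    )


def select_samples(
    annotations: Sequence[SampleAnnotation], **criteria: str
) -> list[str]:
    """Sample ids whose annotation matches every ``field=value`` criterion."""
    out = []
    for a in annotations:
        if all(getattr(a, k) == v for k, v in criteria.items()):
            out.append(a.sample_id)
    return out


@dataclass(frozen=True)
class MiRNASet:
    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(
            self, "members", frozenset(normalize_id(m) for m in members)
        )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return normalize_id(item) in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class VennPartition:
    """Exact two-set decomposition A\\B | A∩B | B\\A."""

    exclusive_a: MiRNASet
    shared: MiRNASet
    exclusive_b: MiRNASet

    def __post_init__(self) -> None:
        a, s, b = (
            self.exclusive_a.members,
            self.shared.members,
            self.exclusive_b.members,
        )
        if a & s or a & b or s & b:
            raise DetectomeError("Venn partition blocks must be pairwise disjoint")

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.exclusive_a), len(self.shared), len(self.exclusive_b))

    @property
    def set_a(self) -> frozenset[str]:
        return self.exclusive_a.members | self.shared.members

    @property
    def set_b(self) -> frozenset[str]:
        return self.exclusive_b.members | self.shared.members


@dataclass(frozen=True)
class ClusterPartition:
    """Uniform-detection partition of a call matrix over a sample scope:
    miRNAs absent in every sample, present in every sample, or variable."""

    uniformly_absent: MiRNASet
    variable: MiRNASet
    uniformly_present: MiRNASet

    def __post_init__(self) -> None:
        a, v, p = (
            self.uniformly_absent.members,
            self.variable.members,
            self.uniformly_present.members,
        )
        if a & v or a & p or v & p:
            raise DetectomeError("partition blocks must be pairwise disjoint")

    def sizes(self) -> tuple[int, int, int]:
        return (
            len(self.uniformly_absent),
            len(self.variable),
            len(self.uniformly_present),
        )

    @property
    def total(self) -> int:
        return sum(self.sizes())


DIFFERENTIAL_COLUMNS = ("logFC", "AveExpr", "t", "p_value", "adj_p_value")


def validate_differential_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-miRNA differential result schema and probability bounds."""
    for col in DIFFERENTIAL_COLUMNS:
        if col not in table.columns:
            raise DetectomeError(f"differential table missing column {col!r}")
    _check_unique(list(table.index), "miRNA")
    for col in ("p_value", "adj_p_value"):
        v = table[col].to_numpy(float)
        if (v < 0).any() or (v > 1).any():
            raise DetectomeError(f"{col} outside [0, 1]")
    if (table["adj_p_value"].to_numpy() < table["p_value"].to_numpy() - 1e-12).any():
        raise DetectomeError("adjusted p-values must be >= raw p-values")
    return table


@dataclass
class Dendrogram:
    """Rooted binary merge tree over leaf labels with non-negative merge
    heights, as produced by agglomerative clustering.

    ``merges`` follows the scipy linkage convention: row k merges nodes
    ``merges[k, 0]`` and ``merges[k, 1]`` (ids < n are leaves in ``labels``
    order) at height ``merges[k, 2]``.  A single-leaf tree has an empty
    merge table.
    """

    labels: list[str]
    merges: np.ndarray  # (n-1, 4) scipy linkage matrix; empty for n == 1
    method: str = "average"
    metric: str = "jaccard"

    def __post_init__(self) -> None:
        _check_unique(self.labels, "leaf")
        n = len(self.labels)
        self.merges = np.asarray(self.merges, float).reshape(-1, 4) if n > 1 else np.empty((0, 4))
        if n > 1:
            if self.merges.shape[0] != n - 1:
                raise DetectomeError(
                    f"expected {n - 1} merges for {n} leaves, got {self.merges.shape[0]}"
                )
            if (self.merges[:, 2] < 0).any():
                raise DetectomeError("merge heights must be non-negative")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        """Leaf labels in dendrogram (left-to-right) order."""
        if self.n_leaves <= 1:
            return list(self.labels)
        from scipy.cluster.hierarchy import leaves_list

        return [self.labels[i] for i in leaves_list(self.merges)]

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.merges[node - n, 2])

    def to_newick(self) -> str:
        """Newick string; branch lengths are parent/child height differences."""
        n = self.n_leaves
        if n == 0:
            raise DetectomeError("empty dendrogram")
        if n == 1:
            return f"{_newick_label(self.labels[0])};"

        def render(node: int, parent_height: float) -> str:
            bl = parent_height - self.node_height(node)
            bls = np.format_float_positional(max(bl, 0.0), trim="0")
            if node < n:
                return f"{_newick_label(self.labels[node])}:{bls}"
            row = self.merges[node - n]
            h = float(row[2])
            left = render(int(row[0]), h)
            right = render(int(row[1]), h)
            return f"({left},{right}):{bls}"

        root = 2 * n - 2
        h = self.node_height(root)
        row = self.merges[-1]
        left = render(int(row[0]), h)
        right = render(int(row[1]), h)
        return f"({left},{right});"


_NEWICK_META = set("();:,[]'\" \t\n")


def _newick_label(label: str) -> str:
    if any(c in _NEWICK_META for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label
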