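"""Readers and writers for the package's text formats.

Matrices travel as delimited text (TSV by default, first row = sample ids,
first column = miRNA ids); gene sets as GMT; dendrograms as Newick; sample
annotations as a TSV with fixed column names.  Every derived artifact gets
a JSON provenance sidecar recording how it was produced (binarization
alpha, source path, orientation), so a present/absent matrix can always be
traced back to its thresholding.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import (
    DetectionCallMatrix,
    DetectionLevelMatrix,
    DetectomeError,
    Dendrogram,
    MiRNASet,
    SampleAnnotation,
    normalize_id,
)

log = logging.getLogger(__name__)

Orientation = Literal["mirnas_as_rows", "samples_as_rows"]

ANNOTATION_COLUMNS = ("sample_id", "group", "compartment", "sex", "age_months")


def _read_table(path, delimiter: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    df.index = [normalize_id(i) for i in df.index]
    df.columns = [normalize_id(c) for c in df.columns]
    return df


def _to_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DetectomeError(
            f"non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    if out.isna().to_numpy().any():
        i, j = np.argwhere(out.isna().to_numpy())[0]
        raise DetectomeError(
            f"missing value at row {out.index[i]!r}, column {out.columns[j]!r} in {path}"
        )
    return out


def _orient(df: pd.DataFrame, orientation: Orientation) -> pd.DataFrame:
    if orientation == "samples_as_rows":
        return df.T
    if orientation != "mirnas_as_rows":
        raise DetectomeError(f"unknown orientation {orientation!r}")
    return df


def read_call_matrix(
    path,
    alpha: float = 0.05,
    orientation: Orientation = "mirnas_as_rows",
    delimiter: str = "\t",
    mode: Literal["auto", "p_values", "calls"] = "auto",
) -> DetectionCallMatrix:
    """Load detection calls from a delimited file.

    Cells may hold detection p-values (binarized at strict ``p < alpha``)
    or ready-made binary calls.  ``mode='auto'`` treats an all-{0,1} matrix
    as binary calls; pass an explicit mode for ambiguous inputs.
    """
    if not 0 < alpha < 1:
        raise DetectomeError(f"alpha must lie in (0, 1), got {alpha}")
    df = _orient(_to_numeric(_read_table(path, delimiter), path), orientation)
    vals = df.to_numpy(float)
    if mode == "auto":
        mode = "calls" if np.isin(vals, (0.0, 1.0)).all() else "p_values"
    if mode == "calls":
        if not np.isin(vals, (0.0, 1.0)).all():
            raise DetectomeError(f"non-binary cell in calls-mode matrix {path}")
        return DetectionCallMatrix(
            calls=df.astype(bool),
            provenance={"source": str(path), "mode": "calls"},
        )
    if (vals < 0).any() or (vals > 1).any():
        i, j = np.argwhere((vals < 0) | (vals > 1))[0]
        raise DetectomeError(
            f"p-value {vals[i, j]} outside [0, 1] at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    return DetectionCallMatrix(
        calls=df < alpha,
        p_values=df,
        alpha=alpha,
        provenance={"source": str(path), "mode": "p_values", "alpha": alpha},
    )


def read_level_matrix(
    path, orientation: Orientation = "mirnas_as_rows", delimiter: str = "\t"
) -> DetectionLevelMatrix:
    """Load a log2 detection-level matrix; non-finite cells are rejected."""
    df = _orient(_to_numeric(_read_table(path, delimiter), path), orientation)
    return DetectionLevelMatrix(levels=df)


def write_matrix(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=delimiter)


def write_call_matrix(matrix: DetectionCallMatrix, path, delimiter: str = "\t") -> None:
    write_matrix(matrix.calls.astype(int), path, delimiter)
    write_provenance(path, {**matrix.provenance, "alpha": matrix.alpha})


def pair_with_annotations(
    sample_ids: Sequence[str], annotations: Sequence[SampleAnnotation]
) -> None:
    """Check every matrix sample is annotated; raise listing the unmatched."""
    known = {a.sample_id for a in annotations}
    missing = [s for s in sample_ids if s not in known]
    if missing:
        raise DetectomeError(f"samples missing from annotations: {missing}")


def read_annotations(path, delimiter: str = "\t") -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise DetectomeError(f"annotation file {path} missing column {col!r}")
    if df.empty:
        log.warning("annotation file %s contains no samples", path)
        return []
    out: list[SampleAnnotation] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = normalize_id(row["sample_id"])
        if sid in seen:
            raise DetectomeError(f"duplicate sample_id {sid!r} in {path}")
        seen.add(sid)
        age = row["age_months"]
        age_val = None if pd.isna(age) or age == "" else float(age)
        out.append(
            SampleAnnotation(
                sample_id=sid,
                group=str(row["group"]).strip(),
                compartment=str(row["compartment"]).strip(),
                sex=str(row["sex"]).strip(),
                age_months=age_val,
            )
        )
    return out


def write_annotations(annotations: Sequence[SampleAnnotation], path, delimiter: str = "\t") -> None:
    pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "group": a.group,
                "compartment": a.compartment,
                "sex": a.sex,
                "age_months": a.age_months,
            }
            for a in annotations
        ],
        columns=list(ANNOTATION_COLUMNS),
    ).to_csv(path, sep=delimiter, index=False)


def read_gene_sets(path) -> list[MiRNASet]:
    """Read GMT: one set per line — name, description, members (tab-separated).
    Duplicate members within a set collapse with a warning."""
    sets: list[MiRNASet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DetectomeError(
                    f"GMT line {lineno} in {path} has fewer than 2 fields"
                )
            name, _desc, *members = fields
            members = [normalize_id(m) for m in members if m.strip()]
            if len(members) != len(set(members)):
                log.warning(
                    "GMT set %r (line %d) has duplicate members; collapsing",
                    name,
                    lineno,
                )
            sets.append(MiRNASet(name=name, members=members))
    return sets


def write_gene_sets(sets: Sequence[MiRNASet], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *s.sorted_members()]) + "\n")


def write_newick(dendrogram: Dendrogram, path) -> None:
    Path(path).write_text(dendrogram.to_newick() + "\n")


def write_provenance(artifact_path, info: dict) -> Path:
    """Write the JSON sidecar ``<artifact>.provenance.json``."""
    side = Path(str(artifact_path) + ".provenance.json")
    side.write_text(json.dumps(info, indent=2, default=str) + "\n")
    return side
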