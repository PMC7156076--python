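"""End-to-end orchestration of the detection-score analysis.

``run_pipeline`` executes the full analysis order on one dataset:
binarize -> per-scope uniform-detection partitions (and optional cluster
maps) -> group-shared sets -> Venn partitions (case vs control per
compartment, signature vs signature across compartments, female vs male)
-> signature derivation, reference overlap and evaluation -> miRNome
sizes -> normalizer ranking -> moderated-t differential contrast.  The
result is one JSON-serializable report whose every number is reproducible
from the stage outputs; provenance (alpha, config hash, input checksums)
rides along, with the timestamp isolated in its own field.

Sample exclusion is declarative: the config lists excluded sample ids with
a reason string; samples are never dropped silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import calls as dcalls
from . import cluster as dcluster
from . import differential as ddiff
from . import io as dio
from . import normalizers as dnorm
from . import signature as dsig
from .model import (
    DetectionCallMatrix,
    DetectionLevelMatrix,
    DetectomeError,
    MiRNASet,
    SampleAnnotation,
    VennPartition,
    annotations_frame,
    select_samples,
)

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG: dict[str, Any] = {
    "alpha": 0.05,
    "delimiter": "\t",
    "orientation": "mirnas_as_rows",
    "exclude_samples": [],
    "contrasts": [
        {"name": "plasma", "compartment": "plasma", "case_label": "case"},
        {"name": "EV", "compartment": "EV", "case_label": "case"},
    ],
    "sex_contrast": True,
    "cluster_maps": False,
    "metric": "jaccard",
    "linkage": "average",
    "differential": {"p_threshold": 0.05, "prior_df": "auto"},
    "inputs": {
        "pvalues": None,
        "calls": None,
        "levels": None,
        "annotations": None,
        "reference_sets": None,
        "conventional_normalizers": None,
    },
}


def default_config() -> dict[str, Any]:
    return json.loads(json.dumps(DEFAULT_CONFIG))


def load_config(path) -> dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for k, v in user.items():
        if isinstance(v, Mapping) and isinstance(cfg.get(k), Mapping):
            cfg[k] = {**cfg[k], **v}
        else:
            cfg[k] = v
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def _venn_dict(v: VennPartition) -> dict[str, Any]:
    return {
        "sizes": list(v.sizes()),
        "exclusive_a": v.exclusive_a.sorted_members(),
        "shared": v.shared.sorted_members(),
        "exclusive_b": v.exclusive_b.sorted_members(),
    }


def sex_contrast(
    calls: DetectionCallMatrix, annotations: Sequence[SampleAnnotation]
) -> VennPartition:
    """Venn of the female-shared vs male-shared detection sets over all
    annotated samples in the matrix."""
    in_matrix = set(calls.sample_ids)
    females = [s for s in select_samples(annotations, sex="F") if s in in_matrix]
    males = [s for s in select_samples(annotations, sex="M") if s in in_matrix]
    if not females or not males:
        raise DetectomeError(
            f"sex contrast needs both sexes (got {len(females)} F, {len(males)} M)"
        )
    f_shared = dcalls.group_shared_set(calls, females, name="female_shared")
    m_shared = dcalls.group_shared_set(calls, males, name="male_shared")
    return dsig.venn_partition(f_shared, m_shared)


@dataclass
class PipelineReport:
    stages: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self, path=None) -> str:
        payload = {"stages": self.stages, "provenance": self.provenance}
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            full = dict(payload)
            full["timestamp"] = self.timestamp
            Path(path).write_text(json.dumps(full, indent=2, default=str) + "\n")
        return text


def run_pipeline_data(
    calls: DetectionCallMatrix,
    levels: DetectionLevelMatrix | None,
    annotations: Sequence[SampleAnnotation],
    config: Mapping[str, Any] | None = None,
    reference_sets: Sequence[MiRNASet] = (),
    conventional_normalizers: MiRNASet | None = None,
    out_dir=None,
) -> PipelineReport:
    """Run every analysis stage on in-memory objects."""
    cfg = default_config()
    if config:
        for k, v in config.items():
            if isinstance(v, Mapping) and isinstance(cfg.get(k), Mapping):
                cfg[k] = {**cfg[k], **v}
            else:
                cfg[k] = v
    report = PipelineReport(timestamp=datetime.now(timezone.utc).isoformat())
    report.provenance = {
        "alpha": calls.alpha,
        "config_hash": _config_hash(cfg),
        "n_mirnas": len(calls.mirna_ids),
        "n_samples": len(calls.sample_ids),
        "excluded_samples": cfg["exclude_samples"],
    }
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    excluded = {e["sample_id"] for e in cfg["exclude_samples"]}
    if excluded:
        log.info("excluding samples (declared): %s", sorted(excluded))
        keep = [s for s in calls.sample_ids if s not in excluded]
        calls = calls.subset_samples(keep)
        if levels is not None:
            keep_l = [s for s in levels.sample_ids if s not in excluded]
            levels = DetectionLevelMatrix(levels.levels.loc[:, keep_l].copy())

    def stage(name):
        def deco(fn):
            log.info("stage %s", name)
            try:
                report.stages[name] = fn()
            except Exception as exc:  # noqa: BLE001 - re-wrapped with stage name
                report.stages[name] = "FAILED"
                if out is not None:
                    report.to_json(out / "report.FAILED.json")
                raise PipelineStageError(name, exc) from exc

        return deco

    dio.pair_with_annotations(calls.sample_ids, annotations)
    ann = annotations_frame(annotations)
    signatures: dict[str, MiRNASet] = {}
    scopes: dict[str, list[str]] = {}

    for contrast in cfg["contrasts"]:
        cname = contrast["name"]
        comp = contrast.get("compartment")
        case_label = contrast.get("case_label", "case")
        in_matrix = set(calls.sample_ids)
        scope = [
            s
            for s in calls.sample_ids
            if comp is None or ann.loc[s, "compartment"] == comp
        ]
        if not scope:
            raise PipelineStageError(cname, DetectomeError(f"no samples in scope {comp!r}"))
        case_samples = [s for s in scope if ann.loc[s, "group"] == case_label]
        ctrl_samples = [s for s in scope if ann.loc[s, "group"] != case_label]
        scopes[cname] = scope

        @stage(f"partition/{cname}")
        def _():
            out_d = {}
            for label, subset in (
                ("cases", case_samples),
                ("controls", ctrl_samples),
                ("all", scope),
            ):
                if not subset:
                    continue
                part = dcalls.partition_mirnome(calls, subset, scope_name=label)
                out_d[label] = {
                    "sizes": list(part.sizes()),
                    "n_samples": len(subset),
                    "uniformly_present": part.uniformly_present.sorted_members(),
                }
            return out_d

        if cfg["cluster_maps"] and out is not None:

            @stage(f"map/{cname}")
            def _():
                sub = calls.subset_samples(scope)
                dmap = dcluster.cluster_calls(sub, cfg["metric"], cfg["linkage"])
                prefix = out / f"map_{cname}"
                dio.write_matrix(dmap.matrix.astype(int), f"{prefix}.matrix.tsv")
                if dmap.row_dendrogram:
                    dio.write_newick(dmap.row_dendrogram, f"{prefix}.rows.nwk")
                if dmap.col_dendrogram:
                    dio.write_newick(dmap.col_dendrogram, f"{prefix}.cols.nwk")
                dcluster.plot_detection_map(dmap, f"{prefix}.png")
                return {"prefix": str(prefix)}

        if case_samples and ctrl_samples:

            @stage(f"venn/{cname}")
            def _():
                case_shared = dcalls.group_shared_set(
                    calls, case_samples, name=f"{cname}_case_shared"
                )
                ctrl_shared = dcalls.group_shared_set(
                    calls, ctrl_samples, name=f"{cname}_control_shared"
                )
                venn = dsig.venn_partition(case_shared, ctrl_shared)
                sig = dsig.derive_signature(
                    case_shared, ctrl_shared, name=f"{cname}_signature"
                )
                signatures[cname] = sig
                d = _venn_dict(venn)
                d["case_shared_size"] = len(case_shared)
                d["control_shared_size"] = len(ctrl_shared)
                return d

            @stage(f"signature/{cname}")
            def _():
                sig = signatures[cname]
                ev = dsig.evaluate_signature(
                    calls,
                    annotations,
                    sig,
                    case_label=case_label,
                    samples=scope,
                    in_sample=True,
                )
                d = {
                    "members": sig.sorted_members(),
                    "size": len(sig),
                    "tp": ev.tp,
                    "fp": ev.fp,
                    "tn": ev.tn,
                    "fn": ev.fn,
                    "sensitivity": ev.sensitivity,
                    "specificity": ev.specificity,
                    "in_sample": ev.in_sample,
                    "per_sample": ev.per_sample,
                }
                for ref in reference_sets:
                    overlap = dsig.reference_overlap(sig, ref)
                    d[f"overlap_{ref.name}"] = {
                        "shared": len(overlap.shared),
                        "signature_only": len(overlap.exclusive_a),
                        "shared_members": overlap.shared.sorted_members(),
                    }
                if levels is not None and case_samples:
                    ab = dsig.abundance_check(levels, sig, case_samples)
                    d["abundance"] = {
                        "global_mean": ab.global_mean,
                        "n_above_average": int(ab.above_average.sum()),
                        "per_mirna_mean": {
                            k: float(v) for k, v in ab.per_mirna_mean.items()
                        },
                    }
                return d

            if levels is not None and len(case_samples) >= 2 and len(ctrl_samples) >= 2:

                @stage(f"differential/{cname}")
                def _():
                    sub_levels = DetectionLevelMatrix(
                        levels.levels.loc[:, scope].copy()
                    )
                    dcfg = cfg["differential"]
                    table = ddiff.moderated_t(
                        sub_levels,
                        annotations,
                        case_label=case_label,
                        prior_df=dcfg.get("prior_df", "auto"),
                    )
                    sel = ddiff.select_and_report(
                        table, dcfg.get("p_threshold", 0.05)
                    )
                    if out is not None:
                        table.to_csv(out / f"differential_{cname}.tsv", sep="\t")
                        sel.volcano.to_csv(out / f"volcano_{cname}.tsv", sep="\t")
                    return {
                        "n_mirnas": len(table),
                        "n_raw_significant": sel.n_selected,
                        "n_adjusted_significant": sel.n_adjusted_significant,
                        "threshold": sel.threshold,
                        "top": {
                            m: {
                                c: float(table.at[m, c])
                                for c in ("logFC", "AveExpr", "t", "p_value", "adj_p_value")
                            }
                            for m in table.index[:5]
                        },
                    }

    if len(signatures) >= 2:

        @stage("venn/signatures")
        def _():
            names = list(signatures)
            a, b = signatures[names[0]], signatures[names[1]]
            venn = dsig.venn_partition(a, b)
            d = _venn_dict(venn)
            inter = MiRNASet("signature_intersection", venn.shared.members)
            for cname in names:
                if inter.members:
                    ev = dsig.evaluate_signature(
                        calls,
                        annotations,
                        inter,
                        case_label="case",
                        samples=scopes[cname],
                    )
                    d[f"intersection_eval_{cname}"] = {
                        "fp": ev.fp,
                        "sensitivity": ev.sensitivity,
                        "specificity": ev.specificity,
                    }
            return d

    @stage("mirnome_size")
    def _():
        summaries = dcalls.mirnome_size(calls, annotations, ("group", "compartment"))
        summaries += dcalls.mirnome_size(calls, annotations, ("compartment",))
        return {
            s.scope: {
                "mean": s.mean,
                "mean_1dp": s.mean_1dp,
                "min": s.minimum,
                "max": s.maximum,
                "n_samples": s.n_samples,
            }
            for s in summaries
        }

    @stage("normalizers")
    def _():
        pool = dnorm.universal_candidates(calls)
        d: dict[str, Any] = {"universal": pool.sorted_members(), "n_universal": len(pool)}
        if levels is not None and pool.members:
            rep = dnorm.stability_report(levels, pool, calls=calls)
            d["ranking"] = {
                m: {
                    "variance": float(rep.at[m, "variance"]),
                    "mean": float(rep.at[m, "mean"]),
                    "median": float(rep.at[m, "median"]),
                    "rank": int(rep.at[m, "rank"]),
                }
                for m in rep.index
            }
        if levels is not None and conventional_normalizers is not None:
            comp = dnorm.candidate_comparison(
                levels, calls, conventional_normalizers, annotations
            )
            d["conventional"] = {
                m: {
                    "variance": float(comp.report.at[m, "variance"]),
                    "mean": float(comp.report.at[m, "mean"]),
                    "median": float(comp.report.at[m, "median"]),
                    "detected_in": int(comp.report.at[m, "detected_in"]),
                    "n_samples": int(comp.report.at[m, "n_samples"]),
                }
                for m in comp.report.index
            }
            d["conventional_missing"] = comp.missing
        return d

    if cfg["sex_contrast"]:

        @stage("sex_contrast")
        def _():
            venn = sex_contrast(calls, annotations)
            d = _venn_dict(venn)
            d["female_shared_size"] = len(venn.set_a)
            d["male_shared_size"] = len(venn.set_b)
            return d

    if out is not None:
        report.to_json(out / "report.json")
    return report


def run_pipeline(config_path, out_dir=None) -> PipelineReport:
    """Load matrices named by a YAML config and run every stage."""
    cfg = load_config(config_path)
    inputs = cfg["inputs"]
    for key in ("annotations",):
        if not inputs.get(key):
            raise DetectomeError(f"config must name inputs.{key}")
    if not inputs.get("pvalues") and not inputs.get("calls"):
        raise DetectomeError("config must name inputs.pvalues or inputs.calls")
    for key in ("pvalues", "calls", "levels", "annotations", "reference_sets",
                "conventional_normalizers"):
        p = inputs.get(key)
        if p and not Path(p).exists():
            raise DetectomeError(f"input file not found: {p}")

    checksums = {
        k: _sha256(v) for k, v in inputs.items() if v and Path(v).exists()
    }
    mat_path = inputs.get("pvalues") or inputs["calls"]
    mode = "p_values" if inputs.get("pvalues") else "calls"
    calls = dio.read_call_matrix(
        mat_path,
        alpha=cfg["alpha"],
        orientation=cfg["orientation"],
        delimiter=cfg["delimiter"],
        mode=mode,
    )
    levels = (
        dio.read_level_matrix(inputs["levels"], cfg["orientation"], cfg["delimiter"])
        if inputs.get("levels")
        else None
    )
    annotations = dio.read_annotations(inputs["annotations"])
    refs = dio.read_gene_sets(inputs["reference_sets"]) if inputs.get("reference_sets") else []
    conventional = None
    if inputs.get("conventional_normalizers"):
        sets = dio.read_gene_sets(inputs["conventional_normalizers"])
        members = [m for s in sets for m in s.sorted_members()]
        conventional = MiRNASet("conventional_normalizers", members)
    report = run_pipeline_data(
        calls,
        levels,
        annotations,
        config=cfg,
        reference_sets=refs,
        conventional_normalizers=conventional,
        out_dir=out_dir,
    )
    report.provenance["input_checksums"] = checksums
    if out_dir is not None:
        report.to_json(Path(out_dir) / "report.json")
    return report
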