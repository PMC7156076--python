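"""Synthetic circulating-miRNome study generator.

Emulates the statistical structure the detection-score analysis assumes: a
platform of ~2578 miRNAs measured in paired plasma and extracellular-
vesicle samples from a small case/control cohort, with

* a large uniformly-undetected background mass,
* a variably-detected background mass (per-miRNA detection probability
  drawn from a U-shaped Beta(0.3, 0.3)),
* planted sets with exact detection scopes: case-exclusive signatures per
  compartment (partially overlapping between compartments), a
  control-exclusive set per compartment, an all-EV set, a universal
  low-variance housekeeping set and sex-linked sets.  A planted miRNA is
  guaranteed present throughout its defining scope and carries only a few
  sparse absences outside it — just enough to keep it out of every other
  shared set and (for signature members) to cover each opposite-group
  sample, so the conjunctive classifier discriminates perfectly while the
  per-group level means stay nearly identical,
* detection p-values strictly below alpha for present calls and strictly
  above for absent ones (binarization is exact unless noise is asked for),
* log2 detection levels ~ Normal(mu_m, sigma_m^2) when detected (mu_m ~
  Uniform(3, 11); housekeeping variance 0.1, background 4.0) and a
  near-floor Normal(1.2, 0.05^2) when undetected.

Presence/absence carries the case/control signal; detected-level means are
group-independent by default, so the differential stage is correctly
powerless on default scenarios while the signature stage discriminates
perfectly.  ``level_shift`` adds a case-group mean shift to the planted
signatures for testing the differential stage's power.

Every variably-detected background miRNA is forced absent in at least one
sample of each group x compartment cell and of each sex, so no background
row is uniformly present in any analysis scope and the planted sets are
exactly identifiable at zero noise (the Beta's mass at 1 would otherwise
leave hundreds of background rows present everywhere).

Randomness is a set of counter-based streams derived from one seed —
per-sample streams are keyed by global sample index, so enlarging a cohort
never perturbs the draws of earlier samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import binarize
from .model import (
    DetectionCallMatrix,
    DetectionLevelMatrix,
    DetectomeError,
    MiRNASet,
    SampleAnnotation,
    annotations_frame,
)
from . import studysets

# stream ids for the counter-based RNG substreams
_S_BETA, _S_BERNOULLI, _S_COVER, _S_NOISE, _S_PVAL, _S_MU, _S_LEVEL, _S_ABS = (
    10,
    20,
    30,
    40,
    50,
    60,
    70,
    15,
)

# Sex and age-in-months rosters for the default cohort (cycled beyond 12).
_CASE_SEX = "FMMMFFMMMMMF"
_CTRL_SEX = "FMMFFMMMMFFM"
_CASE_AGE = (26, 32, 29, 60, 37, 52, 19, 9, 12, 36, 33, 36)
_CTRL_AGE = (9, 52, 41, 28, 30, 71, 15, 22, 4, 17, 57, 67)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-shaped generator configuration.

    ``shared_case_control_ev`` is the size of the EV case∩control shared
    set *inclusive of the universal set* (which is necessarily detected in
    every EV sample); the generator plants ``shared_case_control_ev -
    universal`` additional all-EV miRNAs.  ``signature_overlap`` members
    belong to both compartment signatures.
    """

    n_mirnas: int = 2578
    cohorts: tuple[tuple[str, str, int], ...] = (
        ("case", "plasma", 12),
        ("control", "plasma", 11),
        ("case", "EV", 11),
        ("control", "EV", 10),
    )
    case_exclusive_plasma: int = 19
    control_exclusive_plasma: int = 4
    universal: int = 9
    case_exclusive_ev: int = 13
    shared_case_control_ev: int = 23
    control_exclusive_ev: int = 7
    female_exclusive: int = 5
    male_exclusive: int = 4
    signature_overlap: int = 7
    background_undetected_fraction: float = 0.55
    dropout_rate: float = 0.0  # false-absent rate on planted miRNAs
    false_present_rate: float = 0.0  # false-present rate on planted miRNAs
    alpha: float = 0.05
    mu_range: tuple[float, float] = (3.0, 11.0)
    background_sigma2: float = 4.0
    housekeeping_sigma2: float = 0.1
    undetected_mean: float = 1.2
    undetected_sigma: float = 0.05
    level_shift: float = 0.0
    seed: int = 7

    def planted_total(self) -> int:
        return (
            self.case_exclusive_plasma
            + self.control_exclusive_plasma
            + self.universal
            + (self.case_exclusive_ev - self.signature_overlap)
            + max(0, self.shared_case_control_ev - self.universal)
            + self.control_exclusive_ev
            + self.female_exclusive
            + self.male_exclusive
        )

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise DetectomeError("alpha must lie in (0, 1)")
        for rate in (self.dropout_rate, self.false_present_rate):
            if not 0 <= rate <= 1:
                raise DetectomeError("noise rates must lie in [0, 1]")
        if not 0 <= self.background_undetected_fraction <= 1:
            raise DetectomeError("background_undetected_fraction must lie in [0, 1]")
        if self.signature_overlap > min(
            self.case_exclusive_plasma, self.case_exclusive_ev
        ):
            raise DetectomeError("signature_overlap exceeds a planted signature size")
        if 0 < self.shared_case_control_ev < self.universal:
            raise DetectomeError(
                "shared_case_control_ev includes the universal set and cannot "
                "be smaller than it"
            )
        if self.planted_total() > self.n_mirnas:
            raise DetectomeError("planted sets exceed the miRNome size")
        groups = {(g, c) for g, c, _ in self.cohorts}
        if self.signature_overlap > 0 and not (
            ("case", "plasma") in groups and ("case", "EV") in groups
        ):
            raise DetectomeError(
                "signature_overlap needs case cohorts in both compartments"
            )


@dataclass
class TruthManifest:
    """Everything needed to reconstruct expected outputs at zero noise."""

    sets: dict[str, MiRNASet]
    mu: pd.Series
    sigma2: pd.Series
    seed: int
    config: ScenarioConfig

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "sets": {k: v.sorted_members() for k, v in self.sets.items()},
            "mu": self.mu.to_dict(),
            "sigma2": self.sigma2.to_dict(),
        }
        return json.dumps(payload, indent=2)


@dataclass
class SimulatedStudy:
    levels: DetectionLevelMatrix
    p_values: pd.DataFrame
    annotations: list[SampleAnnotation]
    truth: TruthManifest

    def calls(self, alpha: float | None = None) -> DetectionCallMatrix:
        a = alpha if alpha is not None else self.truth.config.alpha
        return binarize(self.p_values, a)


def _make_annotations(config: ScenarioConfig) -> list[SampleAnnotation]:
    out: list[SampleAnnotation] = []
    for group, compartment, n in config.cohorts:
        prefix = "P" if group == "case" else "C"
        sexes = _CASE_SEX if group == "case" else _CTRL_SEX
        ages = _CASE_AGE if group == "case" else _CTRL_AGE
        for i in range(n):
            out.append(
                SampleAnnotation(
                    sample_id=f"{prefix}{i + 1:02d}_{compartment}",
                    group=group,
                    compartment=compartment,
                    sex=sexes[i % len(sexes)],
                    age_months=float(ages[i % len(ages)]),
                )
            )
    return out


def generate(config: ScenarioConfig | None = None) -> SimulatedStudy:
    """Draw one synthetic study; bit-identical for identical config+seed."""
    config = config or ScenarioConfig()
    config.validate()
    seed = config.seed
    annotations = _make_annotations(config)
    ann = annotations_frame(annotations)
    samples = list(ann.index)
    n_samples = len(samples)

    roster = studysets.build_study_sets(
        n_plasma_case_exclusive=config.case_exclusive_plasma,
        n_control_exclusive_plasma=config.control_exclusive_plasma,
        n_universal=config.universal,
        n_ev_case_exclusive=config.case_exclusive_ev,
        n_ev_shared_both=max(config.shared_case_control_ev, config.universal),
        n_control_exclusive_ev=config.control_exclusive_ev,
        n_female_exclusive=config.female_exclusive,
        n_male_exclusive=config.male_exclusive,
        n_signature_overlap=config.signature_overlap,
        # the tumor core is a reference list, not planted in the matrices;
        # clamp its signature overlaps when the signatures shrink
        n_plasma_sig_in_core=min(14, config.case_exclusive_plasma),
        n_ev_sig_in_core=min(8, config.case_exclusive_ev),
    )

    is_case = (ann["group"] == "case").to_numpy()
    is_plasma = (ann["compartment"] == "plasma").to_numpy()
    is_ev = (ann["compartment"] == "EV").to_numpy()
    is_f = (ann["sex"] == "F").to_numpy()
    is_m = (ann["sex"] == "M").to_numpy()

    circ = sorted(roster["plasma_case_exclusive"].members & roster["ev_case_exclusive"].members)
    plasma_only = sorted(roster["plasma_case_exclusive"].members - set(circ))
    ev_only = sorted(roster["ev_case_exclusive"].members - set(circ))

    pc = is_case & is_plasma  # plasma cases
    pk = ~is_case & is_plasma  # plasma controls
    ec = is_case & is_ev
    ek = ~is_case & is_ev

    # (ids, guaranteed-present scope, cells needing >=1 absence per member)
    # Roles are present everywhere except sparse absences placed in the
    # listed cells; signature members additionally receive a cyclic
    # covering absence over their compartment's control samples so every
    # control lacks at least one member.
    def cells(*masks: np.ndarray) -> list[np.ndarray]:
        return [m for m in masks if m.any()]

    role_defs: list[tuple[list[str], np.ndarray, list[np.ndarray]]] = [
        (sorted(roster["universal"].members), np.ones(n_samples, bool), []),
        (circ, is_case & (is_plasma | is_ev), cells(is_f & ~is_case, is_m & ~is_case)),
        (plasma_only, pc, cells(ec, ek, is_f & ~pc, is_m & ~pc)),
        (
            sorted(roster["plasma_control_exclusive"].members),
            pk,
            cells(pc, ec, ek, is_f & ~pk, is_m & ~pk),
        ),
        (ev_only, ec, cells(pc, pk, is_f & ~ec, is_m & ~ec)),
        (
            sorted(roster["ev_shared_extra"].members),
            is_ev,
            cells(pc, pk, is_f & is_plasma, is_m & is_plasma),
        ),
        (
            sorted(roster["ev_control_exclusive"].members),
            ek,
            cells(ec, pc, pk, is_f & ~ek, is_m & ~ek),
        ),
        (sorted(roster["female_exclusive"].members), is_f, cells(is_m & pc, is_m & pk, is_m & ec, is_m & ek)),
        (sorted(roster["male_exclusive"].members), is_m, cells(is_f & pc, is_f & pk, is_f & ec, is_f & ek)),
    ]
    universal_ids_list = role_defs[0][0]
    for ids, scope, hit_cells in role_defs:
        if ids and not scope.any():
            raise DetectomeError(
                f"infeasible config: planted set {ids[0]!r}... has an empty "
                "presence scope under the given cohorts"
            )
        if ids and ids != universal_ids_list and not hit_cells:
            raise DetectomeError(
                "infeasible config: an exclusive planted set has no sample "
                "outside its scope to be absent in"
            )

    planted_ids = [m for ids, _, _ in role_defs for m in ids]
    n_planted = len(planted_ids)
    n_background = config.n_mirnas - n_planted
    background_ids = [f"bg-miR-{i:04d}" for i in range(1, n_background + 1)]
    mirna_ids = planted_ids + background_ids

    present = np.zeros((config.n_mirnas, n_samples), dtype=bool)
    rng_abs = np.random.default_rng([seed, _S_ABS])
    row = 0
    planted_rows: dict[str, int] = {}
    for ids, scope, hit_cells in role_defs:
        for m in ids:
            present[row] = True
            for cell in hit_cells:
                idx = np.flatnonzero(cell & ~scope)
                if idx.size:
                    present[row, rng_abs.choice(idx)] = False
            present[row] |= scope  # scope presence is guaranteed
            planted_rows[m] = row
            row += 1

    # Cyclic covering: every control sample of a compartment misses at
    # least one member of that compartment's case-exclusive signature.
    for sig_ids, ctrl_mask in (
        (plasma_only + circ, pk),
        (ev_only + circ, ek),
    ):
        ctrl_idx = np.flatnonzero(ctrl_mask)
        if ctrl_idx.size == 0 or not sig_ids:
            continue
        if len(sig_ids) < ctrl_idx.size:
            raise DetectomeError(
                "infeasible config: fewer signature members than opposite-"
                "group samples; the conjunctive classifier cannot cover "
                "every control"
            )
        for i, m in enumerate(sorted(sig_ids)):
            present[planted_rows[m], ctrl_idx[i % ctrl_idx.size]] = False

    # Background: a hard uniformly-undetected block, then Beta-Bernoulli
    # variable rows with covering forced absences.
    n_undet = int(round(config.background_undetected_fraction * n_background))
    n_var = n_background - n_undet
    var_rows = np.arange(n_planted + n_undet, config.n_mirnas)
    if n_var > 0:
        rng_beta = np.random.default_rng([seed, _S_BETA])
        p_bg = rng_beta.beta(0.3, 0.3, size=n_var)
        for j in range(n_samples):
            rng_j = np.random.default_rng([seed, _S_BERNOULLI, j])
            present[var_rows, j] = rng_j.random(n_var) < p_bg
        rng_cover = np.random.default_rng([seed, _S_COVER])
        cover_masks = [
            is_case & is_plasma,
            ~is_case & is_plasma,
            is_case & is_ev,
            ~is_case & is_ev,
            is_f,
            is_m,
        ]
        for mask in cover_masks:
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            chosen = idx[rng_cover.integers(idx.size, size=n_var)]
            present[var_rows, chosen] = False

    # Optional call noise on planted rows.
    if config.dropout_rate > 0 or config.false_present_rate > 0:
        rng_noise = np.random.default_rng([seed, _S_NOISE])
        rows = np.arange(n_planted)
        block = present[rows]
        u = rng_noise.random(block.shape)
        flip_down = block & (u < config.dropout_rate)
        flip_up = ~block & (u < config.false_present_rate)
        present[rows] = (block & ~flip_down) | flip_up

    # Detection p-values: strictly below alpha when present, above when not.
    a = config.alpha
    p_values = np.empty((config.n_mirnas, n_samples))
    for j in range(n_samples):
        rng_j = np.random.default_rng([seed, _S_PVAL, j])
        u = rng_j.random(config.n_mirnas)
        p_values[:, j] = np.where(
            present[:, j], u * (0.9 * a), 1.1 * a + u * (1.0 - 1.1 * a)
        )

    # Detection levels.
    rng_mu = np.random.default_rng([seed, _S_MU])
    lo, hi = config.mu_range
    mu = rng_mu.uniform(lo, hi, size=config.n_mirnas)
    sigma2 = np.full(config.n_mirnas, config.background_sigma2)
    for m in roster["universal"].members:
        sigma2[planted_rows[m]] = config.housekeeping_sigma2
    sigma = np.sqrt(sigma2)

    shift = np.zeros(config.n_mirnas)
    if config.level_shift:
        for m in roster["plasma_case_exclusive"].members | roster["ev_case_exclusive"].members:
            shift[planted_rows[m]] = config.level_shift

    levels = np.empty((config.n_mirnas, n_samples))
    for j in range(n_samples):
        rng_j = np.random.default_rng([seed, _S_LEVEL, j])
        z = rng_j.standard_normal(config.n_mirnas)
        detected = mu + (shift if is_case[j] else 0.0) + sigma * z
        undetected = config.undetected_mean + config.undetected_sigma * z
        levels[:, j] = np.where(present[:, j], detected, undetected)

    idx = pd.Index(mirna_ids, name="mirna_id")
    truth_sets = dict(roster)
    truth_sets["background_variable"] = MiRNASet(
        "background_variable", [mirna_ids[r] for r in var_rows]
    )
    truth_sets["background_undetected"] = MiRNASet(
        "background_undetected",
        mirna_ids[n_planted : n_planted + n_undet],
    )
    truth = TruthManifest(
        sets=truth_sets,
        mu=pd.Series(mu, index=idx, name="mu"),
        sigma2=pd.Series(sigma2, index=idx, name="sigma2"),
        seed=seed,
        config=config,
    )
    return SimulatedStudy(
        levels=DetectionLevelMatrix(pd.DataFrame(levels, index=idx, columns=samples)),
        p_values=pd.DataFrame(p_values, index=idx, columns=samples),
        annotations=annotations,
        truth=truth,
    )


def degrade(
    calls: DetectionCallMatrix, dropout: float, false_present: float, seed: int
) -> DetectionCallMatrix:
    """Flip calls independently: present -> absent with probability
    ``dropout``, absent -> present with probability ``false_present``."""
    for rate in (dropout, false_present):
        if not 0 <= rate <= 1:
            raise DetectomeError("noise rates must lie in [0, 1]")
    rng = np.random.default_rng([seed, 99])
    m = calls.calls.to_numpy(bool)
    u = rng.random(m.shape)
    out = np.where(m, u >= dropout, u < false_present)
    return DetectionCallMatrix(
        calls=pd.DataFrame(out, index=calls.calls.index, columns=calls.calls.columns),
        provenance={
            **calls.provenance,
            "degraded": {"dropout": dropout, "false_present": false_present, "seed": seed},
        },
    )


def write_study(study: SimulatedStudy, out_dir) -> dict[str, Path]:
    """Write levels.tsv, pvalues.tsv, annotations.tsv, truth.gmt, truth.json."""
    from . import io as dio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "levels": out / "levels.tsv",
        "pvalues": out / "pvalues.tsv",
        "annotations": out / "annotations.tsv",
        "truth_gmt": out / "truth.gmt",
        "truth_json": out / "truth.json",
    }
    dio.write_matrix(study.levels.levels, paths["levels"])
    dio.write_matrix(study.p_values, paths["pvalues"])
    dio.write_annotations(study.annotations, paths["annotations"])
    dio.write_gene_sets(list(study.truth.sets.values()), paths["truth_gmt"], "planted")
    paths["truth_json"].write_text(study.truth.to_json() + "\n")
    return paths
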