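"""Synthetic stand-in gene sets with the published circulating-miRNome
cluster structure.

The retinoblastoma plasma/EV study reports its shared-detection clusters
only as counts plus supplementary spreadsheets: plasma case-shared 28 and
control-shared 13 (Venn 19 / 9 / 4), EV case-shared 36 and control-shared
30 (Venn 13 / 23 / 7), a 7-miRNA overlap between the two signatures, a
142-miRNA tumor core containing 14 of the plasma signature and 8 of the EV
signature, and sex-shared sets of 14 (F) and 13 (M) with 5 / 4 exclusives
around the 9 universal miRNAs.  This module constructs member lists that
realize exactly that overlap structure so the set-algebra pipeline can be
exercised end to end.

All member ids are SYNTHETIC (``syn-miR-*``) except the nine universally
detected miRNAs, whose published names are used because they are printed
in the study's normalizer table.  The same roster seeds the simulator's
planted sets, so recovered signatures carry these ids.
"""

from __future__ import annotations

from .model import MiRNASet
from .signature import venn_partition

#: The nine miRNAs detected in every plasma and EV sample (published names).
UNIVERSAL_MIRNAS: tuple[str, ...] = (
    "hsa-miR-5787",
    "hsa-miR-638",
    "hsa-miR-6732-5p",
    "hsa-miR-6803-5p",
    "hsa-miR-8075",
    "hsa-miR-877-5p",
    "hsa-miR-4787-5p",
    "hsa-miR-4487",
    "hsa-miR-6750-5p",
)

#: Conventional qRT-PCR blood normalizers used as the comparison panel.
CONVENTIONAL_NORMALIZERS: tuple[str, ...] = (
    "hsa-miR-21-5p",
    "hsa-miR-21-3p",
    "hsa-miR-16-5p",
    "hsa-miR-16-1-3p",
)


def _ids(prefix: str, n: int) -> list[str]:
    return [f"syn-miR-{prefix}-{i:03d}" for i in range(1, n + 1)]


def universal_ids(n: int) -> list[str]:
    """Universal-set ids: published names first, synthetic beyond nine."""
    names = list(UNIVERSAL_MIRNAS[:n])
    if n > len(UNIVERSAL_MIRNAS):
        names += _ids("UNI", n - len(UNIVERSAL_MIRNAS))
    return names


def build_study_sets(
    n_plasma_case_exclusive: int = 19,
    n_control_exclusive_plasma: int = 4,
    n_universal: int = 9,
    n_ev_case_exclusive: int = 13,
    n_ev_shared_both: int = 23,
    n_control_exclusive_ev: int = 7,
    n_female_exclusive: int = 5,
    n_male_exclusive: int = 4,
    n_signature_overlap: int = 7,
    n_tumor_core: int = 142,
    n_plasma_sig_in_core: int = 14,
    n_ev_sig_in_core: int = 8,
) -> dict[str, MiRNASet]:
    """Construct the full roster of named sets with the stated cardinalities.

    Raises ValueError if the requested sizes are mutually infeasible.
    """
    if n_signature_overlap > min(n_plasma_case_exclusive, n_ev_case_exclusive):
        raise ValueError("signature overlap exceeds a signature size")
    if n_ev_shared_both < n_universal:
        raise ValueError("EV case∩control shared set must contain the universal set")
    if n_plasma_sig_in_core > n_plasma_case_exclusive or n_ev_sig_in_core > n_ev_case_exclusive:
        raise ValueError("in-core overlap exceeds signature size")
    # overlap miRNAs in core: shared between the two in-core intersections
    n_core_from_circ = max(
        0,
        n_plasma_sig_in_core
        - (n_plasma_case_exclusive - n_signature_overlap),
        n_ev_sig_in_core - (n_ev_case_exclusive - n_signature_overlap),
    )
    if n_core_from_circ > n_signature_overlap:
        raise ValueError("tumor-core overlaps incompatible with signature overlap")

    circ = _ids("CIRC", n_signature_overlap)  # in both signatures
    plasma_only = _ids("RbP", n_plasma_case_exclusive - n_signature_overlap)
    ev_only = _ids("RbEV", n_ev_case_exclusive - n_signature_overlap)
    universal = universal_ids(n_universal)
    ctrl_plasma = _ids("CTP", n_control_exclusive_plasma)
    ev_extra = _ids("EVALL", n_ev_shared_both - n_universal)
    ctrl_ev = _ids("CTEV", n_control_exclusive_ev)
    female = _ids("F", n_female_exclusive)
    male = _ids("M", n_male_exclusive)

    # Tumor core: take what is needed from each signature (preferring the
    # signature-specific blocks, topping up from the 7 shared circulating
    # ids), then synthetic tumor-only filler.
    core_from_plasma = plasma_only[: min(len(plasma_only), n_plasma_sig_in_core)]
    core_from_ev = ev_only[: min(len(ev_only), n_ev_sig_in_core)]
    core_circ = circ[:n_core_from_circ]
    need_p = n_plasma_sig_in_core - len(core_from_plasma)
    need_e = n_ev_sig_in_core - len(core_from_ev)
    if max(need_p, need_e) > len(core_circ):
        core_circ = circ[: max(need_p, need_e)]
    core_members = list(dict.fromkeys(core_from_plasma + core_from_ev + core_circ))
    filler = _ids("TUM", n_tumor_core - len(core_members))
    core_members += filler

    plasma_sig = plasma_only + circ
    ev_sig = ev_only + circ
    sets = {
        "universal": MiRNASet("universal", universal),
        "plasma_case_exclusive": MiRNASet("plasma_case_exclusive", plasma_sig),
        "plasma_control_exclusive": MiRNASet("plasma_control_exclusive", ctrl_plasma),
        "ev_case_exclusive": MiRNASet("ev_case_exclusive", ev_sig),
        "ev_shared_extra": MiRNASet("ev_shared_extra", ev_extra),
        "ev_control_exclusive": MiRNASet("ev_control_exclusive", ctrl_ev),
        "female_exclusive": MiRNASet("female_exclusive", female),
        "male_exclusive": MiRNASet("male_exclusive", male),
        "tumor_core": MiRNASet("tumor_core", core_members),
        # composites as the detection analysis would see them
        "plasma_case_shared": MiRNASet("plasma_case_shared", universal + plasma_sig),
        "plasma_control_shared": MiRNASet(
            "plasma_control_shared", universal + ctrl_plasma
        ),
        "ev_case_shared": MiRNASet("ev_case_shared", universal + ev_extra + ev_sig),
        "ev_control_shared": MiRNASet(
            "ev_control_shared", universal + ev_extra + ctrl_ev
        ),
        "female_shared": MiRNASet("female_shared", universal + female),
        "male_shared": MiRNASet("male_shared", universal + male),
    }
    return sets


def study_set_sizes(sets: dict[str, MiRNASet]) -> dict[str, int]:
    """Summary of the Venn arithmetic over the constructed sets."""
    plasma = venn_partition(sets["plasma_case_shared"], sets["plasma_control_shared"])
    ev = venn_partition(sets["ev_case_shared"], sets["ev_control_shared"])
    sig_overlap = venn_partition(
        sets["plasma_case_exclusive"], sets["ev_case_exclusive"]
    )
    sex = venn_partition(sets["female_shared"], sets["male_shared"])
    core_p = venn_partition(sets["plasma_case_exclusive"], sets["tumor_core"])
    core_e = venn_partition(sets["ev_case_exclusive"], sets["tumor_core"])
    return {
        "plasma_venn": plasma.sizes(),
        "ev_venn": ev.sizes(),
        "signature_overlap": len(sig_overlap.shared),
        "sex_venn": sex.sizes(),
        "plasma_sig_in_core": len(core_p.shared),
        "ev_sig_in_core": len(core_e.shared),
    }
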