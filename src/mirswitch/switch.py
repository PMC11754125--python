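"""Switching behaviour of assembled designs.

The OFF state is the equilibrium ensemble of the full guide: a good design
sequesters the spacer (high pairing probability over every spacer position)
while keeping the scaffold's essential stems intact.  The ON state is
modelled as AGO-miRNA occupancy of the binding site, i.e. a re-fold with
every binding-site position forced unpaired; an explicit AGO energy model
is deliberately out of scope, so this proxy is the computable surrogate for
the miRNA-induced conformational change.  Additional diagnostics:

* seed-invasion cost - the ensemble free-energy price of opening the
  binding-site residues that match the miRNA seed (AGO initiates binding
  through the seed, so a cheaper opening means easier activation);
* a two-state strand-displacement check - whether free miRNA alone could
  displace the shield (a well-designed trigger hairpin is stable enough
  that it cannot; activation requires AGO);
* pathway robustness - whether the equilibrium and cotranscriptional
  (distance-rescaled) predictions coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Optional

from .core import DesignConstraints, DesignError, Interval, MiRGuideDesign, MiRNA
from .grammar import build_binding_site
from . import thermo
from .thermo import CofoldParams, EnergyModelParams

#: Probability above which a position counts as "paired" (configurable).
PAIRED_THRESHOLD = 0.5


@dataclass
class SwitchReport:
    """All computed switching diagnostics for one design."""

    design_name: str = ""
    architecture: str = ""
    off_spacer_paired_fraction: Optional[float] = None
    on_spacer_accessible_fraction: Optional[float] = None
    off_spacer_accessible_fraction: Optional[float] = None
    on_gain: Optional[float] = None
    seed_invasion_cost: Optional[float] = None
    displacement_dg: Optional[float] = None
    displacement_favorable: Optional[bool] = None
    pathway_robust: Optional[bool] = None
    trigger_dg: Optional[float] = None
    seed_duplex_run: Optional[int] = None
    stem_pair_probabilities: dict = field(default_factory=dict)
    scaffold_stem_probabilities: dict = field(default_factory=dict)
    parameter_table: str = thermo.PARAMETER_TABLE_ID
    paired_threshold: float = PAIRED_THRESHOLD

    def is_complete(self) -> bool:
        needed = (
            self.off_spacer_paired_fraction,
            self.on_spacer_accessible_fraction,
            self.trigger_dg,
            self.displacement_favorable,
            self.pathway_robust,
        )
        return all(v is not None for v in needed)


def _blocked_interval(design: MiRGuideDesign) -> Interval:
    iv = design.component(design.blocked_element)
    if iv is None:
        raise DesignError(f"design has no {design.blocked_element!r} component")
    return iv


def trigger_hairpin_dg(design: MiRGuideDesign, params: Optional[EnergyModelParams] = None) -> float:
    """MFE free energy of the trigger-hairpin region folded in isolation."""
    iv = design.trigger_hairpin_interval
    sub = design.full_sequence.subseq(iv.start, iv.end)
    return thermo.fold_mfe(sub, params).delta_g


def _site_full_positions(design: MiRGuideDesign, mirna_positions: Optional[set[int]] = None) -> list[int]:
    """Full-sequence positions of binding-site residues, optionally only
    those matching the given miRNA positions (the loop of a full-length
    design holds the distal site residues and is included)."""
    if design.binding_site_spec is None or design.mirna is None:
        return []
    site = build_binding_site(design.mirna, design.binding_site_spec)
    site_iv = design.component("binding_site")
    loop_iv = design.component("loop")
    n_site = len(site.sequence)
    # site positions are laid out loop-first for full-length standard
    # architectures; for every architecture the binding_site component holds
    # the covered (3') part of the site and, for full-length 5' designs, the
    # loop holds the distal part.
    covered = sorted(design.binding_site_spec.resolved_covered(design.mirna))
    covered_site_positions = sorted(
        s for s, m in site.pairing_map.items() if m in covered
    )
    full_positions: dict[int, int] = {}  # site position -> full position
    if design.architecture in ("full_length_5prime_hairpin", "split_and_gate_unit", "seed_only"):
        if design.architecture == "seed_only":
            for rank, s in enumerate(covered_site_positions):
                full_positions[s] = site_iv.start + rank
        else:
            distal = sorted(set(site.pairing_map) - set(covered_site_positions))
            for rank, s in enumerate(distal):
                full_positions[s] = loop_iv.start + rank
            for rank, s in enumerate(covered_site_positions):
                full_positions[s] = site_iv.start + rank
    elif design.architecture == "tetraloop_shield":
        for rank in range(n_site):
            full_positions[rank + 1] = site_iv.start + rank
    else:
        return []
    if mirna_positions is None:
        return sorted(full_positions.values())
    return sorted(
        fp for s, fp in full_positions.items() if site.pairing_map[s] in mirna_positions
    )


def off_state_report(
    design: MiRGuideDesign,
    params: Optional[EnergyModelParams] = None,
    report: Optional[SwitchReport] = None,
) -> SwitchReport:
    """Equilibrium (OFF-state) diagnostics for the full guide."""
    params = params or EnergyModelParams()
    report = report or SwitchReport(design.full_sequence.name, design.architecture)
    pf = thermo.partition_function(design.full_sequence, params)
    probs = pf.probabilities
    blocked = _blocked_interval(design)
    paired = [probs.paired_probability(i) >= report.paired_threshold for i in blocked.positions()]
    report.off_spacer_paired_fraction = sum(paired) / len(paired)
    report.off_spacer_accessible_fraction = 1.0 - report.off_spacer_paired_fraction
    report.stem_pair_probabilities = {
        (i, j): probs.p(i, j) for (i, j) in design.designed_pairs
    }
    # scaffold stems: mean paired probability over each annotated stem region
    scaf_iv = design.component("scaffold")
    if scaf_iv is not None and design.scaffold is not None:
        off = scaf_iv.start - 1
        for name in ("repeat_antirepeat_duplex", "stem_loop_1", "stem_loop_2", "stem_loop_3"):
            ann = design.scaffold.annotations.get(name)
            if ann is None or off + ann.end > len(design.full_sequence):
                continue
            vals = [probs.paired_probability(off + p) for p in ann.positions()]
            report.scaffold_stem_probabilities[name] = sum(vals) / len(vals)
    report.trigger_dg = trigger_hairpin_dg(design, params)
    report.seed_duplex_run = longest_seed_duplex_run(design, params)
    return report


def on_state_proxy(
    design: MiRGuideDesign,
    mirna: MiRNA,
    params: Optional[EnergyModelParams] = None,
    report: Optional[SwitchReport] = None,
) -> SwitchReport:
    """ON-state proxy: re-fold with the binding site forced unpaired.

    Refuses a non-cognate miRNA: specificity is sequence-level, so the
    trigger stored in the design must match the miRNA offered.
    """
    params = params or EnergyModelParams()
    report = report or SwitchReport(design.full_sequence.name, design.architecture)
    if design.mirna is not None and design.mirna.sequence.residues != mirna.sequence.residues:
        raise DesignError(
            f"non-cognate trigger: design senses {design.mirna.name or 'its own miRNA'}, "
            f"got {mirna.name or mirna.sequence.residues}"
        )
    site_positions = _site_full_positions(design)
    constraints = {p: "unpaired" for p in site_positions}
    pf = thermo.partition_function(design.full_sequence, params, constraints or None)
    probs = pf.probabilities
    blocked = _blocked_interval(design)
    accessible = [
        probs.paired_probability(i) < report.paired_threshold for i in blocked.positions()
    ]
    report.on_spacer_accessible_fraction = sum(accessible) / len(accessible)
    if report.off_spacer_accessible_fraction is None:
        off_state_report(design, params, report)
    report.on_gain = (
        report.on_spacer_accessible_fraction - report.off_spacer_accessible_fraction
    )
    return report


def seed_invasion_cost(design: MiRGuideDesign, params: Optional[EnergyModelParams] = None) -> float:
    """Ensemble free-energy cost of opening the seed-matching site residues.

    Non-negative by construction (a constrained ensemble cannot beat the
    unconstrained one); lower cost means easier AGO seed invasion.
    """
    params = params or EnergyModelParams()
    if design.mirna is None or design.binding_site_spec is None:
        return 0.0
    seed_positions = set(design.mirna.seed_region.positions())
    positions = _site_full_positions(design, seed_positions)
    if not positions:
        return 0.0
    g0 = thermo.ensemble_free_energy(design.full_sequence, params)
    g1 = thermo.ensemble_free_energy(
        design.full_sequence, params, {p: "unpaired" for p in positions}
    )
    return max(0.0, g1 - g0)


#: Assumed concentration of AGO-free trigger miRNA (mol/L).  Most cellular
#: miRNA is RISC-loaded; the free fraction available for protein-free strand
#: displacement is tiny, and the bimolecular association penalty
#: RT ln(1 M / c) is what makes displacement of a well-designed trigger
#: hairpin unfavorable without AGO.
FREE_MIRNA_CONCENTRATION = 1e-12


def strand_displacement_check(
    design: MiRGuideDesign,
    mirna: MiRNA,
    params: Optional[EnergyModelParams] = None,
    free_mirna_concentration: float = FREE_MIRNA_CONCENTRATION,
) -> tuple[float, bool]:
    """Two-state test: can free miRNA displace the shield without AGO?

    intact    = MFE(guide) + MFE(free miRNA)
    displaced = duplex(miRNA :: binding site, with the site's mismatches)
                + MFE(guide | site unpaired)
                + RT ln(1 M / c)   (association at free-miRNA concentration c)

    Returns (displacement_dg, favorable) with displacement_dg =
    E(displaced) - E(intact); favorable iff negative.
    """
    params = params or EnergyModelParams()
    if design.mirna is not None and design.mirna.sequence.residues != mirna.sequence.residues:
        raise DesignError("non-cognate trigger for displacement check")
    site = build_binding_site(mirna, design.binding_site_spec)
    intact = thermo.fold_mfe(design.full_sequence, params).delta_g
    intact += thermo.fold_mfe(mirna.sequence, params).delta_g
    site_positions = _site_full_positions(design)
    displaced = thermo.duplex_energy(site.sequence, mirna.sequence, params)
    displaced += thermo.constrained_fold(
        design.full_sequence, params, {p: "unpaired" for p in site_positions}
    ).delta_g
    displaced += params.rt * math.log(1.0 / free_mirna_concentration)
    dg = displaced - intact
    return dg, dg < 0.0


def pathway_robustness(
    design: MiRGuideDesign,
    params: Optional[EnergyModelParams] = None,
    cofold_params: Optional[CofoldParams] = None,
) -> bool:
    """True iff equilibrium and cotranscriptional MFE dot-brackets coincide."""
    params = params or EnergyModelParams()
    cofold_params = cofold_params or CofoldParams()
    eq = thermo.fold_mfe(design.full_sequence, params)
    co = thermo.cofold_mfe(design.full_sequence, params, cofold_params)
    return eq.dot_bracket == co.dot_bracket


def longest_seed_duplex_run(
    design: MiRGuideDesign, params: Optional[EnergyModelParams] = None
) -> int:
    """Longest continuous duplex over the spacer-seed region in the MFE fold.

    Counts consecutive spacer-seed positions that are paired with
    consecutive (helical) partners.  Designs without a spacer return 0.
    """
    if design.component("spacer") is None:
        return 0
    params = params or EnergyModelParams()
    iv = design.trigger_hairpin_interval
    sub = design.full_sequence.subseq(iv.start, iv.end)
    partner = thermo.fold_mfe(sub, params).partner()
    offset = iv.start - 1
    seed_positions = sorted(design.spacer_seed_positions())
    best = run = 0
    prev_partner = None
    for p in seed_positions:
        local = p - offset
        q = partner.get(local)
        if q is None:
            run = 0
        elif prev_partner is not None and run > 0 and q == prev_partner - 1:
            run += 1
        else:
            run = 1
        prev_partner = q
        best = max(best, run)
    return best


def full_report(
    design: MiRGuideDesign,
    params: Optional[EnergyModelParams] = None,
    cofold_params: Optional[CofoldParams] = None,
) -> SwitchReport:
    """Compute every diagnostic for a design against its own trigger."""
    params = params or EnergyModelParams()
    report = SwitchReport(design.full_sequence.name, design.architecture)
    off_state_report(design, params, report)
    if design.mirna is not None and design.binding_site_spec is not None:
        on_state_proxy(design, design.mirna, params, report)
        report.seed_invasion_cost = seed_invasion_cost(design, params)
        dg, fav = strand_displacement_check(design, design.mirna, params)
        report.displacement_dg = dg
        report.displacement_favorable = fav
    else:
        report.on_spacer_accessible_fraction = report.off_spacer_accessible_fraction
        report.on_gain = 0.0
        report.seed_invasion_cost = 0.0
        report.displacement_dg = 0.0
        report.displacement_favorable = False
    report.pathway_robust = pathway_robustness(design, params, cofold_params)
    return report


@dataclass(frozen=True)
class ScoreThresholds:
    """Pass/fail thresholds for the composite switch score.

    The OFF threshold accounts for the metric's ceiling: spacer positions
    carrying designed mismatches cannot pair their partner, so a fully
    as-designed OFF state with up to ~5 spacer mismatches on a 17-nt
    spacer still tops out near 0.7.
    """

    min_off_paired_fraction: float = 0.7
    min_on_gain: float = 0.02
    pair_probability_band: float = 0.05


def switch_score(
    report: SwitchReport,
    constraints: Optional[DesignConstraints] = None,
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> tuple[float, dict[str, bool]]:
    """Deterministic aggregate score with per-criterion pass flags.

    Criteria: OFF sequestration above threshold; ON gain above threshold;
    trigger free energy inside the design window (too-stable hairpins fail
    as "over-stable"); designed-pair probabilities near the target; the
    spacer-seed duplex not exceeding the allowed run ("seed over-blocked");
    displacement unfavorable; folding-pathway robustness.
    """
    constraints = constraints or DesignConstraints()
    if not report.is_complete():
        raise ValueError("incomplete switch report")
    lo, hi = constraints.target_dg_window
    checks = {
        "off_sequestered": report.off_spacer_paired_fraction >= thresholds.min_off_paired_fraction,
        "on_gain": report.on_gain is not None and report.on_gain >= thresholds.min_on_gain,
        "dg_in_window": lo <= report.trigger_dg <= hi,
        "over_stable": report.trigger_dg >= lo,  # False means over-stable failure
        "pair_probabilities": bool(report.stem_pair_probabilities)
        and abs(
            median(report.stem_pair_probabilities.values())
            - constraints.per_pair_probability_target
        )
        <= thresholds.pair_probability_band,
        "seed_not_over_blocked": (report.seed_duplex_run or 0) <= constraints.max_seed_duplex_run,
        "displacement_unfavorable": not report.displacement_favorable,
        "pathway_robust": bool(report.pathway_robust),
    }
    med = (
        median(report.stem_pair_probabilities.values())
        if report.stem_pair_probabilities
        else 0.0
    )
    centre = constraints.dg_window_center
    score = (
        report.off_spacer_paired_fraction
        + max(0.0, report.on_gain or 0.0)
        + max(0.0, 1.0 - abs(med - constraints.per_pair_probability_target) / 0.25)
        + max(0.0, 1.0 - abs(report.trigger_dg - centre) / 10.0)
        + 0.5 * checks["displacement_unfavorable"]
        + 0.5 * checks["pathway_robust"]
    )
    return score, checks


def score_passes(checks: dict[str, bool]) -> bool:
    return all(checks.values())
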