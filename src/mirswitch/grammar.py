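"""Assembly of miRNA-sensing switchable guide architectures.

A switchable guide places a miRNA-binding site immediately upstream of the
Cas9 guide (spacer) sequence and completes a "trigger" hairpin with a
shield sequence that is partially complementary to the binding site, the
spacer and the first G of the scaffold repeat.  In the OFF state the
hairpin sequesters the spacer; AGO-mediated binding of the trigger miRNA
to the binding site destabilizes the hairpin and releases the spacer.

Four architectures are assembled here:

``full_length_5prime_hairpin``
    shield - loop (binding-site residues matching miRNA positions > 16) -
    proximal binding site - spacer - scaffold.  The shield reaches no
    further than miRNA position 16.
``seed_only``
    the binding site covers only the miRNA seed; shield and site are
    joined by a GAAA tetraloop.
``tetraloop_shield``
    binding site and shield replace the scaffold's stem-loop-1 tetraloop;
    the shield sequesters the spacer seed by long-range pairing.
``split_and_gate_unit``
    two units: a crRNA half whose hairpin blocks the spacer (miRNA A) and
    a tracrRNA half whose hairpin blocks the antirepeat (miRNA B).

Two distinct mismatch sets exist: binding-site-vs-miRNA mismatches (for
example the {2, 9, 17} preset, or {10, 11} which ablates AGO cleavage)
control AGO turnover, while shield mismatches (a ``MismatchPattern``)
tune the free energy of the trigger hairpin itself.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import yaml

from .core import (
    BindingSiteSpec,
    complement_base,
    DesignConstraints,
    DesignError,
    Interval,
    MiRGuideDesign,
    MiRNA,
    MismatchPattern,
    RnaSequence,
    Scaffold,
    SpacerGuide,
    SplitGuidePair,
    inject_mismatch,
    mismatch_base,
    reverse_complement,
    validate_design,
)

# Binding-site-vs-miRNA mismatch presets (numbered by miRNA position).
PRESET_ACTIVE = frozenset({2, 9, 17})  # the editing-competent preset
PRESET_AGO_CLEAVAGE_ABLATED = frozenset({10, 11})  # AGO binds but cannot cleave

#: Default shield mismatch pattern: mismatches roughly every 3-4 stem
#: positions, leaving a 6-bp continuous duplex over the spacer seed.
DEFAULT_SHIELD_PATTERN = MismatchPattern(
    positions_in_binding_site=frozenset({3, 6, 10, 14}),
    positions_in_shield_vs_spacer=frozenset({7, 11, 15}),
)

SEED_TETRALOOP = "GAAA"


# --------------------------------------------------------------------------
# Scaffold and catalogue data
# --------------------------------------------------------------------------


@lru_cache(maxsize=None)
def load_scaffold(variant: str = "optimized") -> Scaffold:
    """Load a bundled scaffold ("standard" or "optimized") with annotations."""
    text = (
        importlib.resources.files("mirswitch.data").joinpath("scaffolds.yaml").read_text()
    )
    data = yaml.safe_load(text)
    try:
        entry = data["scaffolds"][variant]
    except KeyError as exc:
        raise DesignError(f"unknown scaffold variant {variant!r}") from exc
    annotations = {
        name: Interval(int(lo), int(hi)) for name, (lo, hi) in entry["annotations"].items()
    }
    return Scaffold(variant, RnaSequence(entry["sequence"], f"scaffold-{variant}"), annotations)


# --------------------------------------------------------------------------
# Binding site and shield
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingSite:
    """A built miRNA-binding site with its site-position -> miRNA-position map."""

    sequence: RnaSequence
    pairing_map: dict[int, int]  # site position -> matched miRNA position
    spec: BindingSiteSpec
    mirna: MiRNA

    def site_position_for(self, mirna_position: int) -> int:
        for s, m in self.pairing_map.items():
            if m == mirna_position:
                return s
        raise KeyError(f"miRNA position {mirna_position} not covered by site")


def build_binding_site(mirna: MiRNA, spec: BindingSiteSpec) -> BindingSite:
    """Reverse-complement binding site for a trigger miRNA.

    ``full_length`` returns the reverse complement of the whole miRNA;
    ``seed_only`` of the seed region only.  Declared mismatches (numbered by
    miRNA position) are injected so the site residue can no longer pair the
    miRNA residue it faces.
    """
    L = len(mirna)
    if spec.mode == "full_length":
        site = reverse_complement(mirna.sequence)
        pairing = {s: L + 1 - s for s in range(1, L + 1)}
    else:
        lo, hi = mirna.seed_region.start, mirna.seed_region.end
        outside = [m for m in spec.mismatch_positions if not lo <= m <= hi]
        if outside:
            raise DesignError(
                f"seed_only site cannot carry mismatches at miRNA positions {sorted(outside)}"
            )
        site = reverse_complement(mirna.seed_sequence())
        pairing = {s: hi + 1 - s for s in range(1, hi - lo + 2)}
    for m in sorted(spec.mismatch_positions):
        if not 1 <= m <= L:
            raise DesignError(f"mismatch position {m} outside miRNA")
        s = next(sp for sp, mp in pairing.items() if mp == m)
        site = inject_mismatch(site, s, mirna.sequence[m])
    return BindingSite(RnaSequence(site.residues, f"site({mirna.name})"), pairing, spec, mirna)


def _stem_target(
    site: BindingSite,
    covered: list[int],
    arm: str,
) -> str:
    """The 5'->3' strand the shield is designed against (X).

    X = [perfect miRNA-complement residues for the covered positions, in
    site order] + [arm residues 5'->3'] (+ the first repeat G appended by
    the caller).  The shield is designed against the PERFECT site: a
    binding-site mutation is one physical nucleotide edit, so it mismatches
    both the miRNA in trans and the shield within the hairpin.
    """
    covered_desc = sorted(covered, reverse=True)
    x = "".join(complement_base(site.mirna.sequence[m]) for m in covered_desc)
    x += arm
    return x


def build_shield(
    site: BindingSite,
    spacer: SpacerGuide,
    scaffold: Scaffold,
    pattern: MismatchPattern = DEFAULT_SHIELD_PATTERN,
) -> RnaSequence:
    """Shield for the standard (5'-hairpin) architectures.

    The shield is the reverse complement of [covered binding-site portion] +
    [spacer] + [first repeat G], with the pattern's mismatches injected.
    Binding-site positions matching miRNA positions > 16 are excluded (they
    form the hairpin loop).
    """
    covered = sorted(site.spec.resolved_covered(site.mirna))
    over = [m for m in covered if site.spec.mode == "full_length" and m > BindingSiteSpec.MAX_COVERED_POSITION]
    if over:
        raise DesignError(f"shield would cover miRNA positions {over} beyond 16")
    first_g = scaffold.sequence[scaffold.first_repeat_g]
    x = _stem_target(site, covered, spacer.spacer.residues) + first_g
    shield = reverse_complement(x)
    lx = len(x)
    n_cov = len(covered)
    bad = [m for m in pattern.positions_in_binding_site if m not in covered]
    if bad:
        raise DesignError(f"shield mismatch positions {sorted(bad)} not covered by the shield")
    bad = [g for g in pattern.positions_in_shield_vs_spacer if not 1 <= g <= spacer.spacer_length]
    if bad:
        raise DesignError(f"shield mismatch spacer positions {sorted(bad)} outside spacer")
    # site-facing mismatches: miRNA position m sits at X index n_cov - rank(m),
    # where site order descends in miRNA position for a reverse-complement site
    covered_desc = sorted(covered, reverse=True)
    for m in sorted(pattern.positions_in_binding_site):
        t = covered_desc.index(m) + 1  # X index of that site residue
        s = lx + 1 - t
        shield = inject_mismatch(shield, s, x[t - 1])
    # spacer-facing mismatches: guide position g faces shield position g + 1
    for g in sorted(pattern.positions_in_shield_vs_spacer):
        s = g + 1
        t = lx + 1 - s
        shield = inject_mismatch(shield, s, x[t - 1])
    return RnaSequence(shield.residues, f"shield({site.mirna.name})")


# --------------------------------------------------------------------------
# Assemblers
# --------------------------------------------------------------------------


def _stem_designed_pairs(
    shield_len: int,
    loop_len: int,
    pattern: MismatchPattern,
    covered: list[int],
    arm_len: int,
    offset: int = 0,
    site_mutations: frozenset[int] = frozenset(),
) -> tuple[tuple[int, int], ...]:
    """Intended stem pairs in full-sequence coordinates.

    Shield occupies [1 + offset, shield_len + offset]; the paired strand X
    is contiguous and starts right after the loop.  Stem position s (from
    the shield 5' end) pairs X position shield_len + 1 - s.  Covered
    positions carrying a binding-site mutation are not designed pairs
    (the mutation mismatches the shield as well as the miRNA).
    """
    covered_desc = sorted(covered, reverse=True)
    mism_t = set()
    for m in pattern.positions_in_binding_site:
        mism_t.add(covered_desc.index(m) + 1)
    for m in site_mutations:
        if m in covered:
            mism_t.add(covered_desc.index(m) + 1)
    for g in pattern.positions_in_shield_vs_spacer:
        mism_t.add(len(covered) + (arm_len - g + 1))
    pairs = []
    for s in range(1, shield_len + 1):
        t = shield_len + 1 - s
        if t in mism_t:
            continue
        pairs.append((s + offset, shield_len + loop_len + t + offset))
    return tuple(pairs)


def assemble_full_length(
    mirna: MiRNA,
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold] = None,
    constraints: Optional[DesignConstraints] = None,
    pattern: MismatchPattern = DEFAULT_SHIELD_PATTERN,
    site_mismatches: frozenset[int] = PRESET_ACTIVE,
    covered_mirna_positions: Optional[frozenset[int]] = None,
) -> MiRGuideDesign:
    """Standard architecture: shield - loop - binding site - spacer - scaffold.

    ``covered_mirna_positions`` optionally shortens the shield's reach into
    the binding site (never beyond position 16); by default the shield
    covers miRNA positions 1..16.
    """
    constraints = constraints or DesignConstraints()
    scaffold = scaffold or load_scaffold(constraints.scaffold_variant)
    spec = BindingSiteSpec(
        mode="full_length",
        mismatch_positions=frozenset(site_mismatches),
        covered_mirna_positions=covered_mirna_positions or frozenset(),
    )
    site = build_binding_site(mirna, spec)
    covered = sorted(spec.resolved_covered(mirna))
    if covered != list(range(1, len(covered) + 1)):
        raise DesignError("covered miRNA positions must be contiguous from position 1")
    shield = build_shield(site, spacer, scaffold, pattern)
    L = len(mirna)
    n_cov = len(covered)
    loop_len = L - n_cov  # distal binding-site residues form the loop
    ls = len(shield)

    full = shield.residues + site.sequence.residues + spacer.spacer.residues + scaffold.sequence.residues
    comps = []
    pos = 1
    for name, length in (
        ("shield", ls),
        ("loop", loop_len),
        ("binding_site", n_cov),
        ("spacer", spacer.spacer_length),
        ("scaffold", len(scaffold.sequence)),
    ):
        comps.append((name, Interval(pos, pos + length - 1)))
        pos += length
    designed = _stem_designed_pairs(
        ls, loop_len, pattern, covered, spacer.spacer_length,
        site_mutations=frozenset(site_mismatches),
    )
    design = MiRGuideDesign(
        architecture="full_length_5prime_hairpin",
        components=tuple(comps),
        full_sequence=RnaSequence(full, f"miRguide({mirna.name})"),
        trigger_hairpin_interval=Interval(1, 2 * ls + loop_len),
        designed_pairs=designed,
        mirna=mirna,
        spacer_guide=spacer,
        constraints=constraints,
        mismatch_pattern=pattern,
        binding_site_spec=spec,
        scaffold=scaffold,
    )
    problems = validate_design(design)
    if problems:
        raise DesignError("; ".join(problems))
    return design


#: Default shield pattern for seed-only designs (shorter stem).
SEED_SHIELD_PATTERN = MismatchPattern(
    positions_in_binding_site=frozenset({5}),
    positions_in_shield_vs_spacer=frozenset({7, 11, 15}),
)


def assemble_seed_only(
    mirna: MiRNA,
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold] = None,
    constraints: Optional[DesignConstraints] = None,
    pattern: MismatchPattern = SEED_SHIELD_PATTERN,
    site_mismatches: frozenset[int] = frozenset({2}),
) -> MiRGuideDesign:
    """Seed-only architecture: the site covers the miRNA seed; GAAA loop.

    The default carries a single binding-site mismatch at miRNA position 2.
    """
    constraints = constraints or DesignConstraints()
    scaffold = scaffold or load_scaffold(constraints.scaffold_variant)
    spec = BindingSiteSpec(mode="seed_only", mismatch_positions=frozenset(site_mismatches))
    site = build_binding_site(mirna, spec)
    covered = sorted(spec.resolved_covered(mirna))
    shield = build_shield(site, spacer, scaffold, pattern)
    n_cov = len(covered)
    ls = len(shield)
    loop = SEED_TETRALOOP

    full = shield.residues + loop + site.sequence.residues + spacer.spacer.residues + scaffold.sequence.residues
    comps = []
    pos = 1
    for name, length in (
        ("shield", ls),
        ("loop", len(loop)),
        ("binding_site", n_cov),
        ("spacer", spacer.spacer_length),
        ("scaffold", len(scaffold.sequence)),
    ):
        comps.append((name, Interval(pos, pos + length - 1)))
        pos += length
    designed = _stem_designed_pairs(
        ls, len(loop), pattern, covered, spacer.spacer_length,
        site_mutations=frozenset(site_mismatches),
    )
    design = MiRGuideDesign(
        architecture="seed_only",
        components=tuple(comps),
        full_sequence=RnaSequence(full, f"seed-miRguide({mirna.name})"),
        trigger_hairpin_interval=Interval(1, 2 * ls + len(loop)),
        designed_pairs=designed,
        mirna=mirna,
        spacer_guide=spacer,
        constraints=constraints,
        mismatch_pattern=pattern,
        binding_site_spec=spec,
        scaffold=scaffold,
    )
    problems = validate_design(design)
    if problems:
        raise DesignError("; ".join(problems))
    return design


def seed_mismatch_scan(
    mirna: MiRNA,
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold] = None,
    constraints: Optional[DesignConstraints] = None,
    pattern: MismatchPattern = SEED_SHIELD_PATTERN,
) -> list[MiRGuideDesign]:
    """Seed-only variants moving a single site mismatch across each seed position."""
    out = []
    for m in mirna.seed_region.positions():
        out.append(
            assemble_seed_only(
                mirna, spacer, scaffold, constraints, pattern, site_mismatches=frozenset({m})
            )
        )
    return out


def assemble_tetraloop_shield(
    mirna: MiRNA,
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold] = None,
    constraints: Optional[DesignConstraints] = None,
    pattern: Optional[MismatchPattern] = None,
    site_mismatches: frozenset[int] = PRESET_ACTIVE,
) -> MiRGuideDesign:
    """Alternative architecture: the trigger module replaces the stem-loop-1
    tetraloop inside the scaffold.

    Layout: spacer - repeat - binding site - GAAA - shield - antirepeat -
    rest of scaffold.  The shield's 5' part pairs the proximal binding site
    locally; its 3' part sequesters the spacer seed by long-range pairing
    (outcompeting the repeat:antirepeat duplex in the OFF state).
    """
    constraints = constraints or DesignConstraints()
    scaffold = scaffold or load_scaffold(constraints.scaffold_variant)
    if "tetraloop" not in scaffold.annotations:
        raise DesignError("scaffold lacks a tetraloop annotation")
    if pattern is None:
        pattern = MismatchPattern(
            positions_in_binding_site=frozenset({3, 6, 10, 14}),
            positions_in_shield_vs_spacer=frozenset({7}),
        )
    spec = BindingSiteSpec(mode="full_length", mismatch_positions=frozenset(site_mismatches))
    site = build_binding_site(mirna, spec)
    covered = sorted(spec.resolved_covered(mirna))
    covered_desc = sorted(covered, reverse=True)

    seed_len = min(10, spacer.spacer_length)
    seed_seg = spacer.spacer.residues[-seed_len:]  # PAM-proximal positions 1..10, 5'->3'
    site_positions = sorted(s for s, m in site.pairing_map.items() if m in covered)
    covered_site_seq = "".join(
        complement_base(mirna.sequence[m]) for m in covered_desc
    )
    y = seed_seg + covered_site_seq
    shield = reverse_complement(y)  # = rc(perfect covered site) + rc(seed segment)
    n_cov = len(covered)
    # inject mismatches: site-facing part occupies shield[1..n_cov]
    for m in sorted(pattern.positions_in_binding_site):
        if m not in covered:
            raise DesignError(f"shield mismatch position {m} not covered")
        t = covered_desc.index(m) + 1  # position within covered site (descending m)
        s = n_cov + 1 - t
        shield = inject_mismatch(shield, s, covered_site_seq[t - 1])
    # spacer-facing part occupies shield[n_cov+1 .. n_cov+seed_len]
    for g in sorted(pattern.positions_in_shield_vs_spacer):
        if not 1 <= g <= seed_len:
            raise DesignError(f"tetraloop shield can only mismatch seed positions (got {g})")
        s = n_cov + seed_len + 1 - g
        idx = seed_len - g  # 0-based index in seed_seg
        shield = inject_mismatch(shield, s, seed_seg[idx])

    tet = scaffold.annotations["tetraloop"]
    scaf = scaffold.sequence.residues
    scaf_5p = scaf[: tet.start - 1]
    scaf_3p = scaf[tet.end :]
    insert = site.sequence.residues + SEED_TETRALOOP + shield.residues
    full = spacer.spacer.residues + scaf_5p + insert + scaf_3p
    comps = []
    pos = 1
    for name, length in (
        ("spacer", spacer.spacer_length),
        ("scaffold_5p", len(scaf_5p)),
        ("binding_site", len(site.sequence)),
        ("loop", len(SEED_TETRALOOP)),
        ("shield", len(shield)),
        ("scaffold_3p", len(scaf_3p)),
    ):
        comps.append((name, Interval(pos, pos + length - 1)))
        pos += length
    shield_iv = dict(comps)["shield"]
    site_iv = dict(comps)["binding_site"]

    # intended pairs: local site::shield stem and long-range seed::shield pairs
    designed: list[tuple[int, int]] = []
    site_mis_t = {covered_desc.index(m) + 1 for m in pattern.positions_in_binding_site}
    site_mis_t |= {covered_desc.index(m) + 1 for m in site_mismatches if m in covered}
    for t in range(1, n_cov + 1):
        if t in site_mis_t:
            continue
        site_full = site_iv.start - 1 + site_positions[t - 1]
        shield_full = shield_iv.start - 1 + (n_cov + 1 - t)
        designed.append((site_full, shield_full))
    for g in range(1, seed_len + 1):
        if g in pattern.positions_in_shield_vs_spacer:
            continue
        spacer_full = spacer.spacer_length - g + 1
        shield_full = shield_iv.start - 1 + n_cov + seed_len + 1 - g
        designed.append((spacer_full, shield_full))

    design = MiRGuideDesign(
        architecture="tetraloop_shield",
        components=tuple(comps),
        full_sequence=RnaSequence(full, f"tetraloop-miRguide({mirna.name})"),
        trigger_hairpin_interval=Interval(site_iv.start, shield_iv.end),
        designed_pairs=tuple(sorted(designed)),
        mirna=mirna,
        spacer_guide=spacer,
        constraints=constraints,
        mismatch_pattern=pattern,
        binding_site_spec=spec,
        scaffold=scaffold,
    )
    problems = validate_design(design)
    if problems:
        raise DesignError("; ".join(problems))
    return design


def assemble_split_and_gate(
    mirna_a: MiRNA,
    mirna_b: MiRNA,
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold] = None,
    constraints: Optional[DesignConstraints] = None,
    pattern: MismatchPattern = DEFAULT_SHIELD_PATTERN,
    site_mismatches: frozenset[int] = PRESET_ACTIVE,
) -> SplitGuidePair:
    """Split AND gate: crRNA unit senses miRNA A (blocks the spacer),
    tracrRNA unit senses miRNA B (blocks the antirepeat).

    Both inputs must be present to open both hairpins and reconstitute an
    active guide:tracr duplex (Boolean AND).
    """
    if mirna_a.sequence.residues == mirna_b.sequence.residues:
        raise DesignError("AND gate requires two distinct trigger miRNAs")
    constraints = constraints or DesignConstraints()
    scaffold = scaffold or load_scaffold(constraints.scaffold_variant)
    rep = scaffold.annotations["repeat"]
    arep = scaffold.annotations["antirepeat"]

    # crRNA half: spacer + repeat, with a standard 5' trigger hairpin.
    cr_scaffold = Scaffold(
        scaffold.variant,
        scaffold.sequence.subseq(rep.start, rep.end, "crRNA-repeat"),
        {"repeat": Interval(1, len(rep))},
    )
    cr_unit = assemble_full_length(
        mirna_a, spacer, cr_scaffold, constraints, pattern, site_mismatches
    )
    cr_unit = MiRGuideDesign(
        architecture="split_and_gate_unit",
        components=cr_unit.components,
        full_sequence=cr_unit.full_sequence,
        trigger_hairpin_interval=cr_unit.trigger_hairpin_interval,
        designed_pairs=cr_unit.designed_pairs,
        mirna=mirna_a,
        spacer_guide=spacer,
        constraints=constraints,
        mismatch_pattern=pattern,
        binding_site_spec=cr_unit.binding_site_spec,
        scaffold=cr_scaffold,
        blocked_element="spacer",
    )

    # tracrRNA half: shield - loop - site - antirepeat + downstream scaffold.
    spec_b = BindingSiteSpec(mode="full_length", mismatch_positions=frozenset(site_mismatches))
    site_b = build_binding_site(mirna_b, spec_b)
    covered = sorted(spec_b.resolved_covered(mirna_b))
    covered_desc = sorted(covered, reverse=True)
    tracr_seq = scaffold.sequence.residues[arep.start - 1 :]
    arm_len = len(arep)  # the shield sequesters the whole antirepeat
    arm = tracr_seq[:arm_len]
    covered_site_seq = "".join(
        complement_base(mirna_b.sequence[m]) for m in covered_desc
    )
    x = covered_site_seq + arm
    shield = reverse_complement(x)
    lx = len(x)
    n_cov = len(covered)
    for m in sorted(pattern.positions_in_binding_site):
        if m not in covered:
            raise DesignError(f"shield mismatch position {m} not covered")
        t = covered_desc.index(m) + 1
        s = lx + 1 - t
        shield = inject_mismatch(shield, s, x[t - 1])
    # reuse the spacer-facing positions of the pattern against the antirepeat arm
    for g in sorted(pattern.positions_in_shield_vs_spacer):
        if g > arm_len:
            continue
        t = n_cov + (arm_len - g + 1)
        s = lx + 1 - t
        shield = inject_mismatch(shield, s, x[t - 1])

    loop_len = len(mirna_b) - n_cov
    full = shield.residues + site_b.sequence.residues + tracr_seq
    comps = []
    pos = 1
    for name, length in (
        ("shield", lx),
        ("loop", loop_len),
        ("binding_site", n_cov),
        ("antirepeat", arm_len),
        ("scaffold", len(tracr_seq) - arm_len),
    ):
        comps.append((name, Interval(pos, pos + length - 1)))
        pos += length
    mism_t = {covered_desc.index(m) + 1 for m in pattern.positions_in_binding_site}
    mism_t |= {covered_desc.index(m) + 1 for m in site_mismatches if m in covered}
    mism_t |= {
        n_cov + (arm_len - g + 1)
        for g in pattern.positions_in_shield_vs_spacer
        if g <= arm_len
    }
    designed = tuple(
        (s, lx + loop_len + (lx + 1 - s))
        for s in range(1, lx + 1)
        if (lx + 1 - s) not in mism_t
    )
    tracr_unit = MiRGuideDesign(
        architecture="split_and_gate_unit",
        components=tuple(comps),
        full_sequence=RnaSequence(full, f"tracr-miRguide({mirna_b.name})"),
        trigger_hairpin_interval=Interval(1, 2 * lx + loop_len),
        designed_pairs=designed,
        mirna=mirna_b,
        spacer_guide=None,
        constraints=constraints,
        mismatch_pattern=pattern,
        binding_site_spec=spec_b,
        scaffold=scaffold,
        blocked_element="antirepeat",
    )
    problems = validate_design(tracr_unit)
    if problems:
        raise DesignError("; ".join(problems))
    return SplitGuidePair(cr_unit=cr_unit, tracr_unit=tracr_unit)


def standard_guide(
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold] = None,
    constraints: Optional[DesignConstraints] = None,
) -> MiRGuideDesign:
    """A plain (non-switch) guide: spacer + scaffold, no trigger hairpin.

    Used as the reference for OFF/ON comparisons; its spacer is
    predominantly unpaired at equilibrium.
    """
    constraints = constraints or DesignConstraints()
    scaffold = scaffold or load_scaffold(constraints.scaffold_variant)
    full = spacer.spacer.residues + scaffold.sequence.residues
    comps = (
        ("spacer", Interval(1, spacer.spacer_length)),
        ("scaffold", Interval(spacer.spacer_length + 1, len(full))),
    )
    design = MiRGuideDesign(
        architecture="standard",
        components=comps,
        full_sequence=RnaSequence(full, f"std-guide({spacer.spacer.name})"),
        trigger_hairpin_interval=Interval(1, spacer.spacer_length),
        designed_pairs=(),
        spacer_guide=spacer,
        constraints=constraints,
        scaffold=scaffold,
    )
    problems = validate_design(design)
    if problems:
        raise DesignError("; ".join(problems))
    return design


# --------------------------------------------------------------------------
# Seed transposition (chimeric binding regions)
# --------------------------------------------------------------------------


def chimeric_mirna(host: MiRNA, seed_donor: MiRNA, name: str = "") -> MiRNA:
    """A miRNA with the host's backbone and the donor's seed residues.

    Designing against the chimera reproduces the seed-swap experiment: the
    seed-matching segment of the resulting guide equals that of a guide
    designed against the donor.
    """
    lo, hi = host.seed_region.start, host.seed_region.end
    if (seed_donor.seed_region.start, seed_donor.seed_region.end) != (lo, hi):
        raise DesignError("seed regions of host and donor must coincide")
    donor_seed = seed_donor.seed_sequence().residues
    residues = host.sequence.residues[: lo - 1] + donor_seed + host.sequence.residues[hi:]
    return MiRNA(
        RnaSequence(residues, name or f"{host.name}[seed<-{seed_donor.name}]"),
        host.seed_region,
        host.scan_region,
    )


# --------------------------------------------------------------------------
# Backbone fixes and template emission
# --------------------------------------------------------------------------


def fix_poly_u(seq: RnaSequence | str, max_run: int = 3) -> tuple[RnaSequence, list[tuple[int, str]]]:
    """Interrupt uracil runs longer than ``max_run`` with U->C substitutions.

    Each over-long run receives one substitution at its central position
    (rounding 3'-ward); scanning repeats until no run exceeds ``max_run``,
    which makes the operation idempotent.  Returns the edited sequence and
    the list of (position, "U->C") edits.
    """
    residues = list(seq.residues if isinstance(seq, RnaSequence) else RnaSequence(seq).residues)
    name = getattr(seq, "name", "")
    edits: list[tuple[int, str]] = []
    changed = True
    while changed:
        changed = False
        i = 0
        n = len(residues)
        while i < n:
            if residues[i] == "U":
                start = i
                while i < n and residues[i] == "U":
                    i += 1
                run_len = i - start
                if run_len > max_run:
                    centre = start + run_len // 2  # 0-based
                    residues[centre] = "C"
                    edits.append((centre + 1, "U->C"))
                    changed = True
            else:
                i += 1
    return RnaSequence("".join(residues), name), edits


T7_PROMOTER = "TAATACGACTCACTATAG"
POL_III_PROMOTERS = ("U6", "H1", "7SK")


@dataclass(frozen=True)
class TemplateSpec:
    """DNA expression-template layout.

    Pol III cassettes (U6/H1/7SK) are emitted as promoter-less bodies ready
    for cloning into a promoter-containing vector, terminated by a poly-T
    run; T7 templates carry the canonical 18-nt T7 promoter and must begin
    with GG when ``leading_g_policy`` is on.
    """

    promoter: str = "U6"
    leading_g_policy: bool = True
    terminator_length: int = 6

    def __post_init__(self) -> None:
        if self.promoter not in POL_III_PROMOTERS + ("T7",):
            raise DesignError(f"unknown promoter {self.promoter!r}")


def emit_dna_template(design: MiRGuideDesign, template: TemplateSpec = TemplateSpec()) -> str:
    """DNA sense strand encoding the design under the requested promoter."""
    body = design.full_sequence.residues.replace("U", "T")
    if template.promoter == "T7":
        while template.leading_g_policy and not body.startswith("GG"):
            body = "G" + body
        return T7_PROMOTER + body
    if template.leading_g_policy and not body.startswith("G"):
        body = "G" + body
    return body + "T" * template.terminator_length


def transcribe_template(dna: str, template: TemplateSpec = TemplateSpec()) -> RnaSequence:
    """In-silico transcription of an emitted template back to RNA."""
    body = dna
    if template.promoter == "T7":
        if not body.startswith(T7_PROMOTER):
            raise DesignError("template lacks the T7 promoter")
        body = body[len(T7_PROMOTER) :]
    elif template.terminator_length:
        if not body.endswith("T" * template.terminator_length):
            raise DesignError("template lacks the poly-T terminator")
        body = body[: -template.terminator_length]
    return RnaSequence(body.replace("T", "U"), "transcript")
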