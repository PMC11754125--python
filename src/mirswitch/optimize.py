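"""Search over shield mismatch placements.

The trigger hairpin is tuned by placing mismatches in the shield: too few
and the hairpin is over-stable (AGO cannot open it), too many and the OFF
state leaks.  The optimizer searches mismatch patterns so that designed
stem pairs hybridize with probability near the target (default 0.90) while
the hairpin free energy stays inside the design window and the continuous
duplex over the spacer seed stays within its cap.

Positions are searched in "stem index" space: index 1 is the stem pair
closest to the hairpin loop (the binding-site end), the last index is the
first repeat G (never mismatched).  Stem indices map back to
binding-site / spacer coordinates of a :class:`MismatchPattern`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Callable, Iterator, Optional, Sequence

from .core import (
    DesignConstraints,
    DesignError,
    MiRGuideDesign,
    MiRNA,
    MismatchPattern,
    Scaffold,
    SpacerGuide,
)
from . import grammar, switch, thermo
from .thermo import EnergyModelParams


@dataclass(frozen=True)
class SearchConfig:
    """Search strategy configuration (fully deterministic given ``seed``)."""

    seed: int = 0
    strategy: str = "greedy"  # greedy | exhaustive_small | annealed
    max_candidates: int = 400
    max_mismatches: int = 12
    shortlist: int = 8
    max_results: int = 3
    exhaustive_cap: int = 4096  # refuse exhaustive_small above this many patterns

    def __post_init__(self) -> None:
        if self.strategy not in ("greedy", "exhaustive_small", "annealed"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


# --------------------------------------------------------------------------
# Stem-index bookkeeping
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class _StemSpace:
    covered_desc: tuple[int, ...]  # miRNA positions, loop-proximal first
    spacer_length: int

    @property
    def size(self) -> int:
        # +1 for the first repeat G, which cannot be mismatched
        return len(self.covered_desc) + self.spacer_length + 1

    @property
    def searchable(self) -> tuple[int, ...]:
        return tuple(range(1, self.size))  # all but the final G

    def to_pattern(self, stem_indices: frozenset[int]) -> MismatchPattern:
        site, spacer = set(), set()
        n_cov = len(self.covered_desc)
        for t in stem_indices:
            if t <= n_cov:
                site.add(self.covered_desc[t - 1])
            elif t < self.size:
                spacer.add(self.spacer_length - (t - n_cov) + 1)
            else:
                raise ValueError("cannot mismatch the first repeat G")
        return MismatchPattern(frozenset(site), frozenset(spacer))

    def from_pattern(self, pattern: MismatchPattern) -> frozenset[int]:
        n_cov = len(self.covered_desc)
        out = set()
        for m in pattern.positions_in_binding_site:
            out.add(self.covered_desc.index(m) + 1)
        for g in pattern.positions_in_shield_vs_spacer:
            out.add(n_cov + (self.spacer_length - g + 1))
        return frozenset(out)

    def spacer_stem_index(self, guide_position: int) -> int:
        return len(self.covered_desc) + (self.spacer_length - guide_position + 1)


def _stem_space(design_skeleton: MiRGuideDesign) -> _StemSpace:
    spec = design_skeleton.binding_site_spec
    mirna = design_skeleton.mirna
    if spec is None or mirna is None or design_skeleton.spacer_guide is None:
        raise DesignError("skeleton lacks binding-site or spacer provenance")
    covered = sorted(spec.resolved_covered(mirna), reverse=True)
    return _StemSpace(tuple(covered), design_skeleton.spacer_guide.spacer_length)


def _spacing_ok(indices: frozenset[int], window: int = 4, max_in_window: int = 3) -> bool:
    if not indices:
        return True
    hi = max(indices)
    for start in range(1, hi + 1):
        if sum(1 for t in range(start, start + window) if t in indices) > max_in_window:
            return False
    return True


def _seed_run_of_pattern(pattern: MismatchPattern, seed_len: int = 10) -> int:
    """Longest designed continuous duplex over spacer-seed positions 1..10."""
    mism = pattern.positions_in_shield_vs_spacer
    best = run = 0
    for g in range(1, seed_len + 1):
        if g in mism:
            run = 0
        else:
            run += 1
            best = max(best, run)
    return best


# --------------------------------------------------------------------------
# Pattern enumeration
# --------------------------------------------------------------------------


def enumerate_mismatch_patterns(
    design_skeleton: MiRGuideDesign,
    constraints: Optional[DesignConstraints] = None,
    pinned: MismatchPattern = MismatchPattern(),
    max_extra: int = 6,
) -> Iterator[MismatchPattern]:
    """All spacing-rule-respecting patterns containing the pinned positions.

    Deterministic order: by number of extra mismatches, then lexicographic
    stem-index tuples.  The skeleton must be assembled without shield
    mismatches (it provides the stem geometry).
    """
    constraints = constraints or DesignConstraints()
    space = _stem_space(design_skeleton)
    base = space.from_pattern(pinned)
    if not _spacing_ok(base):
        raise DesignError("pinned positions already violate the spacing rule")
    free = [t for t in space.searchable if t not in base]

    def rec(chosen: tuple[int, ...], start: int, budget: int) -> Iterator[frozenset[int]]:
        current = base | set(chosen)
        yield frozenset(current)
        if budget == 0:
            return
        for idx in range(start, len(free)):
            t = free[idx]
            cand = current | {t}
            if _spacing_ok(frozenset(cand)):
                yield from rec(chosen + (t,), idx + 1, budget - 1)

    # breadth-ordered: group by size
    seen: set[frozenset[int]] = set()
    by_size: dict[int, list[tuple[tuple[int, ...], frozenset[int]]]] = {}
    for s in rec((), 0, max_extra):
        if s in seen:
            continue
        seen.add(s)
        by_size.setdefault(len(s - base), []).append((tuple(sorted(s)), s))
    for size in sorted(by_size):
        for _, s in sorted(by_size[size]):
            yield space.to_pattern(s)


# --------------------------------------------------------------------------
# Candidate evaluation
# --------------------------------------------------------------------------


@dataclass
class CandidateEval:
    pattern: MismatchPattern
    trigger_dg: float
    median_pair_probability: Optional[float]
    band_fraction: Optional[float]  # fraction of designed pairs within +-0.05
    seed_run: int
    violations: tuple[str, ...]

    @property
    def feasible(self) -> bool:
        return not self.violations


def _assemble(
    mirna: MiRNA,
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold],
    constraints: DesignConstraints,
    pattern: MismatchPattern,
    site_mismatches: frozenset[int],
    assembler: Callable = grammar.assemble_full_length,
) -> MiRGuideDesign:
    return assembler(mirna, spacer, scaffold, constraints, pattern, site_mismatches)


def _hairpin_probs(design: MiRGuideDesign, params: EnergyModelParams) -> list[float]:
    """Designed-pair probabilities evaluated on the trigger hairpin alone."""
    iv = design.trigger_hairpin_interval
    sub = design.full_sequence.subseq(iv.start, iv.end)
    probs = thermo.partition_function(sub, params).probabilities
    off = iv.start - 1
    vals = []
    for (i, j) in design.designed_pairs:
        if i > off and j <= iv.end:
            vals.append(probs.p(i - off, j - off))
    return vals


def _evaluate(
    mirna: MiRNA,
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold],
    constraints: DesignConstraints,
    pattern: MismatchPattern,
    site_mismatches: frozenset[int],
    params: EnergyModelParams,
    with_probs: bool = True,
) -> CandidateEval:
    design = _assemble(mirna, spacer, scaffold, constraints, pattern, site_mismatches)
    dg = switch.trigger_hairpin_dg(design, params)
    seed_run = _seed_run_of_pattern(pattern, min(10, spacer.spacer_length))
    violations = []
    lo, hi = constraints.target_dg_window
    if not lo <= dg <= hi:
        violations.append("target_dg_window")
    if seed_run > constraints.max_seed_duplex_run:
        violations.append("max_seed_duplex_run")
    med = frac = None
    if with_probs:
        vals = _hairpin_probs(design, params)
        if vals:
            med = median(vals)
            target = constraints.per_pair_probability_target
            frac = sum(1 for v in vals if abs(v - target) <= 0.05) / len(vals)
    return CandidateEval(pattern, dg, med, frac, seed_run, tuple(violations))


def _objective(ev: CandidateEval, constraints: DesignConstraints) -> tuple:
    """Lexicographic minimization key."""
    centre = constraints.dg_window_center
    target = constraints.per_pair_probability_target
    return (
        len(ev.violations),
        -(ev.band_fraction if ev.band_fraction is not None else 0.0),
        abs((ev.median_pair_probability if ev.median_pair_probability is not None else 0.0) - target),
        abs(ev.trigger_dg - centre),
        tuple(sorted(ev.pattern.positions_in_binding_site)),
        tuple(sorted(ev.pattern.positions_in_shield_vs_spacer)),
    )


# --------------------------------------------------------------------------
# optimize_design
# --------------------------------------------------------------------------


@dataclass
class OptimizationResult:
    designs: list[MiRGuideDesign]
    reports: list[switch.SwitchReport]
    evaluations: list[CandidateEval]
    feasible: bool
    binding_constraint: Optional[str] = None


def optimize_design(
    mirna: MiRNA,
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold] = None,
    constraints: Optional[DesignConstraints] = None,
    search: SearchConfig = SearchConfig(),
    site_mismatches: frozenset[int] = grammar.PRESET_ACTIVE,
    pinned: MismatchPattern = MismatchPattern(),
    params: Optional[EnergyModelParams] = None,
) -> OptimizationResult:
    """Search mismatch patterns satisfying the constraints; rank the results.

    Returns designs sorted by switch score and distance of the trigger free
    energy from the window centre.  Reproducible: identical inputs and seed
    give identical ranked lists.  If no pattern satisfies the hard
    constraints the result is explicitly marked unsatisfiable, naming the
    binding constraint.
    """
    constraints = constraints or DesignConstraints()
    params = params or EnergyModelParams()
    skeleton = _assemble(
        mirna, spacer, scaffold, constraints, MismatchPattern(), site_mismatches
    )
    space = _stem_space(skeleton)

    def ev(pattern: MismatchPattern, with_probs=True) -> CandidateEval:
        return _evaluate(
            mirna, spacer, scaffold, constraints, pattern, site_mismatches, params, with_probs
        )

    evaluated: dict[frozenset[int], CandidateEval] = {}

    def eval_idx(indices: frozenset[int], with_probs=True) -> CandidateEval:
        if indices not in evaluated or (
            with_probs and evaluated[indices].band_fraction is None
        ):
            evaluated[indices] = ev(space.to_pattern(indices), with_probs)
        return evaluated[indices]

    base = space.from_pattern(pinned)

    if search.strategy == "exhaustive_small":
        count = 0
        for pattern in enumerate_mismatch_patterns(
            skeleton, constraints, pinned, max_extra=search.max_mismatches
        ):
            idx = space.from_pattern(pattern)
            eval_idx(idx)
            count += 1
            if count >= min(search.max_candidates, search.exhaustive_cap):
                break
    elif search.strategy == "greedy":
        current = base
        eval_idx(current)
        for _step in range(search.max_mismatches):
            if len(current - base) >= search.max_mismatches:
                break
            candidates = []
            for t in space.searchable:
                if t in current:
                    continue
                cand = current | {t}
                if not _spacing_ok(cand):
                    continue
                candidates.append(cand)
            if not candidates:
                break
            # cheap pre-ranking by dg distance / violations, then refine
            pre = []
            for cand in candidates:
                e = eval_idx(frozenset(cand), with_probs=False)
                pre.append((len(e.violations), abs(e.trigger_dg - constraints.dg_window_center),
                            tuple(sorted(cand)), frozenset(cand)))
            pre.sort()
            shortlist = [c[3] for c in pre[: search.shortlist]]
            best = min(
                (eval_idx(c) for c in shortlist),
                key=lambda e: _objective(e, constraints),
            )
            if _objective(best, constraints) < _objective(eval_idx(current), constraints):
                current = space.from_pattern(best.pattern)
            else:
                break
    else:  # annealed
        rng = random.Random(search.seed)
        current = base
        cur_ev = eval_idx(current)
        best_key = _objective(cur_ev, constraints)
        temp = 1.0
        for _ in range(search.max_candidates):
            t = rng.choice(space.searchable)
            cand = current ^ {t}
            if not base <= cand or not _spacing_ok(cand):
                continue
            e = eval_idx(frozenset(cand))
            key = _objective(e, constraints)
            if key < best_key or rng.random() < 0.05 * temp:
                current = frozenset(cand)
                best_key = min(best_key, key)
            temp *= 0.995

    feasible = [e for e in evaluated.values() if e.feasible and e.band_fraction is not None]
    if not feasible:
        # name the constraint that binds most often
        counts: dict[str, int] = {}
        for e in evaluated.values():
            for v in e.violations:
                counts[v] = counts.get(v, 0) + 1
        binding = max(counts, key=counts.get) if counts else "target_dg_window"
        return OptimizationResult([], [], list(evaluated.values()), False, binding)

    feasible.sort(key=lambda e: _objective(e, constraints))
    # hairpin-level search is a screen; competing structure outside the
    # hairpin matters, so re-score the shortlist on the full sequence
    top = feasible[: max(search.max_results, min(4 * search.max_results, 12))]
    target = constraints.per_pair_probability_target
    prelim = []
    for e in top:
        d = _assemble(mirna, spacer, scaffold, constraints, e.pattern, site_mismatches)
        rep = switch.SwitchReport(d.full_sequence.name, d.architecture)
        switch.off_state_report(d, params, rep)
        switch.on_state_proxy(d, d.mirna, params, rep)
        vals = list(rep.stem_pair_probabilities.values())
        med = median(vals) if vals else 0.0
        # a candidate that does not actually switch (no spacer release when
        # the site is occupied) is a failed design regardless of its stem
        prelim.append(
            (
                abs(med - target) > 0.05,
                rep.on_gain < switch.ScoreThresholds().min_on_gain,
                abs(med - target),
                abs(e.trigger_dg - constraints.dg_window_center),
                d.full_sequence.residues,
                d,
            )
        )
    prelim.sort(key=lambda k: k[:5])
    designs = [k[5] for k in prelim[: search.max_results]]
    reports = [switch.full_report(d, params) for d in designs]
    designs, reports = rank_designs(designs, reports, constraints)
    return OptimizationResult(designs, reports, list(evaluated.values()), True)


def rank_designs(
    candidates: Sequence[MiRGuideDesign],
    reports: Sequence[switch.SwitchReport],
    constraints: Optional[DesignConstraints] = None,
) -> tuple[list[MiRGuideDesign], list[switch.SwitchReport]]:
    """Deterministic stable ordering of evaluated designs.

    Sort key: criteria passed (desc), switch score (desc), |trigger dG -
    window centre| (asc), full sequence (lexicographic).  Permutation of
    the input order cannot change the output.
    """
    if len(candidates) != len(reports):
        raise ValueError("candidates and reports length mismatch")
    constraints = constraints or DesignConstraints()
    keyed = []
    for d, r in zip(candidates, reports):
        score, checks = switch.switch_score(r, constraints)
        keyed.append(
            (
                -sum(checks.values()),
                -score,
                abs((r.trigger_dg or 0.0) - constraints.dg_window_center),
                d.full_sequence.residues,
                d,
                r,
            )
        )
    keyed.sort(key=lambda k: k[:4])
    return [k[4] for k in keyed], [k[5] for k in keyed]


# --------------------------------------------------------------------------
# Study-panel designers: free-energy series and seed-duplex series
# --------------------------------------------------------------------------


def _greedy_to_target(
    mirna: MiRNA,
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold],
    constraints: DesignConstraints,
    site_mismatches: frozenset[int],
    params: EnergyModelParams,
    target_dg: float,
    pinned_guide_positions: frozenset[int],
    forbidden_guide_positions: frozenset[int],
    covered: Optional[frozenset[int]] = None,
    max_steps: int = 24,
) -> tuple[MiRGuideDesign, float]:
    """Local search on mismatch count to bring the trigger dG to a target.

    Pins and exclusions are given as spacer guide positions (PAM-proximal
    numbering); ``covered`` optionally shortens the shield's site coverage.
    """

    def build(pattern: MismatchPattern) -> MiRGuideDesign:
        return grammar.assemble_full_length(
            mirna, spacer, scaffold, constraints, pattern, site_mismatches,
            covered_mirna_positions=covered,
        )

    skeleton = build(MismatchPattern())
    space = _stem_space(skeleton)
    pinned = frozenset(space.spacer_stem_index(g) for g in pinned_guide_positions)
    forbidden = frozenset(space.spacer_stem_index(g) for g in forbidden_guide_positions)

    def dg_of(indices: frozenset[int]) -> float:
        return switch.trigger_hairpin_dg(build(space.to_pattern(indices)), params)

    movable = [t for t in space.searchable if t not in forbidden]
    current = frozenset(pinned)
    cur_dg = dg_of(current)
    for _ in range(max_steps):
        best_move, best_err = None, abs(cur_dg - target_dg)
        # single toggles
        for t in movable:
            if t in current and t in pinned:
                continue
            cand = current ^ {t}
            if not _spacing_ok(cand):
                continue
            err = abs(dg_of(cand) - target_dg)
            if err < best_err - 1e-9:
                best_move, best_err = cand, err
        if best_move is None:
            # swap moves (add one, remove one) to escape granularity plateaus
            for t_add in movable:
                if t_add in current:
                    continue
                for t_rem in current:
                    if t_rem in pinned:
                        continue
                    cand = (current - {t_rem}) | {t_add}
                    if not _spacing_ok(cand):
                        continue
                    err = abs(dg_of(cand) - target_dg)
                    if err < best_err - 1e-9:
                        best_move, best_err = cand, err
        if best_move is None:
            break
        current = best_move
        cur_dg = dg_of(current)
    return build(space.to_pattern(current)), cur_dg


def design_stability_series(
    mirna: MiRNA,
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold] = None,
    targets: Sequence[float] = (-15.0, -19.0, -25.0, -30.0),
    site_mismatches: frozenset[int] = grammar.PRESET_ACTIVE,
    params: Optional[EnergyModelParams] = None,
) -> list[tuple[MiRGuideDesign, float]]:
    """Trigger hairpins of increasing stability at fixed binding site.

    Emulates the stability study: the binding site is kept constant while
    the number of base pairs formed by the shield varies, yielding designs
    whose hairpin free energies approximate the requested targets.  The
    spacer-seed duplex is pinned at 6 bp throughout.
    """
    params = params or EnergyModelParams()
    constraints = DesignConstraints(target_dg_window=(-40.0, -5.0))
    pin = frozenset({7})  # keep the 6-bp seed duplex
    forbidden = frozenset(range(1, 7))
    out = []
    for target in targets:
        out.append(
            _greedy_to_target(
                mirna, spacer, scaffold, constraints, site_mismatches, params,
                target, pin, forbidden,
            )
        )
    return out


@dataclass
class ReferencePanel:
    """A screened reference input set with its derived construct family."""

    mirna: MiRNA
    spacer: SpacerGuide
    stability_series: list[tuple[MiRGuideDesign, float]]
    seed_run_series: list[tuple[MiRGuideDesign, float]]
    base_design: MiRGuideDesign
    base_report: switch.SwitchReport
    spacer_index: int


def design_reference_panel(
    mirna: MiRNA,
    spacers: Sequence[SpacerGuide],
    scaffold: Optional[Scaffold] = None,
    params: Optional[EnergyModelParams] = None,
    stability_targets: Sequence[float] = (-15.0, -19.0, -25.0, -30.0),
    seed_runs: Sequence[int] = (6, 8, 10),
    seed_run_target: float = -15.0,
    tolerance: float = 2.0,
) -> ReferencePanel:
    """Pick the first spacer whose whole construct family folds as designed.

    Rational design screens candidate guide sequences in silico and rejects
    those whose trigger constructs cannot reach their target free energies
    (for example when the binding site is partially complementary to the
    spacer, creating parasitic helices no shield mismatch can remove).
    The screen is deterministic: spacers are tried in the given order and
    the first one supporting the full stability and seed-coverage series
    within ``tolerance`` is returned with the derived designs.
    """
    params = params or EnergyModelParams()
    for k, sp in enumerate(spacers):
        series = design_stability_series(mirna, sp, scaffold, stability_targets, params=params)
        if any(abs(dg - t) > tolerance for (_, dg), t in zip(series, stability_targets)):
            continue
        runs = design_seed_run_series(
            mirna, sp, scaffold, seed_runs, seed_run_target, params=params
        )
        if any(abs(dg - seed_run_target) > tolerance for _, dg in runs):
            continue
        if any(
            switch.longest_seed_duplex_run(d, params) != r
            for (d, _), r in zip(runs, seed_runs)
        ):
            continue
        # base construct: the optimized design must reach the per-pair
        # hybridization-probability target on the full sequence
        constraints = DesignConstraints()
        result = optimize_design(mirna, sp, scaffold, constraints, params=params)
        if not result.feasible:
            continue
        report = result.reports[0]
        med = (
            median(report.stem_pair_probabilities.values())
            if report.stem_pair_probabilities
            else 0.0
        )
        if abs(med - constraints.per_pair_probability_target) > 0.05:
            continue
        # the emulated base construct must behave as a working switch:
        # it releases the spacer when its site is occupied and resists
        # protein-free strand displacement
        if report.on_gain is None or report.on_gain < switch.ScoreThresholds().min_on_gain:
            continue
        if report.displacement_favorable:
            continue
        return ReferencePanel(mirna, sp, series, runs, result.designs[0], report, k)
    raise DesignError(
        "no spacer in the panel supports the full construct family; "
        "provide more candidates"
    )


def design_seed_run_series(
    mirna: MiRNA,
    spacer: SpacerGuide,
    scaffold: Optional[Scaffold] = None,
    runs: Sequence[int] = (6, 8, 10),
    target_dg: float = -15.0,
    site_mismatches: frozenset[int] = grammar.PRESET_ACTIVE,
    params: Optional[EnergyModelParams] = None,
) -> list[tuple[MiRGuideDesign, float]]:
    """Variants with 6/8/10-bp continuous duplex over the spacer seed.

    The duplex over the spacer-seed region is fixed to exactly ``run`` base
    pairs (a mismatch right after the run, none inside it) and compensating
    mismatches elsewhere hold the hairpin free energy near ``target_dg``.
    """
    params = params or EnergyModelParams()
    constraints = DesignConstraints(
        target_dg_window=(-40.0, -5.0), max_seed_duplex_run=10
    )
    seed_len = min(10, spacer.spacer_length)
    out = []
    for run in runs:
        if not 1 <= run <= seed_len:
            raise DesignError(f"seed run {run} outside 1..{seed_len}")
        pin = (
            frozenset({run + 1}) if run < spacer.spacer_length else frozenset()
        )
        forbidden = frozenset(range(1, run + 1))
        # longer forced seed duplexes may need a shorter shield reach into
        # the binding site to stay at the target free energy
        best = None
        for extent in (16, 14, 12, 10, 8):
            covered = frozenset(range(1, extent + 1))
            design, dg = _greedy_to_target(
                mirna, spacer, scaffold, constraints, site_mismatches, params,
                target_dg, pin, forbidden, covered=covered,
            )
            if best is None or abs(dg - target_dg) < abs(best[1] - target_dg) - 1e-9:
                best = (design, dg)
            if abs(best[1] - target_dg) <= 0.25:
                break
        out.append(best)
    return out
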