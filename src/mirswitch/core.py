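"""Domain types, coordinate conventions and low-level sequence utilities.

Conventions used throughout the package:

* All positions are 1-based and all intervals are closed ``(start, end)``.
* miRNAs are numbered 5'->3'; position 1 is the miRNA 5' nucleotide.
* Spacer (guide-sequence) positions are numbered with position 1 being the
  PAM-proximal nucleotide, i.e. the nucleotide adjacent to the scaffold's
  first repeat G.  In sequence order the spacer is written 5'->3', so spacer
  position ``p`` corresponds to string index ``len(spacer) - p`` (0-based).
* DNA inputs are transcribed to RNA (T->U) on ingest.
* A G.U wobble counts as a pair for folding and validation; "mismatch"
  therefore means a residue that neither Watson-Crick pairs nor wobbles
  with the base it faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

#: Watson-Crick plus wobble pairs (the set the folding engine accepts).
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,U}."""


class DesignError(ValueError):
    """Raised when design inputs cannot produce a valid guide."""


def _normalize(residues: str) -> str:
    s = residues.strip().upper().replace("T", "U")
    if not s:
        raise AlphabetError("empty sequence")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-RNA characters {sorted(bad)} in sequence")
    return s


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence, 5'->3', over {A,C,G,U}.

    DNA input (containing T) is transcribed on construction.
    """

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalize(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """1-based residue access."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside [1, {len(self.residues)}]")
        return self.residues[pos - 1]

    def subseq(self, start: int, end: int, name: str = "") -> "RnaSequence":
        """Closed-interval 1-based slice."""
        if not (1 <= start <= end <= len(self.residues)):
            raise IndexError(f"interval ({start}, {end}) outside sequence")
        return RnaSequence(self.residues[start - 1 : end], name)


def is_pair(a: str, b: str) -> bool:
    """True if a:b is a Watson-Crick or G.U wobble pair."""
    return (a, b) in CANONICAL_PAIRS


def complement_base(b: str) -> str:
    try:
        return _COMPLEMENT[b]
    except KeyError as exc:
        raise AlphabetError(f"non-RNA character {b!r}") from exc


def reverse_complement(seq: RnaSequence | str) -> RnaSequence:
    """Watson-Crick reverse complement (an involution).

    Accepts an :class:`RnaSequence` or a plain string; always returns an
    :class:`RnaSequence`.
    """
    residues = seq.residues if isinstance(seq, RnaSequence) else _normalize(seq)
    rc = "".join(_COMPLEMENT[b] for b in reversed(residues))
    name = getattr(seq, "name", "")
    return RnaSequence(rc, f"rc({name})" if name else "")


# Deterministic substitution used when injecting a mismatch: for the base the
# arm position faces, pick the first candidate (preferring A, then C) that
# neither Watson-Crick pairs nor wobbles with it.
_MISMATCH_CHOICE = {"A": "A", "C": "A", "G": "A", "U": "C"}
# facing A -> arm base A (A:A);    facing C -> A (A:C);
# facing G -> A (A:G);             facing U -> C (C:U).


def mismatch_base(opposite_base: str) -> str:
    """The deterministic non-pairing, non-wobbling residue facing ``opposite_base``."""
    if opposite_base not in RNA_ALPHABET:
        raise AlphabetError(f"non-RNA character {opposite_base!r}")
    b = _MISMATCH_CHOICE[opposite_base]
    assert not is_pair(b, opposite_base) and not is_pair(opposite_base, b)
    return b


def inject_mismatch(arm: RnaSequence, position: int, opposite_base: str) -> RnaSequence:
    """Replace ``arm[position]`` with a residue that cannot pair the facing base.

    ``position`` is 1-based along the arm; ``opposite_base`` is the base that
    arm position faces in the intended duplex.  Exactly one residue changes.
    """
    if not 1 <= position <= len(arm):
        raise IndexError(f"position {position} outside arm of length {len(arm)}")
    new = mismatch_base(opposite_base)
    residues = arm.residues[: position - 1] + new + arm.residues[position:]
    return RnaSequence(residues, arm.name)


@dataclass(frozen=True)
class Interval:
    """1-based closed interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class MiRNA:
    """A trigger miRNA.

    The seed (default positions 2-8 from the 5' end) dominates AGO-mediated
    target recognition; positions 2-4 form the initial scanning subseed.
    """

    sequence: RnaSequence
    seed_region: Interval = Interval(2, 8)
    scan_region: Interval = Interval(2, 4)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (self.seed_region.start >= 1 and self.seed_region.end <= n):
            raise ValueError("seed_region outside miRNA")
        if not (
            self.scan_region.start >= self.seed_region.start
            and self.scan_region.end <= self.seed_region.end
        ):
            raise ValueError("scan_region must lie inside seed_region")

    @property
    def name(self) -> str:
        return self.sequence.name

    def __len__(self) -> int:
        return len(self.sequence)

    def seed_sequence(self) -> RnaSequence:
        return self.sequence.subseq(self.seed_region.start, self.seed_region.end)


@dataclass(frozen=True)
class SpacerGuide:
    """A Cas9 targeting (spacer) sequence.

    ``seed_interval`` is fixed to the 10 PAM-proximal positions; with PAM-proximal
    numbering this is always positions 1-10.
    """

    spacer: RnaSequence
    seed_interval: Interval = Interval(1, 10)

    def __post_init__(self) -> None:
        if not 17 <= len(self.spacer) <= 20:
            raise DesignError(
                f"spacer length {len(self.spacer)} outside supported range 17-20"
            )
        if (self.seed_interval.start, self.seed_interval.end) != (1, 10):
            raise DesignError("seed_interval is fixed to the 10 PAM-proximal positions")

    @property
    def spacer_length(self) -> int:
        return len(self.spacer)

    def base_at_guide_position(self, p: int) -> str:
        """Residue at PAM-proximal position ``p`` (1 = PAM-proximal)."""
        if not 1 <= p <= len(self.spacer):
            raise IndexError(f"guide position {p} outside spacer")
        return self.spacer[len(self.spacer) - p + 1]


@dataclass(frozen=True)
class Scaffold:
    """An sgRNA scaffold (everything 3' of the spacer) with named annotations.

    Annotations cover the crRNA repeat, the tracrRNA antirepeat, the fused
    repeat:antirepeat duplex with its connecting tetraloop (stem-loop 1), and
    the downstream stem-loops required for Cas9 binding.
    """

    variant: str  # "standard" | "optimized"
    sequence: RnaSequence
    annotations: dict[str, Interval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in ("standard", "optimized"):
            raise ValueError(f"unknown scaffold variant {self.variant!r}")
        n = len(self.sequence)
        for name, iv in self.annotations.items():
            if iv.end > n:
                raise ValueError(f"annotation {name!r} outside scaffold")

    @property
    def first_repeat_g(self) -> int:
        """Position of the first G of the repeat (1-based within the scaffold)."""
        pos = self.annotations.get("repeat", Interval(1, 1)).start
        if self.sequence[pos] != "G":
            raise ValueError("repeat does not start with G")
        return pos


@dataclass(frozen=True)
class BindingSiteSpec:
    """How the miRNA-binding site covers the trigger miRNA.

    ``mode`` is ``full_length`` (reverse complement of the whole miRNA; the
    shield-covered part reaches no further than miRNA position 16) or
    ``seed_only`` (reverse complement of the seed, closed by a GAAA tetraloop).
    ``mismatch_positions`` are numbered by the matched miRNA position.
    """

    mode: str = "full_length"
    covered_mirna_positions: frozenset[int] = frozenset()
    mismatch_positions: frozenset[int] = frozenset()

    MAX_COVERED_POSITION = 16

    def __post_init__(self) -> None:
        if self.mode not in ("full_length", "seed_only"):
            raise ValueError(f"unknown binding-site mode {self.mode!r}")

    def resolved_covered(self, mirna: MiRNA) -> frozenset[int]:
        if self.covered_mirna_positions:
            return self.covered_mirna_positions
        if self.mode == "seed_only":
            return frozenset(mirna.seed_region.positions())
        return frozenset(range(1, min(len(mirna), self.MAX_COVERED_POSITION) + 1))


@dataclass(frozen=True)
class MismatchPattern:
    """Mismatches the shield carries against the elements it sequesters.

    ``positions_in_binding_site`` are miRNA positions (<= 16 in full-length
    mode) whose binding-site residue the shield does NOT pair;
    ``positions_in_shield_vs_spacer`` are spacer positions (PAM-proximal = 1)
    left unpaired by the shield.  The spacing rule caps clustering: every
    window of 4 consecutive designed stem positions may contain at most 3
    mismatches.
    """

    positions_in_binding_site: frozenset[int] = frozenset()
    positions_in_shield_vs_spacer: frozenset[int] = frozenset()
    max_mismatches_per_window: int = 3
    window: int = 4

    def stem_mismatch_indices(self, covered: Iterable[int], spacer_length: int) -> list[int]:
        """Mismatch positions as 1-based indices along the designed stem.

        The stem is ordered from the hairpin-loop-proximal end: covered
        binding-site positions (descending miRNA position), then spacer guide
        positions ``spacer_length .. 1``, then the first repeat G.  Index 1 is
        the stem pair closest to the loop.
        """
        covered_sorted = sorted(covered, reverse=True)
        idx = []
        for rank, mpos in enumerate(covered_sorted, start=1):
            if mpos in self.positions_in_binding_site:
                idx.append(rank)
        n_cov = len(covered_sorted)
        for rank, gpos in enumerate(range(spacer_length, 0, -1), start=1):
            if gpos in self.positions_in_shield_vs_spacer:
                idx.append(n_cov + rank)
        return sorted(idx)

    def violates_spacing(self, covered: Iterable[int], spacer_length: int) -> bool:
        idx = set(self.stem_mismatch_indices(covered, spacer_length))
        stem_len = len(list(covered)) + spacer_length + 1
        for start in range(1, stem_len - self.window + 2):
            if sum(1 for k in range(start, start + self.window) if k in idx) > self.max_mismatches_per_window:
                return True
        return False


@dataclass(frozen=True)
class DesignConstraints:
    """Hard design constraints for switchable guides.

    The trigger hairpin must fall inside ``target_dg_window`` (kcal/mol),
    designed stem pairs should hybridize with probability near
    ``per_pair_probability_target`` at equilibrium, and the continuous duplex
    over the spacer seed may not exceed ``max_seed_duplex_run`` base pairs.
    The hybridization-probability target is the primary design rule; the
    default window brackets where that target lands under this package's
    parameter table (moderately stable hairpins around -15 to -18 kcal/mol).
    """

    target_dg_window: tuple[float, float] = (-22.0, -12.0)
    per_pair_probability_target: float = 0.90
    max_seed_duplex_run: int = 6
    architecture: str = "full_length_5prime_hairpin"
    scaffold_variant: str = "optimized"

    def __post_init__(self) -> None:
        lo, hi = self.target_dg_window
        if not (lo < hi and lo < 0 and hi < 0):
            raise ValueError("ΔG window bounds must be negative with lo < hi")
        if not 0 < self.per_pair_probability_target < 1:
            raise ValueError("probability target must be in (0, 1)")

    @property
    def dg_window_center(self) -> float:
        lo, hi = self.target_dg_window
        return 0.5 * (lo + hi)


ARCHITECTURES = (
    "full_length_5prime_hairpin",
    "seed_only",
    "tetraloop_shield",
    "split_and_gate_unit",
    "standard",  # plain non-switch guide, used as a reference
)


@dataclass(frozen=True)
class MiRGuideDesign:
    """A fully assembled switchable guide.

    ``components`` is an ordered list of (name, interval) tiles covering the
    full sequence without gaps or overlaps.  ``designed_pairs`` lists the
    intended trigger-hairpin stem pairs (i, j) in full-sequence coordinates
    (i < j); mismatched stem positions carry no designed pair.
    """

    architecture: str
    components: tuple[tuple[str, Interval], ...]
    full_sequence: RnaSequence
    trigger_hairpin_interval: Interval
    designed_pairs: tuple[tuple[int, int], ...] = ()
    mirna: Optional[MiRNA] = None
    spacer_guide: Optional[SpacerGuide] = None
    constraints: Optional[DesignConstraints] = None
    mismatch_pattern: Optional[MismatchPattern] = None
    binding_site_spec: Optional[BindingSiteSpec] = None
    scaffold: Optional[Scaffold] = None
    blocked_element: str = "spacer"  # what the trigger hairpin sequesters

    def component(self, name: str) -> Optional[Interval]:
        for n, iv in self.components:
            if n == name:
                return iv
        return None

    @property
    def spacer_interval(self) -> Interval:
        iv = self.component("spacer")
        assert iv is not None
        return iv

    def spacer_seed_positions(self) -> list[int]:
        """Full-sequence positions of spacer guide positions 1..10 (PAM-proximal)."""
        iv = self.spacer_interval
        length = len(iv)
        out = []
        for p in range(1, min(10, length) + 1):
            out.append(iv.end - p + 1)
        return out

    def guide_position_to_full(self, p: int) -> int:
        """Map PAM-proximal spacer position ``p`` to a full-sequence position."""
        iv = self.spacer_interval
        if not 1 <= p <= len(iv):
            raise IndexError(f"guide position {p} outside spacer")
        return iv.end - p + 1


@dataclass(frozen=True)
class SplitGuidePair:
    """The two halves of a Boolean AND-gated split guide.

    ``cr_unit`` carries the spacer-blocking trigger hairpin and senses miRNA A;
    ``tracr_unit`` carries the antirepeat-blocking hairpin and senses miRNA B.
    """

    cr_unit: MiRGuideDesign
    tracr_unit: MiRGuideDesign

    def __post_init__(self) -> None:
        a, b = self.cr_unit.mirna, self.tracr_unit.mirna
        if a is not None and b is not None and a.sequence.residues == b.sequence.residues:
            raise DesignError("AND gate requires two distinct trigger miRNAs")


def validate_design(design: MiRGuideDesign) -> list[str]:
    """Grammar validation; returns a list of human-readable violations.

    Checks component tiling, the position-16 coverage bound, the mismatch
    spacing rule, the spacer-length rule and scaffold-annotation integrity.
    Violations are data, not exceptions.
    """
    violations: list[str] = []
    n = len(design.full_sequence)

    if design.architecture not in ARCHITECTURES:
        violations.append(f"unknown architecture {design.architecture!r}")

    # Component tiling.
    pos = 1
    for name, iv in design.components:
        if iv.start != pos:
            violations.append(
                f"component {name!r} starts at {iv.start}, expected {pos} (tiling broken)"
            )
            pos = iv.start
        pos = iv.end + 1
    if pos != n + 1:
        violations.append(f"components end at {pos - 1}, sequence length is {n}")

    # Spacer length.  The tracrRNA half of a split AND gate carries no spacer.
    sp = design.component("spacer")
    if sp is None:
        if not (
            design.architecture == "split_and_gate_unit"
            and design.blocked_element != "spacer"
        ):
            violations.append("missing spacer component")
    elif not 17 <= len(sp) <= 20:
        violations.append(f"spacer length {len(sp)} outside 17-20")

    # Position-16 bound for full-length binding sites.
    spec = design.binding_site_spec
    if spec is not None and design.mirna is not None and spec.mode == "full_length":
        covered = spec.resolved_covered(design.mirna)
        over = [p for p in covered if p > BindingSiteSpec.MAX_COVERED_POSITION]
        if over:
            violations.append(
                f"covered position > 16: shield covers miRNA positions {sorted(over)}"
            )

    # Mismatch spacing.
    if (
        design.mismatch_pattern is not None
        and spec is not None
        and design.mirna is not None
        and sp is not None
    ):
        covered = spec.resolved_covered(design.mirna)
        if design.mismatch_pattern.violates_spacing(covered, len(sp)):
            violations.append(
                "mismatch spacing violated: >3 mismatches in a 4-nt stem window"
            )

    # Scaffold annotation integrity (annotations must fit inside the scaffold).
    if design.scaffold is not None:
        try:
            Scaffold(
                design.scaffold.variant,
                design.scaffold.sequence,
                design.scaffold.annotations,
            )
        except ValueError as exc:
            violations.append(f"scaffold annotations invalid: {exc}")

    # Designed pairs must be mutually compatible and within the sequence.
    seen: set[int] = set()
    for i, j in design.designed_pairs:
        if not (1 <= i < j <= n):
            violations.append(f"designed pair ({i}, {j}) outside sequence")
        if i in seen or j in seen:
            violations.append(f"designed pair ({i}, {j}) reuses a position")
        seen.update((i, j))

    return violations
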