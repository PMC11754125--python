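# Methods

This note documents the models implemented in `mirswitch`, the parameters
that matter, the design decisions taken where the design was genuinely
open, and what the synthetic study conditions do and do not show.

## RNA thermodynamics engine

### Energy model

Secondary structures are nested sets of Watson–Crick and G·U wobble pairs
(pseudoknots are never allowed; minimum hairpin loop 3 nt).  A structure's
free energy is the sum of loop terms:

* **Stacks** — the ten published Watson–Crick nearest-neighbor dimer free
  energies at 37 °C (e.g. 5′GC/3′CG = −3.42, 5′GG/3′CC = −3.26 kcal/mol).
  Wobble-containing stacks use category approximations (−2.1 next to a
  C·G/G·C, −1.3 next to an A·U/U·A, ±0.5 for tandem wobbles, with the
  destabilizing 5′UG/3′GU motif positive).
* **Hairpin, bulge and internal loops** — tabulated initiation energies
  with Jacobson–Stockmayer `1.75·RT·ln(n/n_max)` extrapolation; bulges of
  one keep the flanking stack; internal loops add 0.6 kcal/mol per
  nucleotide of asymmetry (capped at 3.0) and 0.7 per A·U/G·U closure.
  GNRA-type tetraloops receive a −1.5 kcal/mol bonus.
* **Multiloops** — affine: 3.4 (closing) + 0.4 per branch; unpaired
  multiloop nucleotides are free.
* **Helix ends** — +0.5 kcal/mol per A·U/G·U helix end; with
  `dangle_mode="some"` (the default) dangle terms for the bases flanking
  helix ends in exterior loops and multiloops are added whenever the
  neighboring base exists.  This convention is chosen because it is a
  pure function of (sequence, structure), so a *single grammar* is shared
  exactly by `structure_energy`, the MFE recursions and the partition
  function — which is what lets the exhaustive oracle check the dynamic
  programs to 1e−6.

The table ships as `mirswitch-nn-1` and its identifier is recorded in
every structure and report.  It is deliberately simplified relative to a
full Turner set (no terminal-mismatch tables, approximate wobble and
dangle terms); against an independent reference implementation the MFE
values rank-correlate at ρ ≈ 0.94 with a mean offset of ~2 kcal/mol
(this package's stacks are on average slightly less stabilizing).  All
free energies quoted by the package are therefore on the
`mirswitch-nn-1` scale, and every reported number is designed *and*
measured on that same scale.

Temperature enters the Boltzmann factor (R = 1.98717e−3 kcal/(mol·K),
T converted to kelvin); the free-energy table itself is defined at 37 °C.
Salt (1 M Na⁺) is the table's reference condition and is metadata only.

### Algorithms

* **MFE** — Zuker-style dynamic programming over V (pair-closed), M / M1
  (multiloop segments, decomposed by the last branch ending exactly at the
  segment boundary) and W (exterior) matrices; interior loops capped at 30
  unpaired nucleotides.  Traceback is deterministic with a fixed candidate
  order (5′-most pairings preferred), so identical inputs give bitwise
  identical dot-brackets.
* **Partition function** — McCaskill inside–outside recursions over the
  identical grammar, computed in log space (no overflow for sequences of
  several hundred nucleotides).  The outside pass handles exterior,
  interior-loop and multiloop contexts; for the multiloop context the
  factorized segment measure makes a three-case formula (other branches
  before / after / both sides of the distinguished branch) exact.
  `p_unpaired(i) = 1 − Σ_j p(i,j)` holds to numerical tolerance.
* **Constraints** — per-position forced-unpaired / forced-paired masks are
  honored by every recursion (used by the ON-state proxy, the
  seed-invasion cost and the displacement check).
* **Cotranscriptional folding** — each loop term closed by a pair spanning
  distance d is scaled by `γ(d) = α·e^(−d/τ) + (1−α)` during the search
  (α = 0.5, τ = 640 nt by default), down-weighting long-range pairs that a
  co-transcriptionally folding chain reaches late.  The returned ΔG is the
  *unscaled* energy of the chosen structure, and α = 0 reproduces the
  equilibrium fold bitwise.  The exact functional form used by upstream
  web services is not published in full; the form above follows the cited
  method's description and is isolated behind `CofoldParams`.
* **Exhaustive oracle** — every nested structure is enumerated (n ≤ 22)
  and scored with `structure_energy`; the test suite checks MFE values,
  log Z and every pair probability against these sums at 1e−6 relative
  tolerance on hundreds of random sequences.

### Two-strand duplex and strand displacement

Hybridization of a binding site with its trigger miRNA is scored with the
same stack table in two-strand mode: a +4.09 kcal/mol duplex initiation,
stacks along complementary runs, helix-end penalties, and symmetric
internal-loop penalties across mismatched aligned positions.

The displacement check is a two-state comparison:

```
intact    = MFE(guide) + MFE(free miRNA)
displaced = duplex(miRNA :: site) + MFE(guide | site unpaired)
            + RT·ln(1 M / c)
```

The last term is the bimolecular association penalty at the free
(AGO-unbound) miRNA concentration c.  Almost all stable cellular miRNA is
RISC-loaded and naked RNA is short-lived, so the default is c = 1 pM
(sub-percent of a ~0.1–10 nM total miRNA pool).  Without this term the
1 M standard state makes displacement of any realistic trigger hairpin
"favorable", which is not the regime the mechanism operates in.  Note the
verdict for hairpins near −15 kcal/mol sits within ~±2 kcal/mol of zero:
it is a deliberately coarse screen, not a kinetic model (no toehold or
branch-migration kinetics are computed).  Optimizer-produced designs test
unfavorable; a deliberately weakened toy hairpin facing a perfectly
complementary trigger tests favorable.

## Design grammar

Coordinates are 1-based closed intervals; miRNAs are numbered 5′→3′;
spacer positions are PAM-proximal = 1, so the "guide seed" is positions
1–10.  DNA inputs are transcribed (T→U) on ingest.  "Mismatch" always
means neither Watson–Crick nor wobble; the deterministic substitution
rule (prefer A, then C) guarantees the injected residue cannot re-pair.

The standard architecture is ordered 5′→3′ as
`shield – loop – proximal binding site – spacer – scaffold`: the binding
site is the reverse complement of the miRNA; the shield is the reverse
complement of [covered site portion (never beyond miRNA position 16)] +
[spacer] + [first repeat G]; the uncovered distal site residues form the
hairpin loop.  The seed-only variant covers the full seed (positions 2–8)
and closes the stem with a GAAA tetraloop.

Two mismatch sets are distinct in purpose but not in chemistry:

* **Binding-site mutations** (presets {2, 9, 17}, the editing-competent
  set, or {10, 11}, which ablates AGO cleavage) modulate the AGO–miRNA
  interaction.  A site mutation is one physical nucleotide edit, so it
  mismatches *both* the miRNA in trans and the shield within the hairpin;
  the shield is designed against the perfect miRNA complement and
  mutated positions are excluded from the designed pairs.
* **Shield mismatches** (`MismatchPattern`) tune the trigger-hairpin free
  energy.  The spacing rule caps clustering at 3 mismatches per 4
  consecutive stem positions; the "at least one mismatch every few
  nucleotides" half of the design style is a behavior of the optimizer,
  not a validity rule, because the seed-coverage study variants
  intentionally contain 8–10-bp perfect runs.

The tetraloop-shield architecture replaces the scaffold's stem-loop-1
GAAA tetraloop with `binding site – GAAA – shield`, where the shield's 5′
part pairs the proximal site locally and its 3′ part sequesters the
spacer seed by long-range pairing; the internal layout is config-driven
since only the placement, not the exact geometry, is fixed by the
architecture's description.  The split AND gate separates the molecule
into a crRNA half (trigger hairpin blocking the spacer, sensing miRNA A)
and a tracrRNA half (hairpin blocking the antirepeat, sensing miRNA B;
full-length sensing by default); both inputs are required to open both
hairpins.

Scaffold data: the standard SpCas9 sgRNA scaffold is the canonical
published 76-nt sequence with annotated repeat, tetraloop, antirepeat and
stem-loops.  The optimized backbone is a documented synthetic construct
built by rule from it — a 5-bp extension of the repeat:antirepeat duplex
plus one U→C substitution at the central position of the repeat's uracil
run (`fix_poly_u`, which repeats until no run exceeds three, making it
idempotent).  Pol III expression templates are emitted promoter-less
(ready for cloning into a promoter vector) with a poly-T terminator; T7
templates carry the canonical 18-nt promoter and a leading-GG policy.

## Switch analysis

The OFF state is the equilibrium ensemble of the full guide; a spacer
position counts as sequestered when its pairing probability is ≥ 0.5
(configurable).  The ON state is a *proxy*: the guide is re-folded with
every binding-site position forced unpaired, standing in for AGO–miRNA
occupancy; an explicit AGO energy model is out of scope because the
underlying biology is itself unresolved.

Known limitation of the proxy: the freed shield arm is a miRNA-mimicking
sequence and can re-pair the spacer in a shifted register, so the
intuitive invariant "occupying the site never increases spacer pairing"
is **not** a theorem of the ensemble model — roughly one design in five
violates it at one or two spacer positions.  The acceptance suite asserts
the invariant over the reference construct family and reports the
violation honestly when the frozen study conditions contain such a
design; a two-state approximation would hide this behavior, not fix it.

`seed_invasion_cost` is the ensemble free-energy difference between the
unconstrained guide and the guide with the seed-matching site residues
forced open (non-negative by construction; a seed-region site mutation
strictly lowers it).  `pathway_robustness` is true iff the equilibrium
and distance-rescaled MFE dot-brackets are identical; degenerate
equal-energy alternatives can flip this flag, which is why it is a flag
and not an error.  The composite switch score aggregates OFF
sequestration, ON gain, window membership (too-stable hairpins fail as
"over-stable"), median designed-pair probability (±0.05 band),
seed-duplex cap ("seed over-blocked"), displacement verdict and pathway
robustness.  The OFF threshold is 0.7 because spacer positions carrying
designed mismatches cannot pair their partner, capping the attainable
fraction below 1.

## Optimizer and study-condition calibration

The optimizer searches shield mismatch patterns (greedy with a cheap
MFE pre-ranking and partition-function shortlist by default; exhaustive
for small spaces; seeded annealing above).  The hairpin-level screen is
followed by full-sequence re-scoring of the shortlist, because structure
outside the hairpin competes with the designed stem; the final ranking
prefers candidates whose full-sequence median designed-pair probability
is within ±0.05 of the 0.90 target *and* which actually switch (positive
ON gain) — a candidate that never releases its spacer is a failed design
regardless of its stem statistics.  Ties are broken deterministically
(pattern lexicographic order, then sequence), so fixed inputs and seed
give identical ranked lists.

The ~90 % per-pair hybridization probability is the primary design rule;
the default free-energy window (−22 to −12 kcal/mol) brackets where that
target lands under the `mirswitch-nn-1` table.  Note that per-pair
probabilities are not uniform along a stem: interior pairs of intact
helix segments saturate near 1.0 and only pairs near mismatches sit near
0.90, so the target is stated (and met) as a *median*.

Two study-panel designers recreate the mechanism-study construct
families: `design_stability_series` holds the binding site fixed and
varies shield mismatches to hit −15/−19/−25/−30 kcal/mol (spacer-seed
duplex pinned at 6 bp), and `design_seed_run_series` pins exact
6/8/10-bp continuous duplexes over the guide seed, compensating
elsewhere — shortening the shield's reach into the site when needed — to
hold ≈ −15 kcal/mol.

`design_reference_panel` is the deterministic in-silico screen used by
the tests and the acceptance script: candidate spacers are tried in panel
order and the first one whose *whole* construct family is realizable
(stability targets within ±2 kcal/mol, exact seed runs, base design with
in-band median, positive ON gain and unfavorable displacement) becomes
the reference input.  This mirrors how such constructs are designed in
practice — candidate guides are screened computationally and pathological
combinations (e.g. a binding site partially complementary to the spacer,
creating parasitic helices no shield mismatch can remove) are never
built.

## Synthetic fixtures and the reporter model

`generate_fixtures` emulates realistic design inputs: 21–23-nt miRNAs
with 30–70 % GC, 17-nt spacers with moderate GC overall *and* in the
PAM-proximal 10-mer (30–60 %; extreme-GC seeds make poor Cas9 guides and
would also make the 10-bp seed-coverage construct physically unable to
reach −15 kcal/mol), one pair of distinct miRNAs sharing an identical
seed (the muscle miR-206-3p / miR-1a-3p situation), and adversarial
spacers (self-complementary; long U run).  What the fixtures do **not**
emulate: real miRNA expression or activity levels, AGO loading and
kinetics, chromatin or genomic context of the target, or delivery — so
passing tests demonstrate the *design-side* machinery, not editing
outcomes in cells.

The Stoplight reporter model reduces the fluorescence readout to its
combinatorial core: two out-of-frame reporter ORFs behind the cut site
mean an INDEL activates iff its net frame shift is +1 or +2 (size not a
multiple of 3).  With the default uniform support on −9…−1, 1…9 the exact
activation expectation is 12/18 = 2/3, matching the published rule that
about two-thirds of non-homologous end-joining events restore a reporter
frame; the simulator returns a seeded Monte-Carlo estimate with a
normal-approximation binomial confidence interval.  No INDEL size
distribution is asserted beyond this default (the real spectrum is
locus-dependent).

## Problem sizes

Tests and the acceptance script use: an 8-pair fixture panel; guides of
~150–170 nt; oracle verification on 200 random sequences of 5–22 nt;
10⁵ reporter events; and construct families of 7 designs plus the
optimized base design.  These sizes were chosen so the whole pipeline —
screening, design, folding and verification — runs comfortably on a
single CPU while still exercising every stage at realistic guide lengths.

## Known limitations

* The parameter table is simplified; absolute free energies are on the
  package's own scale (internally consistent; ~2 kcal/mol offset and
  ρ ≈ 0.94 rank agreement against an independent implementation).
* The ON state is an occupancy proxy, not an AGO model; see the
  re-invasion caveat above.  Ancillary RNA-binding proteins are not
  modeled.
* The displacement check is thermodynamic and two-state; its verdict near
  −15 kcal/mol hairpins is margin-of-error and depends on the assumed
  free-miRNA standard state.
* No PAM scanning, genome-wide target search, kinetic folding, or
  editing-efficiency prediction.  Wet-lab readouts (fluorescence ratios,
  editing percentages, protein restoration) have no computable
  counterpart here and are out of scope.
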