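"""File I/O, the bundled miRNA catalogue, synthetic fixtures and the
Stoplight reporter model.

The fixture generator emulates realistic design inputs - 21-23-nt miRNAs
with 30-70% GC and 17-nt spacers - plus adversarial cases (a
self-complementary spacer, a spacer with a long U run, and a pair of
distinct miRNAs sharing an identical seed, mirroring the miR-206-3p /
miR-1a-3p situation).  The Stoplight model captures the frameshift
reporter logic: an INDEL in the linker activates eGFP iff its net frame
shift is +1 or +2 (size not a multiple of three), so about two-thirds of
random nonzero INDELs activate.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .core import (
    AlphabetError,
    DesignError,
    MiRNA,
    MiRGuideDesign,
    RnaSequence,
    SpacerGuide,
    reverse_complement,
)
from . import switch, thermo


# --------------------------------------------------------------------------
# Input reading
# --------------------------------------------------------------------------


def read_inputs(path: str | Path) -> list[RnaSequence]:
    """Read miRNA/spacer records from FASTA or TSV.

    DNA is transcribed (T->U), case is normalized, duplicate names and
    non-ACGU(T) characters are rejected with the offending record named.
    """
    path = Path(path)
    records: list[RnaSequence] = []
    if path.suffix.lower() in (".tsv", ".txt", ".csv"):
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        cols = {c.lower(): c for c in df.columns}
        if "name" not in cols or "sequence" not in cols:
            raise DesignError(f"{path}: expected 'name' and 'sequence' columns")
        for _, row in df.iterrows():
            records.append(_make_record(str(row[cols["name"]]), str(row[cols["sequence"]])))
    else:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(_make_record(rec.id, str(rec.seq)))
        if not records:
            raise DesignError(f"{path}: no FASTA records found")
    names = [r.name for r in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise DesignError(f"duplicate record names: {sorted(dupes)}")
    return records


def _make_record(name: str, seq: str) -> RnaSequence:
    try:
        return RnaSequence(seq, name)
    except AlphabetError as exc:
        raise AlphabetError(f"record {name!r}: {exc}") from exc


@dataclass(frozen=True)
class CatalogueEntry:
    mirna: MiRNA
    notes: str


def load_mirna_catalogue() -> dict[str, CatalogueEntry]:
    """The bundled catalogue of trigger miRNAs (public registry sequences)."""
    text = (
        importlib.resources.files("mirswitch.data")
        .joinpath("mirna_catalogue.tsv")
        .read_text()
    )
    out: dict[str, CatalogueEntry] = {}
    for line in text.strip().splitlines()[1:]:
        name, seq, notes = line.split("\t")
        out[name] = CatalogueEntry(MiRNA(RnaSequence(seq, name)), notes)
    return out


def get_mirna(name: str) -> MiRNA:
    cat = load_mirna_catalogue()
    if name not in cat:
        raise DesignError(f"unknown miRNA {name!r}; catalogue has {sorted(cat)}")
    return cat[name].mirna


# --------------------------------------------------------------------------
# Report writing
# --------------------------------------------------------------------------


def _round_floats(obj, nd=4):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {str(k): _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def report_to_dict(report: switch.SwitchReport) -> dict:
    d = dict(report.__dict__)
    d["stem_pair_probabilities"] = {
        f"{i}-{j}": p for (i, j), p in report.stem_pair_probabilities.items()
    }
    return _round_floats(d)


def write_design_report(
    designs: Sequence[MiRGuideDesign],
    reports: Sequence[switch.SwitchReport],
    out_dir: str | Path,
    prefix: str = "designs",
) -> dict[str, Path]:
    """Write FASTA (+ dot-brackets), a TSV summary and a JSON report.

    Output is byte-stable: fixed float precision, sorted JSON keys, one TSV
    row per design.
    """
    if len(designs) != len(reports):
        raise ValueError("designs and reports length mismatch")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{prefix}.fasta"
    structures = out_dir / f"{prefix}.db"
    tsv = out_dir / f"{prefix}.tsv"
    js = out_dir / f"{prefix}.json"

    with fasta.open("w") as fh:
        for d in designs:
            fh.write(f">{d.full_sequence.name} architecture={d.architecture}\n")
            fh.write(d.full_sequence.residues + "\n")
    with structures.open("w") as fh:
        for d in designs:
            s = thermo.fold_mfe(d.full_sequence)
            fh.write(f">{d.full_sequence.name}\n{d.full_sequence.residues}\n")
            fh.write(f"{s.dot_bracket} ({s.delta_g:.2f})\n")

    rows = []
    for d, r in zip(designs, reports):
        med = (
            median(r.stem_pair_probabilities.values())
            if r.stem_pair_probabilities
            else float("nan")
        )
        rows.append(
            {
                "name": d.full_sequence.name,
                "architecture": d.architecture,
                "length": len(d.full_sequence),
                "trigger_dg": round(r.trigger_dg, 2) if r.trigger_dg is not None else "",
                "median_stem_pair_p": round(med, 4),
                "off_spacer_paired_fraction": round(r.off_spacer_paired_fraction, 4),
                "on_gain": round(r.on_gain, 4) if r.on_gain is not None else "",
                "seed_duplex_run": r.seed_duplex_run,
                "displacement_favorable": r.displacement_favorable,
                "pathway_robust": r.pathway_robust,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "name", "architecture", "length", "trigger_dg", "median_stem_pair_p",
            "off_spacer_paired_fraction", "on_gain", "seed_duplex_run",
            "displacement_favorable", "pathway_robust",
        ],
    ).to_csv(tsv, sep="\t", index=False)

    with js.open("w") as fh:
        json.dump(
            {d.full_sequence.name: report_to_dict(r) for d, r in zip(designs, reports)},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return {"fasta": fasta, "structures": structures, "tsv": tsv, "json": js}


# --------------------------------------------------------------------------
# Synthetic fixtures
# --------------------------------------------------------------------------


@dataclass
class FixturePanel:
    mirnas: list[MiRNA]
    spacers: list[SpacerGuide]
    shared_seed_pair: tuple[MiRNA, MiRNA] = None
    adversarial_spacers: dict[str, SpacerGuide] = field(default_factory=dict)

    def pairs(self) -> list[tuple[MiRNA, SpacerGuide]]:
        return list(zip(self.mirnas, self.spacers))


def _random_rna(rng: random.Random, length: int, gc_lo=0.30, gc_hi=0.70) -> str:
    while True:
        s = "".join(rng.choice("ACGU") for _ in range(length))
        gc = (s.count("G") + s.count("C")) / length
        if gc_lo <= gc <= gc_hi:
            return s


def _random_spacer(rng: random.Random, length: int = 17) -> str:
    """A functional-guide-like spacer: moderate GC overall and in the
    PAM-proximal seed (extreme-GC seeds make poor Cas9 guides)."""
    while True:
        s = _random_rna(rng, length)
        seed = s[-10:]
        gc = (seed.count("G") + seed.count("C")) / len(seed)
        if 0.30 <= gc <= 0.60:
            return s


def generate_fixtures(n: int, seed: int) -> FixturePanel:
    """Seeded synthetic panel of (miRNA, spacer) design inputs.

    ``n`` regular pairs (21-23-nt miRNAs, 30-70% GC; 17-nt spacers), plus a
    pair of distinct miRNAs sharing an identical seed and two adversarial
    spacers (self-complementary; long U run).  Identical seeds give
    identical panels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    mirnas, spacers = [], []
    for k in range(n):
        L = rng.choice((21, 22, 23))
        mirnas.append(MiRNA(RnaSequence(_random_rna(rng, L), f"syn-miR-{k + 1}")))
        spacers.append(SpacerGuide(RnaSequence(_random_spacer(rng), f"syn-spacer-{k + 1}")))
    # shared-seed pair: same residues 2-8, different elsewhere
    base = _random_rna(rng, 22)
    other = _random_rna(rng, 22)
    twin = other[:1] + base[1:8] + other[8:]
    if twin == base:
        twin = twin[:-1] + ("A" if twin[-1] != "A" else "C")
    pair = (
        MiRNA(RnaSequence(base, "syn-seed-twin-a")),
        MiRNA(RnaSequence(twin, "syn-seed-twin-b")),
    )
    # adversarial spacers
    half = _random_rna(rng, 7)
    selfc = half + "AAA" + reverse_complement(half).residues
    u_run = _random_rna(rng, 5) + "UUUUUU" + _random_rna(rng, 6)
    adversarial = {
        "self_complementary": SpacerGuide(RnaSequence(selfc, "syn-spacer-selfcomp")),
        "u_run": SpacerGuide(RnaSequence(u_run, "syn-spacer-urun")),
    }
    return FixturePanel(mirnas, spacers, pair, adversarial)


# --------------------------------------------------------------------------
# Stoplight reporter model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StoplightModel:
    """Frame-restoration logic of the dual out-of-frame eGFP reporter.

    The construct expresses mCherry constitutively, followed by two eGFP
    ORFs at net frame shifts +1 and +2 relative to the linker.  An INDEL of
    net size s restores one eGFP frame iff s mod 3 is 1 or 2; in-frame
    events (s mod 3 == 0) never activate.
    """

    activating_shifts: frozenset[int] = frozenset({1, 2})

    def activates(self, indel_size: int) -> bool:
        if indel_size == 0:
            raise ValueError("INDEL size 0 is not an edit")
        return indel_size % 3 in self.activating_shifts


@dataclass(frozen=True)
class StoplightResult:
    activation_fraction: float
    ci_low: float
    ci_high: float
    n_events: int
    confidence: float


DEFAULT_INDEL_SUPPORT = tuple(range(-9, 0)) + tuple(range(1, 10))


def simulate_stoplight(
    n_events: int,
    indel_size_distribution: Optional[dict[int, float] | Sequence[int]] = None,
    seed: int = 0,
    confidence: float = 0.99,
) -> StoplightResult:
    """Monte-Carlo activation fraction of the frameshift reporter.

    ``indel_size_distribution`` is either a mapping size -> probability or a
    support sequence sampled uniformly (default: uniform on -9..-1, 1..9).
    Returns the activating fraction with a normal-approximation binomial
    confidence interval.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if indel_size_distribution is None:
        sizes, weights = list(DEFAULT_INDEL_SUPPORT), None
    elif isinstance(indel_size_distribution, dict):
        sizes = list(indel_size_distribution)
        weights = [indel_size_distribution[s] for s in sizes]
    else:
        sizes, weights = list(indel_size_distribution), None
    if 0 in sizes and (weights is None or weights[sizes.index(0)] > 0):
        raise ValueError("INDEL size distribution assigns mass to size 0")
    model = StoplightModel()
    rng = random.Random(seed)
    hits = 0
    for s in rng.choices(sizes, weights=weights, k=n_events):
        if model.activates(s):
            hits += 1
    p = hits / n_events
    z = {0.90: 1.6449, 0.95: 1.9600, 0.99: 2.5758}.get(round(confidence, 2))
    if z is None:
        # inverse error function via Newton on the normal CDF
        z = _z_for(confidence)
    half = z * math.sqrt(max(p * (1 - p), 1e-12) / n_events)
    return StoplightResult(p, max(0.0, p - half), min(1.0, p + half), n_events, confidence)


def _z_for(confidence: float) -> float:
    target = 0.5 + confidence / 2.0
    z = 2.0
    for _ in range(60):
        cdf = 0.5 * (1 + math.erf(z / math.sqrt(2)))
        pdf = math.exp(-z * z / 2) / math.sqrt(2 * math.pi)
        z -= (cdf - target) / pdf
    return z


def stoplight_expected_fraction(
    indel_size_distribution: Optional[dict[int, float] | Sequence[int]] = None,
) -> float:
    """Exact expectation of the activation fraction over the support."""
    model = StoplightModel()
    if indel_size_distribution is None:
        indel_size_distribution = DEFAULT_INDEL_SUPPORT
    if isinstance(indel_size_distribution, dict):
        tot = sum(indel_size_distribution.values())
        return (
            sum(p for s, p in indel_size_distribution.items() if model.activates(s)) / tot
        )
    sizes = list(indel_size_distribution)
    return sum(1 for s in sizes if model.activates(s)) / len(sizes)
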