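"""Sequence primitives shared by the whole toolkit.

Conventions used throughout the package: DNA is the canonical storage
alphabet (RNA views are produced on demand for folding), coordinates are
0-based half-open intervals, and all sequences are stored top-strand 5'→3'.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucSequence",
    "Spacer",
    "SpeciesProfile",
    "SpacerLibrary",
    "SequenceError",
    "normalize_sequence",
    "gc_fraction",
    "reverse_complement",
    "generate_spacer",
    "generate_benchmark_library",
    "load_species_registry",
    "read_fasta",
    "write_fasta",
]

# IUPAC nucleotide codes and the base sets they denote (no gaps: gapped
# alignments are handled by seqstats.AlignedSet as plain rows).
IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class SequenceError(ValueError):
    """Raised for invalid residues, alphabet violations or empty input."""


@dataclass(frozen=True)
class NucSequence:
    """An uppercase IUPAC nucleotide sequence, 5'→3'.

    Parameters
    ----------
    residues
        The sequence text. Must already be normalized (see
        :func:`normalize_sequence`, the usual constructor path).
    kind
        ``"DNA"`` or ``"RNA"``.
    """

    residues: str
    kind: str = "DNA"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("empty sequence")
        if self.kind not in ("DNA", "RNA"):
            raise SequenceError(f"unknown alphabet kind {self.kind!r}")
        banned = "U" if self.kind == "DNA" else "T"
        if banned in self.residues:
            raise SequenceError(f"{banned!r} not allowed in {self.kind} sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def as_rna(self) -> "NucSequence":
        """RNA view (T→U); identity if already RNA."""
        if self.kind == "RNA":
            return self
        return NucSequence(self.residues.replace("T", "U"), "RNA")

    def as_dna(self) -> "NucSequence":
        if self.kind == "DNA":
            return self
        return NucSequence(self.residues.replace("U", "T"), "DNA")


def normalize_sequence(raw: str, kind: str = "DNA") -> NucSequence:
    """Normalize raw text into a validated :class:`NucSequence`.

    Uppercases, strips whitespace, converts T↔U to match *kind* and rejects
    anything outside the IUPAC nucleotide codes, reporting the 1-based
    position of the first offending character.
    """
    if raw is None or not str(raw).strip():
        raise SequenceError("empty sequence")
    text = "".join(str(raw).split()).upper()
    if kind == "DNA":
        text = text.replace("U", "T")
    elif kind == "RNA":
        text = text.replace("T", "U")
    else:
        raise SequenceError(f"unknown alphabet kind {kind!r}")
    check = text if kind == "DNA" else text.replace("U", "T")
    for i, c in enumerate(check):
        if c not in IUPAC_DNA:
            raise SequenceError(f"invalid character {text[i]!r} at position {i + 1}")
    return NucSequence(text, kind)


def _coerce(seq: "NucSequence | str", kind: str = "DNA") -> NucSequence:
    if isinstance(seq, NucSequence):
        return seq
    return normalize_sequence(seq, kind)


def gc_fraction(seq: "NucSequence | str", permissive: bool = False) -> float:
    """G+C fraction of a sequence.

    The two-state ambiguity codes with defined GC content are always
    accepted (S counts as 1, W as 0).  Other ambiguity codes are rejected
    unless ``permissive=True``, in which case each counts its expected GC
    fraction over the bases it denotes (e.g. N = 0.5, B = 2/3).
    """
    s = _coerce(seq).as_dna().residues
    total = 0.0
    for i, c in enumerate(s):
        if c in "GCS":
            total += 1.0
        elif c in "ATW":
            pass
        else:
            if not permissive:
                raise SequenceError(
                    f"ambiguity code {c!r} at position {i + 1} has undefined GC "
                    "content (pass permissive=True to use its expectation)"
                )
            bases = IUPAC_DNA[c]
            total += len(bases & {"G", "C"}) / len(bases)
    return total / len(s)


def reverse_complement(seq: "NucSequence | str") -> NucSequence:
    """Watson–Crick reverse complement of a DNA sequence."""
    s = _coerce(seq)
    if s.kind != "DNA":
        raise SequenceError("reverse_complement is defined for DNA input only")
    return NucSequence(s.residues.translate(_COMPLEMENT)[::-1], "DNA")


@dataclass(frozen=True)
class Spacer:
    """A candidate guide (spacer) sequence with its GC metrics.

    ``terminal_gc_k3`` is the GC fraction of the last three residues — the
    region adjacent to the downstream Cas12a cleavage site, which is the
    single most predictive feature for interference with the downstream
    gRNA.
    """

    name: str
    seq: NucSequence
    gc_fraction: float = field(init=False)
    terminal_gc_k3: float = field(init=False)

    def __post_init__(self) -> None:
        if self.seq.kind != "DNA":
            raise SequenceError("spacers are stored as DNA")
        object.__setattr__(self, "gc_fraction", gc_fraction(self.seq))
        tail = self.seq.residues[-3:]
        object.__setattr__(self, "terminal_gc_k3", gc_fraction(tail))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SpeciesProfile:
    """Cas12a/Cas13d species-specific sequences.

    ``full_separator`` is the ~16–18 nt AT-rich fragment of the natural
    pre-processing repeat that is excised during maturation;
    ``default_synseparator`` is the short (1–4 nt) 3'-derived fragment of
    it used as the synthetic insulator (e.g. AAAT for *L. bacterium*,
    TTTT for *A. species*).
    """

    species_name: str
    mature_repeat: NucSequence
    full_separator: NucSequence
    default_synseparator: NucSequence
    leader: NucSequence | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 6 <= len(self.full_separator) <= 25:
            raise SequenceError(
                f"full separator length {len(self.full_separator)} outside [6, 25]"
            )
        if not 1 <= len(self.default_synseparator) <= 8:
            raise SequenceError(
                f"synSeparator length {len(self.default_synseparator)} outside [1, 8]"
            )


@dataclass(frozen=True)
class SpacerLibrary:
    """An ordered, named collection of spacers with its generation recipe."""

    entries: tuple[Spacer, ...]
    recipe: str
    seed: int

    def __post_init__(self) -> None:
        names = [s.name for s in self.entries]
        if len(set(names)) != len(names):
            raise SequenceError("spacer names must be unique within a library")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Spacer]:
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp in self.entries:
            rows.append(
                {
                    "name": sp.name,
                    "sequence": sp.seq.residues,
                    "gc_fraction": sp.gc_fraction,
                    "decile": int(round(sp.gc_fraction * 10)) * 10,
                    "recipe": self.recipe,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: "str | Path") -> None:
        self.to_frame().to_csv(path, index=False)


def generate_spacer(
    length: int, gc_target: float, seed: "int | np.random.Generator"
) -> Spacer:
    """Random spacer with an exact G/C count of ``round(gc_target * length)``.

    The G/C positions, and the identity of each residue (G vs C, A vs T),
    are drawn uniformly from a seeded generator, so the construction is
    deterministic per seed.  ``gc_target`` is clamped to [0, 1]; rounding
    is half-up so the realized count is testable exactly.
    """
    if length < 1:
        raise SequenceError("spacer length must be >= 1")
    gc_target = min(1.0, max(0.0, float(gc_target)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_gc = int(np.floor(gc_target * length + 0.5))
    positions = rng.choice(length, size=n_gc, replace=False)
    residues = np.array(["A"] * length, dtype="<U1")
    residues[positions] = "G"
    gc_flip = rng.random(length) < 0.5
    at_flip = rng.random(length) < 0.5
    for i in range(length):
        if residues[i] == "G":
            if gc_flip[i]:
                residues[i] = "C"
        elif at_flip[i]:
            residues[i] = "T"
    seq = NucSequence("".join(residues), "DNA")
    name = f"spacer_gc{int(round(gc_target * 100))}"
    return Spacer(name, seq)


#: GC deciles of the benchmark dummy-spacer library (fractions).
BENCHMARK_DECILES = tuple(d / 10 for d in range(1, 10))
#: GC range of the six pilot spacers carried over from the pilot experiment.
PILOT_DECILES = tuple(d / 10 for d in range(3, 9))


def generate_benchmark_library(seed: int, length: int = 20) -> SpacerLibrary:
    """The 51-spacer dummy-spacer benchmark library.

    Five random 20-nt spacers per 10%-GC decile from 10% to 90% (45
    spacers) plus six pilot spacers spanning 30–80% GC, one per decile —
    the pilot set's per-decile composition is this package's choice, as
    only the overall 30–80% range is fixed by the benchmark recipe.
    """
    rng = np.random.default_rng(seed)
    entries: list[Spacer] = []
    for gc in BENCHMARK_DECILES:
        for rep in range(1, 6):
            sp = generate_spacer(length, gc, rng)
            entries.append(Spacer(f"gc{int(gc * 100):02d}_r{rep}", sp.seq))
    for gc in PILOT_DECILES:
        sp = generate_spacer(length, gc, rng)
        entries.append(Spacer(f"pilot_gc{int(gc * 100):02d}", sp.seq))
    recipe = (
        f"5x{length}nt per GC decile 10-90% (45) + 6 pilot spacers, "
        "one per decile 30-80% (pilot composition: package choice, "
        "range fixed at 30-80%)"
    )
    return SpacerLibrary(tuple(entries), recipe, seed)


# ---------------------------------------------------------------------------
# Species registry


def _default_registry_text() -> str:
    return (
        resources.files("casarray.data").joinpath("species.cfg").read_text()
    )


def load_species_registry(path: "str | Path | None" = None) -> dict[str, SpeciesProfile]:
    """Load species profiles from a plain-text config file.

    Without *path*, the packaged registry is used.  Each section defines one
    species; profiles are keyed by both section name and ``alias``.
    """
    cfg = configparser.ConfigParser()
    if path is None:
        cfg.read_string(_default_registry_text())
    else:
        text = Path(path).read_text()
        cfg.read_string(text)
    registry: dict[str, SpeciesProfile] = {}
    for section in cfg.sections():
        sec = cfg[section]
        leader = sec.get("leader", "").strip()
        profile = SpeciesProfile(
            species_name=section,
            mature_repeat=normalize_sequence(sec["mature_repeat"], "DNA"),
            full_separator=normalize_sequence(sec["full_separator"], "DNA"),
            default_synseparator=normalize_sequence(sec["default_synseparator"], "DNA"),
            leader=normalize_sequence(leader, "DNA") if leader else None,
            provenance=sec.get("provenance", ""),
        )
        registry[section] = profile
        alias = sec.get("alias", "").strip()
        if alias:
            registry[alias] = profile
    return registry


# ---------------------------------------------------------------------------
# FASTA I/O (thin Biopython wrappers; 60-column wrapping is SeqIO's default)


def read_fasta(path: "str | Path | io.TextIOBase", kind: str = "DNA") -> list[tuple[str, NucSequence]]:
    """Read a multi-record FASTA into (name, sequence) pairs."""
    records = list(SeqIO.parse(path, "fasta"))
    return [(rec.id, normalize_sequence(str(rec.seq), kind)) for rec in records]


def write_fasta(path: "str | Path | io.TextIOBase", entries: Iterable[tuple[str, "NucSequence | str"]]) -> None:
    """Write (name, sequence) pairs as wrapped FASTA."""
    records = [
        SeqRecord(Seq(str(_coerce(seq))), id=name, description="")
        for name, seq in entries
    ]
    SeqIO.write(records, path, "fasta")
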