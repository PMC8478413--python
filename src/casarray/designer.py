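"""Construction of annotated Cas12a CRISPR arrays.

An array transcript reads, 5'→3':

    leader – [separator? – repeat – spacer]×n – (separator? – trailing repeat) – 3' flank

Cas12a cleaves at the 5' end of every repeat; any separator sits
immediately upstream of a repeat, so after cleavage it remains attached to
the *upstream* fragment.  With a synSeparator upstream of every repeat
each excised single-gRNA fragment is therefore
repeat + spacer + following-separator, 4 nt longer than without for AAAT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .seqcore import NucSequence, SequenceError, Spacer, SpeciesProfile, _coerce

__all__ = [
    "SeparatorPolicy",
    "Feature",
    "ArrayDesign",
    "FragmentModel",
    "build_array",
    "predicted_fragments",
    "polya_scan",
    "design_report",
    "DEFAULT_POLYA_MOTIFS",
]

FULL = "full"  # policy sentinel: use the species' full natural separator

#: Human polyadenylation-signal hexamer variants screened by default (the
#: canonical AATAAA plus the common single-substitution variants); the set
#: is configurable per call.
DEFAULT_POLYA_MOTIFS = (
    "AATAAA", "ATTAAA", "TATAAA", "AGTAAA", "AAGAAA", "AATATA",
    "AATACA", "CATAAA", "GATAAA", "AATGAA", "TTTAAA", "ACTAAA",
)


@dataclass(frozen=True)
class SeparatorPolicy:
    """One entry per cleavage site (upstream of each repeat, trailing repeat
    included): ``None`` (no separator), :data:`FULL`, or a literal sequence."""

    per_site: tuple["str | None", ...]

    def __len__(self) -> int:
        return len(self.per_site)

    @classmethod
    def uniform(cls, separator: "str | None", n_sites: int) -> "SeparatorPolicy":
        return cls(tuple([separator] * n_sites))

    @classmethod
    def none(cls, n_sites: int) -> "SeparatorPolicy":
        return cls.uniform(None, n_sites)

    def resolve(self, profile: SpeciesProfile) -> tuple["NucSequence | None", ...]:
        out: list[NucSequence | None] = []
        for entry in self.per_site:
            if entry is None:
                out.append(None)
            elif entry == FULL:
                out.append(profile.full_separator)
            else:
                out.append(_coerce(entry))
        return tuple(out)


@dataclass(frozen=True)
class Feature:
    """Typed annotation interval, 0-based half-open on the top strand."""

    start: int
    end: int
    kind: str  # leader | separator | repeat | spacer | flank
    name: str = ""

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArrayDesign:
    """A fully annotated array construct whose features tile its sequence."""

    sequence: NucSequence
    features: tuple[Feature, ...]
    profile: SpeciesProfile
    spacer_names: tuple[str, ...]
    has_trailing_repeat: bool

    def __post_init__(self) -> None:
        pos = 0
        for f in self.features:
            if f.start != pos or f.end <= f.start:
                raise SequenceError("features must tile the sequence without gaps")
            pos = f.end
        if pos != len(self.sequence):
            raise SequenceError("features do not cover the full sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_seq(self, f: Feature) -> str:
        return self.sequence.residues[f.start:f.end]

    def features_of(self, kind: str) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if f.kind == kind)

    def to_seqrecord(self, name: str = "crispr_array") -> SeqRecord:
        rec = SeqRecord(Seq(self.sequence.residues), id=name, name=name[:16],
                        description="Cas12a CRISPR array design")
        rec.annotations["molecule_type"] = "DNA"
        for f in self.features:
            rec.features.append(
                SeqFeature(
                    FeatureLocation(f.start, f.end, strand=1),
                    type=f.kind,
                    qualifiers={"label": [f.name or f.kind]},
                )
            )
        return rec

    def to_genbank(self, path: "str | Path", name: str = "crispr_array") -> None:
        SeqIO.write([self.to_seqrecord(name)], str(path), "genbank")


@dataclass(frozen=True)
class FragmentModel:
    """Predicted Cas12a cleavage fragments of an array transcript.

    ``single_grna_indices`` marks the fragments that are fully excised
    single gRNAs (repeat + spacer, plus a trailing separator when one is
    present).
    """

    fragment_lengths: tuple[int, ...]
    single_grna_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        for idx in self.single_grna_indices:
            if not 0 <= idx < len(self.fragment_lengths):
                raise ValueError(f"single-gRNA index {idx} out of range")

    @property
    def transcript_length(self) -> int:
        return sum(self.fragment_lengths)

    @property
    def single_lengths(self) -> tuple[int, ...]:
        return tuple(self.fragment_lengths[i] for i in self.single_grna_indices)


def build_array(
    spacers: Sequence[Spacer],
    profile: SpeciesProfile,
    policy: "SeparatorPolicy | None" = None,
    include_trailing_repeat: bool = True,
    leader: "NucSequence | str | None" = None,
    three_prime_flank: "NucSequence | str | None" = None,
) -> ArrayDesign:
    """Assemble an annotated array from spacers and a species profile.

    ``policy`` must carry one entry per repeat (n spacers, plus one for the
    trailing repeat when enabled); default is the species synSeparator at
    every site.  Leader and 3' flank default to empty.
    """
    if not spacers:
        raise SequenceError("need at least one spacer")
    n_repeats = len(spacers) + (1 if include_trailing_repeat else 0)
    if policy is None:
        policy = SeparatorPolicy.uniform(
            profile.default_synseparator.residues, n_repeats
        )
    if len(policy) != n_repeats:
        raise SequenceError(
            f"policy has {len(policy)} entries for {n_repeats} repeats"
        )
    seps = policy.resolve(profile)

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0

    def emit(text: str, kind: str, name: str = "") -> None:
        nonlocal pos
        if not text:
            return
        parts.append(text)
        features.append(Feature(pos, pos + len(text), kind, name))
        pos += len(text)

    if leader is not None:
        emit(_coerce(leader).residues, "leader", "leader")
    repeat = profile.mature_repeat.residues
    for i, sp in enumerate(spacers):
        if seps[i] is not None:
            emit(seps[i].residues, "separator", f"separator_{i + 1}")
        emit(repeat, "repeat", f"repeat_{i + 1}")
        emit(sp.seq.residues, "spacer", sp.name)
    if include_trailing_repeat:
        if seps[-1] is not None:
            emit(seps[-1].residues, "separator", f"separator_{n_repeats}")
        emit(repeat, "repeat", f"repeat_{n_repeats}")
    if three_prime_flank is not None:
        emit(_coerce(three_prime_flank).residues, "flank", "three_prime_flank")

    return ArrayDesign(
        sequence=NucSequence("".join(parts), "DNA"),
        features=tuple(features),
        profile=profile,
        spacer_names=tuple(sp.name for sp in spacers),
        has_trailing_repeat=include_trailing_repeat,
    )


def predicted_fragments(design: ArrayDesign) -> FragmentModel:
    """Cleavage fragments of the array transcript.

    The transcript is cut at the 5' boundary of every repeat.  A separator
    immediately upstream of a cleavage site stays on the upstream fragment,
    so single-gRNA fragments are repeat + spacer (+ following separator)
    and the leader fragment absorbs the first separator.
    """
    cuts = [f.start for f in design.features if f.kind == "repeat"]
    # the separator right before each repeat belongs upstream: cut AT the
    # repeat start, which the feature layout already encodes.
    bounds = [0] + cuts + [len(design)]
    bounds = sorted(set(bounds))
    lengths = []
    singles = []
    for k in range(len(bounds) - 1):
        start, end = bounds[k], bounds[k + 1]
        if end == start:
            continue
        contained = [f for f in design.features if f.start >= start and f.end <= end]
        kinds = [f.kind for f in contained]
        lengths.append(end - start)
        if kinds.count("repeat") == 1 and kinds.count("spacer") == 1 and "flank" not in kinds and "leader" not in kinds:
            singles.append(len(lengths) - 1)
    return FragmentModel(tuple(lengths), tuple(singles))


def polya_scan(
    seq: "NucSequence | str",
    motifs: Sequence[str] = DEFAULT_POLYA_MOTIFS,
) -> list[tuple[int, str]]:
    """All (possibly overlapping) sense-strand occurrences of the
    polyadenylation-signal hexamers, as sorted (0-based position, motif)."""
    s = _coerce(seq).residues
    hits = []
    for motif in motifs:
        m = motif.upper()
        start = s.find(m)
        while start != -1:
            hits.append((start, m))
            start = s.find(m, start + 1)
    return sorted(hits)


def _feature_at(design: ArrayDesign, position: int) -> Feature:
    for f in design.features:
        if f.start <= position < f.end:
            return f
    raise IndexError(position)


def design_report(
    design: ArrayDesign,
    backend: str = "thermodynamic",
    polya_motifs: Sequence[str] = DEFAULT_POLYA_MOTIFS,
) -> dict:
    """Combined machine-readable report for a design.

    Per-spacer structure risk (downstream context = the next repeat +
    spacer in the array), polyadenylation-signal hits annotated with the
    feature they fall in, predicted cleavage fragments and total length.
    """
    from .structure import risk_report  # local import to keep module load light

    spacer_feats = design.features_of("spacer")
    repeat_feats = design.features_of("repeat")
    spacers = [
        Spacer(f.name, NucSequence(design.feature_seq(f), "DNA"))
        for f in spacer_feats
    ]
    contexts = []
    for i in range(len(spacer_feats)):
        if i + 1 < len(spacer_feats):
            ctx = design.feature_seq(repeat_feats[i + 1]) + design.feature_seq(
                spacer_feats[i + 1]
            )
        elif len(repeat_feats) > len(spacer_feats):  # trailing repeat only
            ctx = design.feature_seq(repeat_feats[i + 1])
        else:
            ctx = None
        contexts.append(ctx)
    # a None context (last spacer of a no-trailing design) folds spacer-only
    risks = risk_report(spacers, contexts, backend=backend)
    hits = []
    for pos, motif in polya_scan(design.sequence, polya_motifs):
        f = _feature_at(design, pos)
        hits.append({"position": pos, "motif": motif, "feature": f.kind, "name": f.name})
    model = predicted_fragments(design)
    return {
        "total_length": len(design),
        "n_repeats": len(repeat_feats),
        "n_separators": len(design.features_of("separator")),
        "spacer_risk": risks,
        "polya_hits": hits,
        "fragments": list(model.fragment_lengths),
        "single_grna_indices": list(model.single_grna_indices),
    }


def report_to_csv(report: dict, path: "str | Path") -> None:
    """Flatten a design report's per-spacer risk table to CSV."""
    df: pd.DataFrame = report["spacer_risk"].copy()
    df["polya_hits_total"] = len(report["polya_hits"])
    df["total_length"] = report["total_length"]
    df.to_csv(path, index=False)
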