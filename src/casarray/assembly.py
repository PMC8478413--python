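"""Oligonucleotide duplexing-and-ligation assembly planning.

A designed array (plus 20-bp In-Fusion vector overlaps) is divided into
double-stranded duplexes built from two single-stranded oligos of at most
60 nt each.  Adjacent duplexes join through complementary 4-nt 5'
overhangs; within and across ligation pots every overhang must be unique
(and, by default, non-palindromic and not the reverse complement of any
other) so duplexes can only assemble in the designed order.  Up to eight
duplexes are ligated per pot; longer arrays split into balanced pots whose
products are joined in a second ligation round — which is why overhang
uniqueness is enforced globally, not per pot.

Stagger convention (top strand left→right, 4-nt overhangs marked ``····``)::

    duplex k              duplex k+1
    5'-TTTTTTTTTTTT          ····TTTTTTTTT-3'   top oligos
    3'-BBBBBBBBBBBB····          BBBBBBBBB-5'   bottom oligos

Every overhang is a 5' single-stranded extension: the bottom oligo of
duplex k extends 4 nt past its top oligo on the right, and the top oligo
of duplex k+1 extends 4 nt past its bottom oligo on the left; the two
extensions are complementary.  Plan ends are blunt (In-Fusion, not
ligation, joins the array to the vector).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .seqcore import NucSequence, SequenceError, _coerce, reverse_complement

__all__ = [
    "OligoDuplex",
    "LigationPlan",
    "InfeasiblePlanError",
    "PlanVerificationError",
    "add_infusion_flanks",
    "plan_oligos",
    "partition_pots",
    "order_sheet",
    "reassemble",
    "verify_plan",
]

INFUSION_OVERLAP = 20


class InfeasiblePlanError(RuntimeError):
    """No constraint-satisfying plan exists; the message names the first
    violated constraint encountered."""


class PlanVerificationError(AssertionError):
    """An emitted or re-loaded plan violates an assembly constraint."""


@dataclass(frozen=True)
class OligoDuplex:
    """Two annealed oligos; overhangs recorded as top-strand text of the
    junction (empty string at blunt plan ends)."""

    top_oligo: str
    bottom_oligo: str  # 5'→3', i.e. reverse complement of its top-strand span
    left_overhang: str
    right_overhang: str


@dataclass(frozen=True)
class LigationPlan:
    duplexes: tuple[OligoDuplex, ...]
    pots: tuple[tuple[int, ...], ...]  # duplex indices per pot, in order
    junction_overhangs: tuple[str, ...]
    source_sequence: NucSequence
    max_oligo: int
    overhang_len: int
    pot_capacity: int = 8

    @property
    def n_duplexes(self) -> int:
        return len(self.duplexes)

    def to_json(self, path: "str | Path | None" = None) -> str:
        payload = {
            "source_sequence": self.source_sequence.residues,
            "max_oligo": self.max_oligo,
            "overhang_len": self.overhang_len,
            "pot_capacity": self.pot_capacity,
            "junction_overhangs": list(self.junction_overhangs),
            "pots": [list(p) for p in self.pots],
            "duplexes": [
                {
                    "top": d.top_oligo,
                    "bottom": d.bottom_oligo,
                    "left_overhang": d.left_overhang,
                    "right_overhang": d.right_overhang,
                }
                for d in self.duplexes
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: "str | Path") -> "LigationPlan":
        text = str(source)
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except (OSError, ValueError):
            pass
        payload = json.loads(text)
        return cls(
            duplexes=tuple(
                OligoDuplex(d["top"], d["bottom"], d["left_overhang"], d["right_overhang"])
                for d in payload["duplexes"]
            ),
            pots=tuple(tuple(p) for p in payload["pots"]),
            junction_overhangs=tuple(payload["junction_overhangs"]),
            source_sequence=NucSequence(payload["source_sequence"], "DNA"),
            max_oligo=payload["max_oligo"],
            overhang_len=payload["overhang_len"],
            pot_capacity=payload.get("pot_capacity", 8),
        )


def add_infusion_flanks(
    array_seq: "NucSequence | str",
    left_arm: "NucSequence | str",
    right_arm: "NucSequence | str",
) -> NucSequence:
    """Add the 20-bp vector-overlap flanks required for In-Fusion cloning.

    The last 20 nt of the left arm and the first 20 nt of the right arm
    flank the array; longer arms are truncated to the overlap.
    """
    arr = _coerce(array_seq)
    left = _coerce(left_arm)
    right = _coerce(right_arm)
    for arm, side in ((left, "left"), (right, "right")):
        if len(arm) < INFUSION_OVERLAP:
            raise SequenceError(
                f"{side} vector arm is {len(arm)} nt; needs >= {INFUSION_OVERLAP}"
            )
    return NucSequence(
        left.residues[-INFUSION_OVERLAP:] + arr.residues + right.residues[:INFUSION_OVERLAP],
        "DNA",
    )


def partition_pots(n_duplexes: int, pot_capacity: int = 8) -> list[int]:
    """Balanced pot sizes: ⌈n/capacity⌉ pots, sizes differing by at most
    one, larger pots first (12 duplexes → two pots of six)."""
    if n_duplexes < 1:
        raise ValueError("need at least one duplex")
    n_pots = math.ceil(n_duplexes / pot_capacity)
    base, extra = divmod(n_duplexes, n_pots)
    return [base + (1 if i < extra else 0) for i in range(n_pots)]


def _overhang_ok(
    oh: str,
    chosen: Sequence[str],
    forbid_palindromes: bool,
    forbid_revcomp_pairs: bool,
) -> str | None:
    """None if acceptable, else the violated-constraint description."""
    if oh in chosen:
        return f"duplicate overhang {oh}"
    rc = reverse_complement(oh).residues
    if forbid_palindromes and oh == rc:
        return f"palindromic (self-complementary) overhang {oh}"
    if forbid_revcomp_pairs and rc in chosen:
        return f"overhang {oh} is the reverse complement of overhang {rc}"
    if any(c not in "ACGT" for c in oh):
        return f"ambiguous bases in overhang {oh}"
    return None


def plan_oligos(
    ds_seq: "NucSequence | str",
    max_oligo: int = 60,
    overhang_len: int = 4,
    pot_capacity: int = 8,
    forbid_palindromes: bool = True,
    forbid_revcomp_pairs: bool = True,
) -> LigationPlan:
    """Divide a double-stranded sequence into a ligation plan.

    Deterministic backtracking over staggered cut positions: junctions
    start at the most balanced spacing and are perturbed outward
    (0, +1, −1, +2, …) until every oligo is within ``max_oligo`` and every
    overhang satisfies the global uniqueness/complementarity constraints.
    Raises :class:`InfeasiblePlanError` with the first violated constraint
    when no assignment exists (e.g. homopolymer input, where all candidate
    overhangs are identical).
    """
    seq = _coerce(ds_seq)
    s = seq.residues
    L = len(s)
    if L < 2 * overhang_len:
        raise InfeasiblePlanError(
            f"sequence length {L} below minimum {2 * overhang_len}"
        )
    # every fragment bounded by max_oligo - overhang_len: the longer strand
    # of a terminal duplex picks up the adjacent overhang
    frag_cap = max_oligo - overhang_len
    min_frag = 2 * overhang_len

    last_violation = "no junction assignment possible"
    if L <= frag_cap:
        return _finalize(seq, [], max_oligo, overhang_len, pot_capacity)
    # target fragments one overhang short of the cap: at the cap exactly the
    # junctions have no slack and the search degenerates
    n_start = max(2, math.ceil(L / (frag_cap - overhang_len)))
    n_limit = min(max(n_start + 16, n_start), max(n_start, L // min_frag))
    for n_frags in range(n_start, n_limit + 1):
        ideal = [round(k * L / n_frags) for k in range(1, n_frags)]
        result = _search(
            s, ideal, frag_cap, min_frag, overhang_len,
            forbid_palindromes, forbid_revcomp_pairs,
        )
        if isinstance(result, list):
            return _finalize(seq, result, max_oligo, overhang_len, pot_capacity)
        last_violation = result
    raise InfeasiblePlanError(last_violation)


def _search(
    s: str,
    ideal: list[int],
    frag_cap: int,
    min_frag: int,
    overhang_len: int,
    forbid_palindromes: bool,
    forbid_revcomp_pairs: bool,
    max_shift: int = 24,
    node_budget: int = 200_000,
) -> "list[int] | str":
    """Backtracking junction placement; returns cut positions or the first
    violated constraint's description.  A node budget bounds pathological
    backtracking; exhausting it fails this fragment count so the caller can
    retry with one fragment more (graceful degradation, never a hang)."""
    L = len(s)
    n_junc = len(ideal)
    # candidate offsets by distance from ideal; deterministic + before -
    offsets = [0]
    for d in range(1, max_shift + 1):
        offsets.extend((d, -d))
    first_violation: str | None = None
    cuts: list[int] = []
    overhangs: list[str] = []
    nodes = 0

    def place(k: int) -> bool:
        nonlocal first_violation, nodes
        if k == n_junc:
            return True
        nodes += 1
        if nodes > node_budget:
            return False
        prev = cuts[-1] if cuts else 0
        for off in offsets:
            p = ideal[k] + off
            if p < prev + min_frag or p + overhang_len > L:
                continue
            if p - prev > frag_cap:
                continue
            if k == n_junc - 1 and not (min_frag <= L - p <= frag_cap):
                continue
            oh = s[p:p + overhang_len]
            why = _overhang_ok(oh, overhangs, forbid_palindromes, forbid_revcomp_pairs)
            if why is not None:
                if first_violation is None:
                    first_violation = why
                continue
            cuts.append(p)
            overhangs.append(oh)
            if place(k + 1):
                return True
            cuts.pop()
            overhangs.pop()
        return False

    if place(0):
        return cuts
    return first_violation or "no junction assignment possible"


def _finalize(
    seq: NucSequence,
    cuts: list[int],
    max_oligo: int,
    overhang_len: int,
    pot_capacity: int,
) -> LigationPlan:
    s = seq.residues
    L = len(s)
    bounds = [0] + cuts + [L]
    overhangs = [s[p:p + overhang_len] for p in cuts]
    duplexes = []
    for k in range(len(bounds) - 1):
        top_start, top_end = bounds[k], bounds[k + 1]
        bot_start = bounds[k] + (overhang_len if k > 0 else 0)
        bot_end = bounds[k + 1] + (overhang_len if k < len(bounds) - 2 else 0)
        top = s[top_start:top_end]
        bottom = reverse_complement(s[bot_start:bot_end]).residues
        left = overhangs[k - 1] if k > 0 else ""
        right = overhangs[k] if k < len(overhangs) else ""
        duplexes.append(OligoDuplex(top, bottom, left, right))
    sizes = partition_pots(len(duplexes), pot_capacity)
    pots = []
    pos = 0
    for size in sizes:
        pots.append(tuple(range(pos, pos + size)))
        pos += size
    plan = LigationPlan(
        duplexes=tuple(duplexes),
        pots=tuple(pots),
        junction_overhangs=tuple(overhangs),
        source_sequence=seq,
        max_oligo=max_oligo,
        overhang_len=overhang_len,
        pot_capacity=pot_capacity,
    )
    verify_plan(plan)  # never emit an invalid plan
    return plan


def reassemble(plan: LigationPlan) -> NucSequence:
    """Concatenate duplex top strands in order (overhang overlaps are part
    of exactly one top strand, so plain concatenation restores the source)."""
    return NucSequence("".join(d.top_oligo for d in plan.duplexes), "DNA")


def verify_plan(
    plan: LigationPlan,
    forbid_palindromes: bool = True,
    forbid_revcomp_pairs: bool = True,
) -> None:
    """Independent brute-force re-check of every assembly constraint.

    Recomputes overhangs from the oligo sequences themselves (not the
    plan's recorded list), checks oligo lengths, pot capacities,
    duplex complementarity, pairwise overhang uniqueness and
    non-complementarity, and exact round-trip to the source sequence.
    Raises :class:`PlanVerificationError` naming the first violation.
    """
    src = plan.source_sequence.residues
    if reassemble(plan).residues != src:
        raise PlanVerificationError("reassembled top strands do not match source")
    for i, d in enumerate(plan.duplexes):
        for strand, oligo in (("top", d.top_oligo), ("bottom", d.bottom_oligo)):
            if len(oligo) > plan.max_oligo:
                raise PlanVerificationError(
                    f"duplex {i} {strand} oligo is {len(oligo)} nt > {plan.max_oligo}"
                )
    # recompute overhangs from oligo geometry
    pos = 0
    derived: list[str] = []
    for i, d in enumerate(plan.duplexes[:-1]):
        pos += len(d.top_oligo)
        derived.append(src[pos:pos + plan.overhang_len])
    if tuple(derived) != plan.junction_overhangs:
        raise PlanVerificationError("recorded overhangs disagree with oligo geometry")
    for i, d in enumerate(plan.duplexes):
        # bottom oligo must be the reverse complement of its top-strand span
        start = sum(len(x.top_oligo) for x in plan.duplexes[:i])
        bot_start = start + (plan.overhang_len if i > 0 else 0)
        bot_end = start + len(d.top_oligo) + (
            plan.overhang_len if i < len(plan.duplexes) - 1 else 0
        )
        expect = reverse_complement(src[bot_start:bot_end]).residues
        if d.bottom_oligo != expect:
            raise PlanVerificationError(f"duplex {i} bottom oligo not complementary")
    for a in range(len(derived)):
        for b in range(a + 1, len(derived)):
            if derived[a] == derived[b]:
                raise PlanVerificationError(f"duplicated overhang {derived[a]}")
            if forbid_revcomp_pairs and derived[a] == reverse_complement(derived[b]).residues:
                raise PlanVerificationError(
                    f"overhangs {derived[a]}/{derived[b]} are reverse complements"
                )
        if forbid_palindromes and derived[a] == reverse_complement(derived[a]).residues:
            raise PlanVerificationError(f"palindromic overhang {derived[a]}")
    sizes = [len(p) for p in plan.pots]
    if max(sizes) > plan.pot_capacity:
        raise PlanVerificationError(
            f"pot of {max(sizes)} duplexes exceeds capacity {plan.pot_capacity}"
        )
    if sum(sizes) != len(plan.duplexes) or sorted(
        i for p in plan.pots for i in p
    ) != list(range(len(plan.duplexes))):
        raise PlanVerificationError("pots do not partition the duplexes")
    if max(sizes) - min(sizes) > 1:
        raise PlanVerificationError("pot sizes differ by more than one")


def order_sheet(plan: LigationPlan, name_prefix: str = "oligo") -> pd.DataFrame:
    """Vendor-agnostic order sheet: one row per single-stranded oligo."""
    pot_of = {}
    for pot_idx, pot in enumerate(plan.pots):
        for d in pot:
            pot_of[d] = pot_idx + 1
    rows = []
    for i, d in enumerate(plan.duplexes):
        for strand, oligo in (("top", d.top_oligo), ("bottom", d.bottom_oligo)):
            rows.append(
                {
                    "name": f"{name_prefix}_{i + 1:03d}_{strand}",
                    "pot": pot_of[i],
                    "duplex": i + 1,
                    "strand": strand,
                    "sequence_5to3": oligo,
                    "length": len(oligo),
                    "left_overhang": d.left_overhang,
                    "right_overhang": d.right_overhang,
                }
            )
    return pd.DataFrame(rows)


def sheet_to_plan_source(sheet: pd.DataFrame) -> NucSequence:
    """Re-derive the source sequence from an order sheet (round-trip check)."""
    tops = sheet[sheet["strand"] == "top"].sort_values("duplex")["sequence_5to3"]
    return NucSequence("".join(tops), "DNA")
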