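"""Secondary-structure interference scoring of spacers in array context.

A spacer with high GC content can base-pair with the downstream gRNA
(repeat + spacer) in the unprocessed array transcript and impede Cas12a
processing.  The propensity is scored as the negated ensemble free energy
of the folded spacer+downstream-gRNA concatenation: the ensemble free
energy −RT·ln(Z) summarizes the stability of the whole Boltzmann ensemble
of structures, so larger scores mean more stable predicted structure.

Two backends satisfy the same contract:

``thermodynamic``
    ViennaRNA's partition function (McCaskill) at 37 °C, imported lazily.
``oracle``
    An internal exact base-pair-maximization dynamic program (weighted
    Nussinov) rescaled to pseudo-kcal/mol.  It has no external
    dependencies and doubles as the test oracle.

Backends are never substituted silently: requesting an unavailable one
raises :class:`BackendUnavailableError` naming the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seqcore import NucSequence, SequenceError, Spacer, _coerce

__all__ = [
    "FoldResult",
    "StructureScore",
    "BackendUnavailableError",
    "fold",
    "pairing_oracle",
    "context_score",
    "risk_report",
]

#: Pair weights for the fallback DP (canonical Watson–Crick plus wobble).
PAIR_WEIGHTS = {
    frozenset("GC"): 3.0,
    frozenset("AU"): 2.0,
    frozenset("GU"): 1.0,
}

#: Pseudo-energy per weight unit for the oracle backend (kcal/mol per unit).
ORACLE_KCAL_PER_WEIGHT = 0.8

#: Terminal-GC threshold above which a spacer is flagged HIGH risk: 2 of the
#: last 3 residues being G/C.
HIGH_TERMINAL_GC = 2.0 / 3.0


class BackendUnavailableError(RuntimeError):
    """The requested folding backend cannot run in this environment."""


@dataclass(frozen=True)
class FoldResult:
    sequence: NucSequence
    ensemble_free_energy: float  # kcal/mol; <= 0 for any structured RNA
    backend_name: str


@dataclass(frozen=True)
class StructureScore:
    """Non-negative structure propensity: max(0, −ensemble free energy)."""

    score: float
    context_kind: str  # "spacer-only" | "spacer-plus-downstream-gRNA"
    backend_name: str

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("structure score must be non-negative")


def _thermodynamic_efe(rna: str, temperature: float) -> float:
    try:
        import RNA  # ViennaRNA python bindings
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise BackendUnavailableError(
            "the thermodynamic backend needs the ViennaRNA python bindings "
            "(module 'RNA'); select backend='oracle' to use the internal "
            "base-pair-maximization fallback"
        ) from exc
    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(rna, md)
    _, efe = fc.pf()
    return float(efe)


def pairing_oracle(seq: "NucSequence | str", min_loop: int = 3) -> float:
    """Maximum weighted nested base-pair count (exact dynamic program).

    Weights GC=3, AU=2, GU=1; hairpin loops must enclose at least
    ``min_loop`` unpaired residues.  O(n³) Nussinov-style recursion, exact
    over all pseudoknot-free structures.
    """
    rna = _coerce(seq, "RNA").as_rna().residues if isinstance(seq, str) else seq.as_rna().residues
    n = len(rna)
    if n == 0:
        raise SequenceError("empty sequence")
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            w[i, j] = PAIR_WEIGHTS.get(frozenset((rna[i], rna[j])), 0.0)
    dp = np.zeros((n + 1, n + 1))  # dp[i][j]: best weight on rna[i:j]
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # half-open
            best = dp[i + 1][j]  # i unpaired
            for k in range(i + 1, j):  # i pairs with k (needs loop room)
                if w[i, k] > 0 and k - i - 1 >= min_loop:
                    cand = w[i, k] + dp[i + 1][k] + dp[k + 1][j]
                    if cand > best:
                        best = cand
            dp[i][j] = best
    return float(dp[0][n])


def fold(
    seq: "NucSequence | str",
    temperature: float = 37.0,
    backend: str = "thermodynamic",
    min_loop: int = 3,
) -> FoldResult:
    """Ensemble free energy of an RNA (kcal/mol) under the chosen backend.

    Deterministic for a fixed (sequence, backend, temperature).  DNA input
    is folded through its RNA view.
    """
    nseq = seq if isinstance(seq, NucSequence) else _coerce(seq, "DNA")
    rna = nseq.as_rna()
    if backend == "thermodynamic":
        efe = _thermodynamic_efe(rna.residues, temperature)
    elif backend == "oracle":
        efe = -ORACLE_KCAL_PER_WEIGHT * pairing_oracle(rna, min_loop=min_loop)
    else:
        raise BackendUnavailableError(
            f"unknown backend {backend!r}; choose 'thermodynamic' or 'oracle'"
        )
    return FoldResult(rna, efe, backend)


def context_score(
    upstream_spacer: "Spacer | NucSequence | str",
    downstream_grna: "NucSequence | str | None" = None,
    backend: str = "thermodynamic",
    temperature: float = 37.0,
) -> StructureScore:
    """Structure propensity of a spacer in its array context.

    The spacer and the downstream gRNA (repeat + spacer) are concatenated
    directly, with no linker, exactly as they occur in the unprocessed
    transcript, and folded as one molecule.  With ``downstream_grna=None``
    the spacer is folded alone (spacer-only context).
    """
    up = upstream_spacer.seq if isinstance(upstream_spacer, Spacer) else _coerce(upstream_spacer)
    if downstream_grna is None:
        joined = up.as_rna().residues
        kind = "spacer-only"
    else:
        down = _coerce(downstream_grna)
        joined = up.as_rna().residues + down.as_rna().residues
        kind = "spacer-plus-downstream-gRNA"
    res = fold(NucSequence(joined, "RNA"), temperature=temperature, backend=backend)
    return StructureScore(max(0.0, -res.ensemble_free_energy), kind, res.backend_name)


def risk_report(
    spacers: Sequence[Spacer],
    downstream_contexts: Sequence["NucSequence | str | None"],
    backend: str = "thermodynamic",
    high_terminal_gc: float = HIGH_TERMINAL_GC,
    elevated_percentile: float = 75.0,
) -> pd.DataFrame:
    """Per-spacer interference risk table.

    Flags: ``HIGH`` when the last-3-nt GC fraction reaches
    ``high_terminal_gc`` (default 2/3 — two of the three residues next to
    the cleavage site are G/C); else ``ELEVATED`` when the context
    structure score exceeds the library's ``elevated_percentile``; else
    ``LOW``.
    """
    if len(spacers) != len(downstream_contexts):
        raise ValueError("spacers and downstream contexts must align")
    scores = [
        context_score(sp, ctx or None, backend=backend).score
        for sp, ctx in zip(spacers, downstream_contexts)
    ]
    cutoff = float(np.percentile(scores, elevated_percentile)) if scores else 0.0
    rows = []
    for sp, score in zip(spacers, scores):
        if sp.terminal_gc_k3 >= high_terminal_gc:
            flag = "HIGH"
        elif score > cutoff:
            flag = "ELEVATED"
        else:
            flag = "LOW"
        rows.append(
            {
                "name": sp.name,
                "gc_fraction": sp.gc_fraction,
                "terminal_gc_k3": sp.terminal_gc_k3,
                "context_score": score,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
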