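"""GC-window statistics, window-scan predictive power and natural-sequence
profiling.

The sliding-window profile walks a base-width (default 5 nt) window along
the sequence and then shrinks the window width stepwise (4, 3, 2 nt),
anchoring each shrunken window at the 3' terminus — this raises resolution
at the 3' end, next to the Cas12a cleavage site, which is where spacer GC
content matters most.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqcore import IUPAC_DNA, NucSequence, SequenceError, Spacer, gc_fraction

__all__ = [
    "GcProfile",
    "WindowScan",
    "AlignedSet",
    "sliding_gc",
    "group_profiles",
    "window_predictive_power",
    "anchor_3prime",
    "column_gc_profile",
    "iupac_consensus",
    "spacer_set_summary",
    "read_aligned_fasta",
    "read_responses",
]

GAP = "-"


@dataclass(frozen=True)
class GcProfile:
    """GC content per sliding window.

    ``windows`` holds ``(start, width, gc)`` triples with 0-based starts;
    ``gc`` may be NaN where every contributing column was a gap.
    """

    windows: tuple[tuple[int, int, float], ...]
    source_length: int

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def gc(self) -> np.ndarray:
        return np.array([w[2] for w in self.windows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows, columns=["start", "width", "gc"])


@dataclass(frozen=True)
class WindowScan:
    """Per-window regression R² of a response against window GC content."""

    window_width: int
    r2_by_window: tuple[tuple[int, float], ...]
    whole_sequence_r2: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.r2_by_window, columns=["start", "r2"])
        df.insert(1, "width", self.window_width)
        return df

    def best_window(self) -> tuple[int, float]:
        """(start, R²) of the most predictive window; first wins ties."""
        return max(self.r2_by_window, key=lambda t: t[1])


@dataclass(frozen=True)
class AlignedSet:
    """Equal-length gapped rows ('-' gaps), with the anchoring convention
    recorded (3'-anchored stacks vs externally aligned sets)."""

    rows: tuple[str, ...]
    anchor: str = "none"  # "3prime", "5prime" or "none" (external alignment)

    def __post_init__(self) -> None:
        if not self.rows:
            raise SequenceError("alignment needs at least one row")
        width = len(self.rows[0])
        for r in self.rows:
            if len(r) != width:
                raise SequenceError("alignment rows must have equal length")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)


def _window_starts(length: int, base_width: int, min_width: int) -> list[tuple[int, int]]:
    spans = [(s, base_width) for s in range(length - base_width + 1)]
    for w in range(base_width - 1, min_width - 1, -1):
        spans.append((length - w, w))
    return spans


def sliding_gc(seq: "NucSequence | str", base_width: int = 5, min_width: int = 2) -> GcProfile:
    """Sliding-window GC profile with 3'-anchored shrinking windows.

    Full-width windows at every start, then one window of each width from
    ``base_width - 1`` down to ``min_width``, each ending at the 3'
    terminus.  A 20-mer at defaults yields 16 + 3 = 19 windows.
    """
    s = str(seq if isinstance(seq, str) else seq.residues)
    if base_width < 1 or min_width < 1 or min_width > base_width:
        raise ValueError("require 1 <= min_width <= base_width")
    if len(s) < base_width:
        raise SequenceError(
            f"sequence length {len(s)} shorter than window width {base_width}"
        )
    windows = tuple(
        (start, width, gc_fraction(s[start:start + width]))
        for start, width in _window_starts(len(s), base_width, min_width)
    )
    return GcProfile(windows, len(s))


def group_profiles(
    spacers: Sequence[Spacer],
    responses: Sequence[float],
    n_groups: int = 3,
    base_width: int = 5,
    min_width: int = 2,
) -> list[dict]:
    """Mean GC profile (± standard error) per response group.

    Spacers are split into ``n_groups`` tertile-like groups by response
    rank (highest response first), groups as equal in size as possible,
    ties broken by stable input order.  Returns one dict per group with
    keys ``label``, ``members``, ``mean`` (GcProfile) and ``se``.
    """
    if len(spacers) != len(responses):
        raise ValueError("spacers and responses must align")
    if len(spacers) < n_groups:
        raise ValueError(f"need at least {n_groups} spacers for {n_groups} groups")
    lengths = {len(sp) for sp in spacers}
    if len(lengths) != 1:
        raise SequenceError("all spacers must have equal length for group profiles")

    order = sorted(range(len(spacers)), key=lambda i: (-responses[i], i))
    sizes = _balanced_sizes(len(spacers), n_groups)
    labels = ["high", "medium", "low"] if n_groups == 3 else [
        f"group{i + 1}" for i in range(n_groups)
    ]
    out = []
    pos = 0
    spans = _window_starts(lengths.pop(), base_width, min_width)
    for label, size in zip(labels, sizes):
        members = order[pos:pos + size]
        pos += size
        mat = np.array(
            [[gc_fraction(str(spacers[i].seq)[s:s + w]) for s, w in spans] for i in members]
        )
        mean = mat.mean(axis=0)
        se = (
            mat.std(axis=0, ddof=1) / math.sqrt(len(members))
            if len(members) > 1
            else np.zeros(mat.shape[1])
        )
        out.append(
            {
                "label": label,
                "members": [spacers[i].name for i in members],
                "mean": GcProfile(
                    tuple((s, w, m) for (s, w), m in zip(spans, mean)),
                    len(spacers[members[0]]),
                ),
                "se": np.asarray(se),
            }
        )
    return out


def _balanced_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 0 by convention when either side has
    zero variance (degenerate regression)."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def window_predictive_power(
    spacers: Sequence[Spacer],
    responses: Sequence[float],
    window_width: int = 3,
) -> WindowScan:
    """How predictive is the GC content of each short window of a response?

    Each spacer is divided into overlapping windows of ``window_width``
    (eighteen 3-nt windows for 20-nt spacers); for each window position a
    simple linear regression of response on window GC is fit across the
    library and its R² recorded, alongside the whole-sequence GC R².
    """
    if len(spacers) != len(responses) or len(spacers) < 3:
        raise ValueError("need >= 3 spacers with matching responses")
    lengths = {len(sp) for sp in spacers}
    if len(lengths) != 1:
        raise SequenceError("all spacers must have equal length")
    length = lengths.pop()
    if length < window_width:
        raise SequenceError("spacers shorter than the scan window")
    y = np.asarray(responses, dtype=float)
    r2s = []
    for start in range(length - window_width + 1):
        x = np.array(
            [gc_fraction(str(sp.seq)[start:start + window_width]) for sp in spacers]
        )
        r2s.append((start, _r_squared(x, y)))
    whole = _r_squared(np.array([sp.gc_fraction for sp in spacers]), y)
    return WindowScan(window_width, tuple(r2s), whole)


def anchor_3prime(
    seqs: Iterable["NucSequence | str"], target_length: int = 25
) -> AlignedSet:
    """Stack sequences anchored at their 3' ends.

    Sequences longer than ``target_length`` are truncated at the 5' end
    (keeping the 3'-most residues, the ones closest to the cleavage site);
    shorter ones are left-padded with gaps.
    """
    rows = []
    for s in seqs:
        text = str(s if isinstance(s, str) else s.residues)
        if not text:
            raise SequenceError("empty sequence in 3'-anchored stack")
        if len(text) >= target_length:
            rows.append(text[-target_length:])
        else:
            rows.append(GAP * (target_length - len(text)) + text)
    return AlignedSet(tuple(rows), anchor="3prime")


def _column_gc(aln: AlignedSet) -> np.ndarray:
    """Per-column GC over non-gap residues; NaN for all-gap columns."""
    out = np.full(aln.width, np.nan)
    for j in range(aln.width):
        col = [r[j] for r in aln.rows if r[j] != GAP]
        if col:
            out[j] = gc_fraction("".join(col))
    return out


def column_gc_profile(
    aln: AlignedSet, base_width: int = 5, min_width: int = 2
) -> GcProfile:
    """Sliding/shrinking window averaging applied to per-column GC.

    Gap residues are excluded from both numerator and denominator of each
    column; all-gap columns are missing and drop out of window means (a
    window of only missing columns is NaN).
    """
    col_gc = _column_gc(aln)
    if aln.width < base_width:
        raise SequenceError("alignment narrower than the base window")
    windows = []
    for start, width in _window_starts(aln.width, base_width, min_width):
        vals = col_gc[start:start + width]
        vals = vals[~np.isnan(vals)]
        windows.append((start, width, float(vals.mean()) if vals.size else float("nan")))
    return GcProfile(tuple(windows), aln.width)


_CODE_BY_BASESET = {bases: code for code, bases in IUPAC_DNA.items()}


def iupac_consensus(aln: AlignedSet, min_freq: float = 0.25) -> str:
    """Minimal IUPAC consensus of an alignment.

    Per column, the smallest degenerate code covering every base whose
    frequency among non-gap residues is at least ``min_freq``; all-gap
    columns give '-'.  The default threshold makes a 50/50 two-state
    column yield a two-fold code (C/T → Y).
    """
    out = []
    for j in range(aln.width):
        col = [r[j] for r in aln.rows if r[j] != GAP]
        if not col:
            out.append(GAP)
            continue
        counts: dict[str, float] = {}
        for c in col:
            for base in IUPAC_DNA[c]:
                counts[base] = counts.get(base, 0.0) + 1.0 / len(IUPAC_DNA[c])
        kept = frozenset(b for b, n in counts.items() if n / len(col) >= min_freq)
        if not kept:  # every base below threshold: fall back to the modal base
            kept = frozenset([max(counts, key=lambda b: counts[b])])
        out.append(_CODE_BY_BASESET[kept])
    return "".join(out)


def spacer_set_summary(seqs: Sequence["NucSequence | str"]) -> dict:
    """Count, mean/min/max GC and a per-decile histogram of a spacer set."""
    if not seqs:
        raise SequenceError("empty spacer set")
    gcs = np.array([gc_fraction(s) for s in seqs])
    hist = {}
    for d in range(11):
        lo, hi = d / 10 - 0.05, d / 10 + 0.05
        hist[d * 10] = int(((gcs >= lo) & (gcs < hi)).sum())
    return {
        "count": len(gcs),
        "mean_gc": float(gcs.mean()),
        "min_gc": float(gcs.min()),
        "max_gc": float(gcs.max()),
        "decile_histogram": hist,
    }


# ---------------------------------------------------------------------------
# I/O helpers


def read_aligned_fasta(path: "str | Path") -> AlignedSet:
    """Read a gapped (externally aligned) FASTA as an AlignedSet."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append(str(rec.seq).upper())
    return AlignedSet(tuple(rows), anchor="none")


def read_responses(path: "str | Path") -> pd.Series:
    """Two-column CSV (name, response) → Series indexed by name."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("responses CSV needs two columns: name, response")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str).values)
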