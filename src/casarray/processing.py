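"""Quantification of Cas12a array-processing efficiency from
electropherogram peak tables.

The Bioanalyzer reports one (fragment length, peak area) pair per RNA
species; area is proportional to RNA mass.  If processing of an array ran
to completion, the fraction of total RNA mass found in fully excised
single gRNAs would equal the length-weighted theoretical maximum, e.g.
(41 + 42)/(57 + 41 + 42 + 158) = 0.28 for a two-gRNA array without a
synSeparator (0.29 with AAAT at every cleavage site, which lengthens the
gRNAs to 45/46 nt).  Percent-of-maximum processing is the observed
single-gRNA mass fraction divided by that ceiling, ×100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .designer import FragmentModel

__all__ = [
    "PeakTable",
    "PeakAssignment",
    "ProcessingResult",
    "AmbiguousAssignmentError",
    "theoretical_max_fraction",
    "match_peaks",
    "normalize_replicates",
    "percent_of_max",
    "simulate_electropherogram",
    "read_peak_csv",
    "results_to_frame",
]

#: Sizing marker spiked into every Bioanalyzer run; never part of the array.
DEFAULT_MARKER_LENGTH = 25.0
#: Relative sizing tolerance when matching peaks to expected fragments.
DEFAULT_REL_TOLERANCE = 0.10


class AmbiguousAssignmentError(ValueError):
    """More expected fragments than peaks inside one tolerance cluster and
    no declared fragment group to absorb them."""


@dataclass(frozen=True)
class PeakTable:
    """Electropherogram peaks: (length in nt, area in arbitrary units)."""

    peaks: tuple[tuple[float, float], ...]
    sample_id: str = ""
    timepoint: float = float("nan")  # minutes

    def __post_init__(self) -> None:
        for length, area in self.peaks:
            if length <= 0:
                raise ValueError(f"non-positive peak length {length}")
            if area < 0:
                raise ValueError(f"negative peak area {area}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def areas(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    def scaled(self, factor: float) -> "PeakTable":
        return PeakTable(
            tuple((l, a * factor) for l, a in self.peaks), self.sample_id, self.timepoint
        )


@dataclass(frozen=True)
class PeakAssignment:
    """Per-peak classification: fragment index, 'marker' or 'unassigned'."""

    classes: tuple["int | str", ...]  # parallel to the table's peaks

    def fragment_peaks(self) -> list[tuple[int, int]]:
        """(peak index, fragment index) pairs."""
        return [(i, c) for i, c in enumerate(self.classes) if isinstance(c, int)]


@dataclass(frozen=True)
class ProcessingResult:
    observed_single_fraction: float
    theoretical_max_fraction: float
    percent_of_max: float = field(init=False)
    sample_id: str = ""
    timepoint: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 <= self.observed_single_fraction <= 1:
            raise ValueError("observed fraction outside [0, 1]")
        if not 0 < self.theoretical_max_fraction <= 1:
            raise ValueError("theoretical maximum outside (0, 1]")
        object.__setattr__(
            self,
            "percent_of_max",
            100.0 * self.observed_single_fraction / self.theoretical_max_fraction,
        )


def theoretical_max_fraction(model: FragmentModel) -> float:
    """Mass fraction of the transcript held in single gRNAs at complete
    processing, assuming RNA mass proportional to length."""
    if not model.single_grna_indices:
        raise ValueError("fragment model declares no single-gRNA fragments")
    return sum(model.single_lengths) / model.transcript_length


def match_peaks(
    table: PeakTable,
    model: FragmentModel,
    rel_tolerance: float = DEFAULT_REL_TOLERANCE,
    marker_length: float = DEFAULT_MARKER_LENGTH,
    fragment_groups: "Sequence[Sequence[int]] | None" = None,
) -> PeakAssignment:
    """Assign peaks to expected fragments by nearest length within a
    relative tolerance.

    The declared marker length is classed ``'marker'`` first and excluded
    from quantification.  Within each cluster of mutually-in-tolerance
    peaks and fragments, equal counts resolve one-to-one by sorted order;
    a single peak may absorb several fragments only when those fragments
    form a declared group (e.g. a co-migrating 41/42-nt doublet) —
    otherwise the ambiguity is an error listing the candidates.
    """
    if not table.peaks:
        raise ValueError("empty peak table")
    groups = [tuple(sorted(g)) for g in (fragment_groups or [])]
    expected = list(model.fragment_lengths)
    classes: list[int | str] = []
    candidates: list[list[int]] = []
    for length, _ in table.peaks:
        if marker_length and abs(length - marker_length) <= rel_tolerance * marker_length:
            classes.append("marker")
            candidates.append([])
            continue
        cands = [
            j for j, exp in enumerate(expected)
            if abs(length - exp) <= rel_tolerance * exp
        ]
        classes.append("unassigned")
        candidates.append(cands)

    # connected components over the peak<->fragment in-tolerance graph
    unresolved_peaks = [i for i, c in enumerate(classes) if c == "unassigned" and candidates[i]]
    frag_to_peaks: dict[int, list[int]] = {}
    for i in unresolved_peaks:
        for j in candidates[i]:
            frag_to_peaks.setdefault(j, []).append(i)

    seen_p: set[int] = set()
    for i in unresolved_peaks:
        if i in seen_p:
            continue
        comp_p, comp_f = {i}, set(candidates[i])
        frontier = list(candidates[i])
        while frontier:
            j = frontier.pop()
            for p in frag_to_peaks.get(j, []):
                if p not in comp_p:
                    comp_p.add(p)
                    for jj in candidates[p]:
                        if jj not in comp_f:
                            comp_f.add(jj)
                            frontier.append(jj)
        seen_p |= comp_p
        ps = sorted(comp_p, key=lambda p: table.peaks[p][0])
        fs = sorted(comp_f, key=lambda j: expected[j])
        if len(ps) == len(fs):
            for p, j in zip(ps, fs):
                classes[p] = j
        elif len(ps) < len(fs):
            grp = next((g for g in groups if set(fs) <= set(g)), None)
            if grp is not None and len(ps) == 1:
                classes[ps[0]] = fs[0]  # peak stands for the whole group
            else:
                raise AmbiguousAssignmentError(
                    f"{len(fs)} expected fragments {sorted(expected[j] for j in fs)} nt "
                    f"compete for {len(ps)} peak(s) at "
                    f"{[round(table.peaks[p][0], 1) for p in ps]} nt; declare a "
                    "fragment group or tighten the tolerance"
                )
        else:  # more peaks than fragments: nearest peaks win, rest unassigned
            order = sorted(ps, key=lambda p: min(abs(table.peaks[p][0] - expected[j]) for j in fs))
            chosen = sorted(order[: len(fs)], key=lambda p: table.peaks[p][0])
            for p, j in zip(chosen, fs):
                classes[p] = j
    return PeakAssignment(tuple(classes))


def normalize_replicates(tables: Sequence[PeakTable],
                         marker_length: float = DEFAULT_MARKER_LENGTH,
                         rel_tolerance: float = DEFAULT_REL_TOLERANCE) -> list[PeakTable]:
    """Scale replicate tables to the replicate with the lowest total RNA.

    Marker peaks are excluded from the totals; after scaling, every
    table's non-marker total equals the smallest original total.
    """
    if not tables:
        raise ValueError("no tables to normalize")

    def non_marker_total(t: PeakTable) -> float:
        return sum(
            a for l, a in t.peaks
            if not (marker_length and abs(l - marker_length) <= rel_tolerance * marker_length)
        )

    totals = [non_marker_total(t) for t in tables]
    if any(tot == 0 for tot in totals):
        raise ValueError("a replicate has zero total (non-marker) peak area")
    target = min(totals)
    return [t.scaled(target / tot) for t, tot in zip(tables, totals)]


def percent_of_max(
    table: PeakTable,
    model: FragmentModel,
    rel_tolerance: float = DEFAULT_REL_TOLERANCE,
    marker_length: float = DEFAULT_MARKER_LENGTH,
    fragment_groups: "Sequence[Sequence[int]] | None" = None,
) -> ProcessingResult:
    """Percent of the maximum possible processing reached by a sample.

    Observed single-gRNA fraction = area matched to single-gRNA fragments
    (a group peak counts if the group contains a single-gRNA fragment)
    over the total non-marker area; divided by the theoretical maximum.
    """
    assignment = match_peaks(table, model, rel_tolerance, marker_length, fragment_groups)
    singles = set(model.single_grna_indices)
    groups = [tuple(sorted(g)) for g in (fragment_groups or [])]
    single_area = 0.0
    total_area = 0.0
    for (length, area), cls in zip(table.peaks, assignment.classes):
        if cls == "marker":
            continue
        total_area += area
        if isinstance(cls, int):
            in_singles = cls in singles or any(
                cls in g and set(g) & singles for g in groups
            )
            if in_singles:
                single_area += area
    if total_area == 0:
        raise ValueError("zero total non-marker area")
    return ProcessingResult(
        observed_single_fraction=single_area / total_area,
        theoretical_max_fraction=theoretical_max_fraction(model),
        sample_id=table.sample_id,
        timepoint=table.timepoint,
    )


def simulate_electropherogram(
    model: FragmentModel,
    completeness: float,
    seed: int,
    marker_length: float = DEFAULT_MARKER_LENGTH,
    marker_area: float = 50.0,
    area_noise: float = 0.02,
    sizing_noise: float = 0.005,
    sample_id: str = "synthetic",
    timepoint: float = float("nan"),
) -> PeakTable:
    """Synthetic peak table for an array processed to a given completeness.

    A fraction ``completeness`` of the transcript pool is fully cleaved
    (one peak per fragment, area ∝ fragment length); the remainder stays
    intact (one peak at the full transcript length).  Multiplicative
    Gaussian noise perturbs areas and sizing; a marker peak is added.
    Intermediate (partially processed) species are not modeled — the
    recovered percent-of-max is then ``100·completeness`` up to noise.
    """
    if not 0 <= completeness <= 1:
        raise ValueError("completeness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    peaks: list[tuple[float, float]] = []
    for length in model.fragment_lengths:
        area = completeness * length
        if area > 0:
            area *= 1 + area_noise * rng.standard_normal()
            size = length * (1 + sizing_noise * rng.standard_normal())
            peaks.append((max(size, 1e-3), max(area, 0.0)))
    intact = (1 - completeness) * model.transcript_length
    if intact > 0:
        intact *= 1 + area_noise * rng.standard_normal()
        size = model.transcript_length * (1 + sizing_noise * rng.standard_normal())
        peaks.append((size, max(intact, 0.0)))
    peaks.append((marker_length, marker_area))
    return PeakTable(tuple(peaks), sample_id=sample_id, timepoint=timepoint)


def read_peak_csv(path: "str | Path") -> list[PeakTable]:
    """Read peak tables from CSV (length_nt, area[, sample_id, timepoint]),
    one PeakTable per sample_id/timepoint combination."""
    df = pd.read_csv(path)
    missing = {"length_nt", "area"} - set(df.columns)
    if missing:
        raise ValueError(f"peak CSV missing column(s): {sorted(missing)}")
    if "sample_id" not in df.columns:
        df["sample_id"] = ""
    if "timepoint" not in df.columns:
        df["timepoint"] = float("nan")
    tables = []
    for (sample, tp), grp in df.groupby(["sample_id", "timepoint"], dropna=False, sort=False):
        tables.append(
            PeakTable(
                tuple(zip(grp["length_nt"].astype(float), grp["area"].astype(float))),
                sample_id=str(sample),
                timepoint=float(tp) if pd.notna(tp) else float("nan"),
            )
        )
    return tables


def results_to_frame(results: Sequence[ProcessingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in results],
            "timepoint": [r.timepoint for r in results],
            "observed_fraction": [r.observed_single_fraction for r in results],
            "theoretical_max": [r.theoretical_max_fraction for r in results],
            "percent_of_max": [r.percent_of_max for r in results],
        }
    )
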