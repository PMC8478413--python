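"""Sliding-window GC statistics, window-scan regression and profiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casarray.seqcore import Spacer, gc_fraction, normalize_sequence
from casarray.seqstats import (
    AlignedSet,
    anchor_3prime,
    column_gc_profile,
    group_profiles,
    iupac_consensus,
    sliding_gc,
    spacer_set_summary,
    window_predictive_power,
)
from casarray import generate_spacer

dna_text = st.text(alphabet="ACGT", min_size=5, max_size=40)


def brute_force_windows(s, base_width=5, min_width=2):
    spans = [(i, base_width) for i in range(len(s) - base_width + 1)]
    spans += [(len(s) - w, w) for w in range(base_width - 1, min_width - 1, -1)]
    return [
        (start, w, sum(c in "GC" for c in s[start:start + w]) / w)
        for start, w in spans
    ]


class TestSlidingGc:
    def test_poly_a_flat_zero(self):
        prof = sliding_gc("A" * 20)
        assert len(prof) == 19
        assert np.all(prof.gc == 0.0)

    def test_window_count_20mer(self):
        prof = sliding_gc("ACGT" * 5)
        assert len(prof) == (20 - 5 + 1) + 3

    def test_matches_brute_force(self):
        s = "ATGCGCATATATATATATAT"
        prof = sliding_gc(s)
        assert list(prof.windows) == [
            (a, b, pytest.approx(c)) for a, b, c in brute_force_windows(s)
        ]

    @given(dna_text)
    @settings(deadline=None)
    def test_window_count_formula(self, s):
        base, mn = 5, 2
        prof = sliding_gc(s, base, mn)
        assert len(prof) == (len(s) - base + 1) + (base - mn)

    def test_too_short_rejected(self):
        with pytest.raises(Exception):
            sliding_gc("ACG", base_width=5)

    def test_shrunken_windows_anchor_3prime(self):
        s = "A" * 15 + "GGGGG"
        prof = sliding_gc(s)
        shrunk = [w for w in prof.windows if w[1] < 5]
        assert [(s0 + w, gc) for s0, w, gc in shrunk] == [(20, 1.0)] * 3


class TestGroupProfiles:
    def test_identical_spacers_zero_se(self):
        sp = [Spacer(f"s{i}", normalize_sequence("ACGT" * 5)) for i in range(6)]
        groups = group_profiles(sp, [1, 2, 3, 4, 5, 6])
        single = sliding_gc("ACGT" * 5)
        for g in groups:
            assert np.allclose(g["mean"].gc, single.gc)
            assert np.all(g["se"] == 0)

    def test_singleton_groups(self):
        sp = [Spacer(f"s{i}", generate_spacer(20, 0.5, i).seq) for i in range(3)]
        groups = group_profiles(sp, [3.0, 2.0, 1.0])
        assert [g["members"] for g in groups] == [["s0"], ["s1"], ["s2"]]
        assert all(np.all(g["se"] == 0) for g in groups)

    def test_low_gc_spacers_occupy_high_response_group(self, library51):
        spacers = list(library51)
        responses = [1 - sp.gc_fraction for sp in spacers]
        groups = group_profiles(spacers, responses)
        # direct sort oracle: the 17 highest-response names
        expect_high = {
            sp.name
            for sp in sorted(
                spacers, key=lambda s: (-(1 - s.gc_fraction), spacers.index(s))
            )[:17]
        }
        assert groups[0]["label"] == "high"
        assert set(groups[0]["members"]) == expect_high
        mean_gc_high = np.mean([sp.gc_fraction for sp in spacers if sp.name in expect_high])
        mean_gc_low = np.mean([sp.gc_fraction for sp in spacers if sp.name in set(groups[2]["members"])])
        assert mean_gc_high < mean_gc_low

    def test_fewer_spacers_than_groups(self):
        sp = [Spacer("a", normalize_sequence("ACGTACGTACGTACGTACGT"))]
        with pytest.raises(ValueError):
            group_profiles(sp, [1.0])


def lstsq_r2(x, y):
    """Independent least-squares oracle: R² from normal-equations residuals."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1 - np.sum(resid**2) / ss_tot


class TestWindowPredictivePower:
    def test_eighteen_windows_for_20mers(self, library51):
        scan = window_predictive_power(list(library51), np.arange(51.0))
        assert len(scan.r2_by_window) == 18

    def test_perfect_fit_at_target_window(self, library51):
        spacers = list(library51)
        k = 7
        y = [
            3.0 - 2.0 * gc_fraction(str(sp.seq)[k:k + 3]) for sp in spacers
        ]
        scan = window_predictive_power(spacers, y)
        assert dict(scan.r2_by_window)[k] == pytest.approx(1.0)

    def test_constant_response_all_zero(self, library51):
        scan = window_predictive_power(list(library51), [2.0] * 51)
        assert all(r2 == 0.0 for _, r2 in scan.r2_by_window)
        assert scan.whole_sequence_r2 == 0.0

    def test_matches_lstsq_oracle(self, library51):
        rng = np.random.default_rng(5)
        spacers = list(library51)
        y = rng.random(51)
        scan = window_predictive_power(spacers, y)
        for start, r2 in scan.r2_by_window:
            x = np.array([gc_fraction(str(sp.seq)[start:start + 3]) for sp in spacers])
            if np.ptp(x) > 0:
                assert r2 == pytest.approx(lstsq_r2(x, y), abs=1e-10)

    def test_affine_response_invariance(self, library51):
        rng = np.random.default_rng(6)
        y = rng.random(51)
        a = window_predictive_power(list(library51), y)
        b = window_predictive_power(list(library51), 7.0 - 3.0 * y)
        for (s1, r1), (s2, r2) in zip(a.r2_by_window, b.r2_by_window):
            assert (s1, pytest.approx(r1)) == (s2, r2)

    def test_terminal_window_wins_for_terminal_gc_response(self, library51):
        rng = np.random.default_rng(11)
        spacers = list(library51)
        y = [1 - sp.terminal_gc_k3 + 0.05 * rng.standard_normal() for sp in spacers]
        scan = window_predictive_power(spacers, y)
        assert scan.best_window()[0] == 17  # the last 3-nt window


class TestAnchor3Prime:
    def test_truncates_long(self):
        s = "".join(np.random.default_rng(0).choice(list("ACGT"), 36))
        aln = anchor_3prime([s])
        assert aln.rows[0] == s[-25:]

    def test_keeps_exact_and_pads_short(self):
        aln = anchor_3prime(["ACGT" * 6 + "A", "ACGT" * 5])
        assert aln.rows[0] == "ACGT" * 6 + "A"
        assert aln.rows[1] == "-" * 5 + "ACGT" * 5
        assert aln.anchor == "3prime"

    @given(st.lists(dna_text, min_size=1, max_size=8))
    @settings(deadline=None)
    def test_preserves_3prime_terminus(self, seqs):
        aln = anchor_3prime(seqs)
        for row, s in zip(aln.rows, seqs):
            assert row[-1] == s[-1]


class TestColumnGc:
    def test_all_g_rows(self):
        aln = AlignedSet(("G" * 8, "G" * 8))
        prof = column_gc_profile(aln)
        assert np.all(prof.gc == 1.0)

    def test_two_row_mixture(self):
        aln = AlignedSet(("ATATAT", "GCGCGC"))
        prof = column_gc_profile(aln, base_width=5)
        assert np.all(prof.gc == 0.5)

    def test_gapped_matches_brute_force(self):
        rows = ("AC-GT-", "A-GG--", "TCCG-A")
        aln = AlignedSet(rows)
        col_gc = []
        for j in range(6):
            col = [r[j] for r in rows if r[j] != "-"]
            col_gc.append(
                sum(c in "GC" for c in col) / len(col) if col else np.nan
            )
        prof = column_gc_profile(aln, base_width=5)
        for start, width, gc in prof.windows:
            vals = [v for v in col_gc[start:start + width] if not np.isnan(v)]
            assert gc == pytest.approx(np.mean(vals))


class TestConsensus:
    def test_gtyta(self):
        assert iupac_consensus(AlignedSet(("GTCTA", "GTTTA"))) == "GTYTA"

    def test_identical_rows(self):
        assert iupac_consensus(AlignedSet(("ACGT",) * 3)) == "ACGT"

    def test_full_degeneracy(self):
        aln = AlignedSet(("A", "C", "G", "T"))
        assert iupac_consensus(aln) == "N"

    def test_all_gap_column(self):
        assert iupac_consensus(AlignedSet(("A-", "C-"))) == "M-"

    @given(st.lists(st.text(alphabet="ACGT", min_size=4, max_size=4), min_size=1, max_size=5))
    @settings(deadline=None)
    def test_idempotent_under_row_duplication(self, rows):
        once = iupac_consensus(AlignedSet(tuple(rows)))
        doubled = iupac_consensus(AlignedSet(tuple(rows + rows)))
        assert once == doubled


class TestSpacerSetSummary:
    def test_simple(self):
        out = spacer_set_summary(["AAAA", "GGGG"])
        assert out["mean_gc"] == 0.5
        assert (out["min_gc"], out["max_gc"]) == (0.0, 1.0)
        assert out["count"] == 2

    def test_single_sequence_degenerate_range(self):
        out = spacer_set_summary(["ATGC"])
        assert out["min_gc"] == out["max_gc"] == out["mean_gc"] == 0.5

    def test_generated_set_mean_matches_target(self):
        seqs = [generate_spacer(25, 0.39, s).seq for s in range(1000)]
        out = spacer_set_summary(seqs)
        # exact-count construction: round(0.39*25)=10 GC per spacer
        assert out["mean_gc"] == pytest.approx(10 / 25)
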