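"""Array construction, separator policies, fragment prediction, poly-A scan."""

import numpy as np
import pytest
from Bio import SeqIO
from hypothesis import given, settings, strategies as st

from casarray.seqcore import NucSequence, SequenceError, Spacer, normalize_sequence
from casarray import generate_spacer
from casarray.designer import (
    DEFAULT_POLYA_MOTIFS,
    FULL,
    ArrayDesign,
    FragmentModel,
    SeparatorPolicy,
    build_array,
    design_report,
    polya_scan,
    predicted_fragments,
)


@pytest.fixture
def two_spacers():
    return [
        Spacer("dummy", generate_spacer(20, 0.7, 1).seq),
        Spacer("gfp", generate_spacer(20, 0.45, 2).seq),
    ]


class TestBuildArray:
    def test_aaat_everywhere_three_separators(self, two_spacers, lb_profile):
        arr = build_array(two_spacers, lb_profile)  # default policy: AAAT at all sites
        assert len(arr.features_of("repeat")) == 3
        seps = arr.features_of("separator")
        assert len(seps) == 3
        assert all(arr.feature_seq(f) == "AAAT" for f in seps)
        # every separator sits immediately upstream of a repeat
        repeat_starts = {f.start for f in arr.features_of("repeat")}
        assert all(f.end in repeat_starts for f in seps)

    def test_no_separators_is_plain_concatenation(self, two_spacers, lb_profile):
        arr = build_array(
            two_spacers, lb_profile, SeparatorPolicy.none(3),
            leader="AAACCC", three_prime_flank="GGTT",
        )
        rep = lb_profile.mature_repeat.residues
        expect = (
            "AAACCC" + rep + two_spacers[0].seq.residues
            + rep + two_spacers[1].seq.residues + rep + "GGTT"
        )
        assert arr.sequence.residues == expect
        assert not arr.features_of("separator")

    def test_trailing_site_only(self, two_spacers, lb_profile):
        arr = build_array(
            two_spacers, lb_profile, SeparatorPolicy((None, None, "AAAT"))
        )
        seps = arr.features_of("separator")
        assert len(seps) == 1
        spacer2 = arr.features_of("spacer")[1]
        assert seps[0].start == spacer2.end  # 3' of the last spacer

    def test_full_separator_policy(self, two_spacers, lb_profile):
        arr = build_array(
            two_spacers, lb_profile, SeparatorPolicy.uniform(FULL, 3)
        )
        seps = arr.features_of("separator")
        assert all(
            arr.feature_seq(f) == lb_profile.full_separator.residues for f in seps
        )

    def test_policy_mismatch_rejected(self, two_spacers, lb_profile):
        with pytest.raises(SequenceError):
            build_array(two_spacers, lb_profile, SeparatorPolicy.none(2))

    def test_empty_spacers_rejected(self, lb_profile):
        with pytest.raises(SequenceError):
            build_array([], lb_profile)

    def test_features_tile_sequence(self, two_spacers, lb_profile):
        arr = build_array(two_spacers, lb_profile, leader="A" * 30, three_prime_flank="C" * 10)
        pos = 0
        for f in arr.features:
            assert f.start == pos
            pos = f.end
        assert pos == len(arr)

    def test_genbank_round_trip(self, two_spacers, lb_profile, tmp_path):
        arr = build_array(two_spacers, lb_profile, leader="A" * 30, three_prime_flank="C" * 10)
        path = tmp_path / "arr.gb"
        arr.to_genbank(path)
        rec = SeqIO.read(str(path), "genbank")
        assert str(rec.seq) == arr.sequence.residues
        got = sorted(
            (int(f.location.start), int(f.location.end), f.type) for f in rec.features
        )
        want = sorted((f.start, f.end, f.kind) for f in arr.features)
        assert got == want


def _worked_example_design(lb_profile, policy):
    """Two-gRNA assay layout: 57-nt leader, 41/42-nt gRNA units (21-nt
    repeat + 20/21-nt spacers), trailing repeat + flank totalling 158 nt."""
    profile21 = type(lb_profile)(
        species_name="Lb21",
        mature_repeat=normalize_sequence("AATTTCTACTAAGTGTAGATT"),  # 21 nt
        full_separator=lb_profile.full_separator,
        default_synseparator=lb_profile.default_synseparator,
    )
    spacers = [
        Spacer("dummy", generate_spacer(20, 0.7, 1).seq),
        Spacer("gfp", generate_spacer(21, 0.45, 2).seq),
    ]
    return build_array(
        spacers, profile21, policy,
        leader="A" * 57, three_prime_flank="C" * 137,
    )


class TestPredictedFragments:
    def test_worked_lengths_without_separator(self, lb_profile):
        arr = _worked_example_design(lb_profile, SeparatorPolicy.none(3))
        model = predicted_fragments(arr)
        assert model.fragment_lengths == (57, 41, 42, 158)
        assert model.single_grna_indices == (1, 2)

    def test_worked_lengths_with_aaat(self, lb_profile):
        arr = _worked_example_design(lb_profile, SeparatorPolicy.uniform("AAAT", 3))
        model = predicted_fragments(arr)
        assert model.fragment_lengths == (61, 45, 46, 158)
        assert model.single_grna_indices == (1, 2)

    def test_single_spacer_no_trailing_two_fragments(self, lb_profile):
        arr = build_array(
            [Spacer("only", generate_spacer(20, 0.3, 5).seq)],
            lb_profile,
            SeparatorPolicy.uniform("AAAT", 1),
            include_trailing_repeat=False,
            leader="A" * 10,
        )
        model = predicted_fragments(arr)
        assert len(model.fragment_lengths) == 2

    def test_lengths_sum_to_transcript(self, two_spacers, lb_profile):
        for policy in (
            SeparatorPolicy.none(3),
            SeparatorPolicy.uniform("AAAT", 3),
            SeparatorPolicy(("G", None, "AAAT")),
        ):
            arr = build_array(two_spacers, lb_profile, policy, leader="A" * 8)
            model = predicted_fragments(arr)
            assert sum(model.fragment_lengths) == len(arr)

    def test_aaat_adds_exactly_four_everywhere(self, lb_profile):
        bare = predicted_fragments(_worked_example_design(lb_profile, SeparatorPolicy.none(3)))
        syn = predicted_fragments(
            _worked_example_design(lb_profile, SeparatorPolicy.uniform("AAAT", 3))
        )
        assert syn.fragment_lengths[0] == bare.fragment_lengths[0] + 4  # leader
        for i in bare.single_grna_indices:
            assert syn.fragment_lengths[i] == bare.fragment_lengths[i] + 4


def naive_polya(s, motifs):
    hits = []
    for i in range(len(s)):
        for m in motifs:
            if s[i:i + len(m)] == m:
                hits.append((i, m))
    return sorted(hits)


class TestPolyaScan:
    def test_single_hit(self):
        assert polya_scan("GGGAATAAAGGG") == [(3, "AATAAA")]

    def test_gc_sequence_clean(self):
        assert polya_scan("GC" * 30) == []

    def test_overlapping_and_oracle(self):
        s = "AATAATAAA"
        assert polya_scan(s) == naive_polya(s, DEFAULT_POLYA_MOTIFS)
        assert (3, "AATAAA") in polya_scan(s)

    @given(st.text(alphabet="ACGT", min_size=6, max_size=80))
    @settings(deadline=None, max_examples=80)
    def test_matches_naive_oracle(self, s):
        assert polya_scan(s) == naive_polya(s, DEFAULT_POLYA_MOTIFS)


class TestDesignReport:
    def test_clean_low_gc_design(self, lb_profile):
        spacers = [
            Spacer("s1", normalize_sequence("ACCGTTACCGTTACCGTCAT")),
            Spacer("s2", normalize_sequence("TGGCACTGGCACTGGCTTGA")),
        ]
        arr = build_array(spacers, lb_profile, SeparatorPolicy.none(3))
        rep = design_report(arr, backend="oracle")
        assert rep["polya_hits"] == []
        assert (rep["spacer_risk"]["flag"] != "HIGH").all()

    def test_polya_inside_spacer_is_located(self, lb_profile):
        spacers = [
            Spacer("bad", normalize_sequence("CGCGCAATAAACGCGCGCGC")),
            Spacer("ok", normalize_sequence("ACCGTTACCGTTACCGTCAT")),
        ]
        arr = build_array(spacers, lb_profile, SeparatorPolicy.none(3))
        rep = design_report(arr, backend="oracle")
        spacer_hits = [h for h in rep["polya_hits"] if h["feature"] == "spacer"]
        assert any(h["name"] == "bad" for h in spacer_hits)

    def test_seven_spacer_array_counts(self, lb_profile):
        spacers = [
            Spacer(f"g{i}", generate_spacer(20, 0.4, 100 + i).seq) for i in range(7)
        ]
        arr = build_array(spacers, lb_profile)  # AAAT policy, trailing repeat
        rep = design_report(arr, backend="oracle")
        assert rep["n_repeats"] == 8
        assert rep["n_separators"] == 8


class TestFragmentModel:
    def test_index_validation(self):
        with pytest.raises(ValueError):
            FragmentModel((10, 20), (5,))

    def test_transcript_length(self):
        m = FragmentModel((57, 41, 42, 158), (1, 2))
        assert m.transcript_length == 298
        assert m.single_lengths == (41, 42)
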