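"""Locus clustering and selection against brute-force oracles."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locusforge.evidence_scoring import (
    EvidenceScores,
    HomologyScore,
    WeightConfig,
    compute_scores,
)
from locusforge.intervals import intervals_overlap_any
from locusforge.io_formats import JunctionRecord, TranscriptModel
from locusforge.locus_selection import (
    BELOW_THRESHOLD,
    JOIN_SUSPECT,
    Locus,
    OverrideConflictError,
    cluster_loci,
    flag_join_candidates,
    iterate_selection,
    select_best,
    validate_alt_transcripts,
)

from conftest import iv, mk_model


def brute_force_components(models):
    """Oracle: connected components of same-strand CDS overlap by closure."""
    groups = []
    for m in models:
        linked = [
            g
            for g in groups
            if any(
                o.seq_id == m.seq_id
                and o.strand == m.strand
                and intervals_overlap_any(o.cds, m.cds)
                for o in g
            )
        ]
        merged = [m]
        for g in linked:
            merged.extend(g)
            groups.remove(g)
        groups.append(merged)
    return {frozenset(x.model_id for x in g) for g in groups}


class TestClusterLoci:
    def test_same_strand_overlap_is_one_locus(self):
        a = mk_model("a", [(100, 300)], [(150, 250)])
        b = mk_model("b", [(200, 400)], [(200, 350)])
        assert len(cluster_loci([a, b])) == 1

    def test_opposite_strands_stay_separate(self):
        a = mk_model("a", [(100, 300)], [(150, 250)], strand="+")
        b = mk_model("b", [(100, 300)], [(150, 250)], strand="-")
        loci = cluster_loci([a, b])
        assert len(loci) == 2

    def test_transitive_chain_single_linkage(self):
        a = mk_model("a", [(100, 200)], [(100, 200)])
        b = mk_model("b", [(150, 350)], [(150, 350)])
        c = mk_model("c", [(300, 400)], [(300, 400)])
        loci = cluster_loci([a, b, c])
        assert len(loci) == 1
        assert sorted(loci[0].members) == ["a", "b", "c"]
        assert not intervals_overlap_any(a.cds, c.cds)  # A and C disjoint

    def test_cdsless_models_become_singletons(self):
        a = mk_model("a", [(100, 300)], [(150, 250)])
        nc = mk_model("nc", [(150, 250)])
        loci = cluster_loci([a, nc])
        assert len(loci) == 2

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 120), st.integers(5, 40), st.sampled_from("+-")
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_partition_matches_connected_components_oracle(self, specs):
        models = [
            mk_model(f"m{i}", [(s, s + l)], [(s, s + l)], strand=strand)
            for i, (s, l, strand) in enumerate(specs)
        ]
        got = {frozenset(l.members) for l in cluster_loci(models)}
        assert got == brute_force_components(models)


def scores_for(members, totals, bits=None):
    return {
        mid: EvidenceScores(
            mid,
            total=t,
            homology=HomologyScore(best_bits=(bits or {}).get(mid, 0.0)),
        )
        for mid, t in zip(members, totals)
    }


def one_locus(members):
    return [Locus("L1", "chr1", "+", list(members), [])]


class TestSelectBest:
    def test_singleton_above_threshold_selected(self):
        m = mk_model("a", [(1, 100)], [(1, 100)])
        res = select_best(one_locus(["a"]), scores_for(["a"], [0.5]), [m])
        assert res.selections["L1"].selected == "a"

    def test_singleton_below_threshold_flagged(self):
        m = mk_model("a", [(1, 100)], [(1, 100)])
        res = select_best(one_locus(["a"]), scores_for(["a"], [0.05]), [m])
        sel = res.selections["L1"]
        assert sel.selected is None
        assert BELOW_THRESHOLD in sel.flags

    def test_five_member_locus_matches_exhaustive_argmax(self):
        members = [f"m{i}" for i in range(5)]
        totals = [0.4, 0.9, 0.7, 0.9, 0.2]
        bits = {"m1": 120.0, "m3": 80.0}
        models = [mk_model(m, [(1, 100)], [(1, 100)]) for m in members]
        scores = scores_for(members, totals, bits)
        res = select_best(one_locus(members), scores, models)
        # oracle: max total, tie broken by homology bits
        best = max(
            members,
            key=lambda m: (scores[m].total, scores[m].homology.best_bits, m),
        )
        oracle = max(t for t in totals)
        assert scores[res.selections["L1"].selected].total == oracle
        assert res.selections["L1"].selected == "m1" == best

    @given(
        st.lists(
            st.floats(0, 2, allow_nan=False), min_size=1, max_size=8
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_selection_equals_bruteforce_on_random_scores(self, totals):
        members = [f"m{i}" for i in range(len(totals))]
        models = [mk_model(m, [(1, 100)], [(1, 100)]) for m in members]
        scores = scores_for(members, totals)
        w = WeightConfig(min_threshold=0.1)
        res = select_best(one_locus(members), scores, models, w)
        eligible = [m for m in members if scores[m].total >= w.min_threshold]
        sel = res.selections["L1"].selected
        if not eligible:
            assert sel is None
        else:
            best_total = max(scores[m].total for m in eligible)
            assert scores[sel].total == best_total


class TestJoinFlag:
    def build(self, join_bits):
        a = mk_model("a", [(100, 300)], [(100, 300)])
        b = mk_model("b", [(600, 900)], [(600, 900)])
        j = mk_model("j", [(100, 300), (600, 900)], [(100, 300), (600, 900)])
        scores = scores_for(
            ["a", "b", "j"],
            [2.0, 1.8, 1.0],
            {"a": 310.0, "b": 250.0, "j": join_bits},
        )
        loci = cluster_loci([a, b, j])
        res = select_best(loci, scores, [a, b, j])
        return flag_join_candidates(res, [a, b, j], scores), loci

    def test_low_bitscore_spanning_model_is_flagged(self):
        res, loci = self.build(join_bits=300.0)
        assert len(loci) == 1  # the chimera merges both genes
        assert JOIN_SUSPECT in res.model_flags.get("j", set())

    def test_high_bitscore_spanning_model_not_flagged(self):
        res, _ = self.build(join_bits=700.0)
        assert JOIN_SUSPECT not in res.model_flags.get("j", set())

    def test_non_spanning_model_not_flagged(self):
        a = mk_model("a", [(100, 300)], [(100, 300)])
        a2 = mk_model("a2", [(120, 310)], [(120, 310)])
        scores = scores_for(["a", "a2"], [2.0, 1.5], {"a": 300.0, "a2": 200.0})
        loci = cluster_loci([a, a2])
        res = select_best(loci, scores, [a, a2])
        flag_join_candidates(res, [a, a2], scores)
        assert res.model_flags == {}


class TestAltTranscripts:
    def setup_method(self):
        self.primary = mk_model(
            "p", [(100, 200), (300, 400), (500, 600)], [(120, 200), (300, 400), (500, 580)]
        )
        self.locus = Locus("L1", "chr1", "+", ["p"], list(self.primary.cds))
        self.junctions = [
            JunctionRecord(i, 10) for i in self.primary.introns
        ] + [JunctionRecord(iv(201, 499), 8)]  # exon-skipping junction

    def test_identical_chain_rejected(self):
        clone = mk_model(
            "asm1", [(100, 200), (300, 400), (500, 600)], [(120, 200)]
        )
        assert (
            validate_alt_transcripts(self.locus, self.primary, [clone], self.junctions)
            == []
        )

    def test_novel_validated_chain_accepted(self):
        skip = mk_model("asm2", [(100, 200), (500, 600)], [(120, 200), (500, 580)])
        accepted = validate_alt_transcripts(
            self.locus, self.primary, [skip], self.junctions
        )
        assert [m.model_id for m in accepted] == ["asm2"]

    def test_unvalidated_distinguishing_intron_rejected(self):
        shifted = mk_model(
            "asm3", [(100, 200), (320, 400), (500, 600)], [(120, 200)]
        )
        assert (
            validate_alt_transcripts(
                self.locus, self.primary, [shifted], self.junctions
            )
            == []
        )

    def test_duplicate_chains_accepted_once_in_id_order(self):
        skip_a = mk_model("asmA", [(100, 200), (500, 600)], [(120, 200)])
        skip_b = mk_model("asmB", [(100, 200), (500, 600)], [(120, 200)])
        accepted = validate_alt_transcripts(
            self.locus, self.primary, [skip_b, skip_a], self.junctions
        )
        assert [m.model_id for m in accepted] == ["asmA"]


class TestIterateSelection:
    def test_idempotent_without_overrides(self, small_fixture):
        models = small_fixture.all_candidates
        r1 = iterate_selection(models, small_fixture.bundle)
        r2 = iterate_selection(models, small_fixture.bundle)
        assert r1.selected_ids() == r2.selected_ids()
        assert {k: s.flags for k, s in r1.selections.items()} == {
            k: s.flags for k, s in r2.selections.items()
        }

    def test_force_keep_overrides_score(self, small_fixture):
        models = small_fixture.all_candidates
        base = iterate_selection(models, small_fixture.bundle)
        locus = next(
            loc for loc in base.loci if len(loc.members) >= 2
            and base.selections[loc.locus_id].selected is not None
        )
        loser = next(
            m
            for m in locus.members
            if m != base.selections[locus.locus_id].selected
        )
        forced = iterate_selection(
            models, small_fixture.bundle, overrides={loser: "force_keep"}
        )
        assert forced.selections[locus.locus_id].selected == loser

    def test_force_drop_removes_model(self, small_fixture):
        models = small_fixture.all_candidates
        base = iterate_selection(models, small_fixture.bundle)
        winner = base.selected_ids()[0]
        dropped = iterate_selection(
            models, small_fixture.bundle, overrides={winner: "force_drop"}
        )
        assert winner not in dropped.selected_ids()

    def test_conflicting_overrides_raise(self):
        a = mk_model("a", [(100, 300)], [(150, 250)])
        b = mk_model("b", [(200, 400)], [(200, 350)])
        from locusforge.io_formats import EvidenceBundle

        with pytest.raises(OverrideConflictError, match="a.*b|b.*a"):
            iterate_selection(
                [a, b],
                EvidenceBundle(),
                overrides={"a": "force_keep", "b": "force_keep"},
            )

    def test_selected_models_do_not_share_cds(self, small_fixture):
        models = small_fixture.all_candidates
        res = iterate_selection(models, small_fixture.bundle)
        by_id = {m.model_id: m for m in models}
        chosen = [by_id[mid] for mid in res.selected_ids()]
        for m1, m2 in itertools.combinations(chosen, 2):
            if m1.seq_id == m2.seq_id and m1.strand == m2.strand:
                assert not intervals_overlap_any(m1.cds, m2.cds)
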