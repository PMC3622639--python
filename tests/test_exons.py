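from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isocover.alignments import ReadStore
from isocover.core import AlignedRead, FragmentStats, Region
from isocover.exons import (
    CandidateExon,
    Interval,
    RegionEvidence,
    build_and_solve_lp,
    chain_distance_range,
    enumerate_candidate_exons,
    is_feasible_combination,
    pair_feasibility_penalty,
    partition_intervals,
    select_exon_set,
)

from oracles import lp_objective_oracle


def make_intervals(lengths, coverages, start=0):
    out, pos = [], start
    for j, (length, cov) in enumerate(zip(lengths, coverages)):
        out.append(Interval(index=j, start=pos, end=pos + length, mean_coverage=cov))
        pos += length
    return out


def exon_over(intervals, a, b, left="region_edge", right="region_edge"):
    return CandidateExon(
        start=intervals[a].start, end=intervals[b].end,
        first_j=a, last_j=b, left_kind=left, right_kind=right,
    )


def empty_evidence():
    return RegionEvidence(requirements=[], pair_points=[], pair_classes={}, n_pairs=0)


class TestPartitionIntervals:
    def test_four_boundaries_give_five_intervals(self):
        region = Region(contig="c", start=0, end=500)
        ivs = partition_intervals(region, [100, 200, 300, 400], ReadStore())
        assert len(ivs) == 5
        assert [(iv.start, iv.end) for iv in ivs] == [
            (0, 100), (100, 200), (200, 300), (300, 400), (400, 500)
        ]

    def test_zero_boundaries_give_whole_region(self):
        region = Region(contig="c", start=50, end=250)
        (iv,) = partition_intervals(region, [], ReadStore())
        assert (iv.start, iv.end) == (50, 250)

    def test_mean_coverage_is_aligned_bases_per_length(self):
        store = ReadStore(
            reads=[AlignedRead(read_id="r", contig="c", strand=".", blocks=((0, 50),))]
        )
        region = Region(contig="c", start=0, end=100, read_ids=[0])
        (iv,) = partition_intervals(region, [], store)
        assert iv.mean_coverage == pytest.approx(0.5)


class TestEnumerateCandidates:
    def test_no_boundaries_gives_single_whole_region_exon(self):
        region = Region(contig="c", start=0, end=500)
        ivs = make_intervals([500], [10.0])
        cands = enumerate_candidate_exons(region, ivs, [])
        assert [(c.start, c.end) for c in cands] == [(0, 500)]

    def test_five_interval_region_admits_six_exons(self):
        # two acceptors and one donor inside a five-interval region pair
        # into six possible exons
        region = Region(contig="c", start=0, end=500)
        boundaries = [(100, "acceptor"), (200, "acceptor"), (300, "donor"), (400, "acceptor")]
        # keep 4 cut points -> 5 intervals but label only three as usable ends
        ivs = make_intervals([100] * 5, [1.0] * 5)
        cands = enumerate_candidate_exons(
            region, ivs, [(100, "acceptor"), (200, "acceptor"), (300, "donor")]
        )
        # left in {0, 100, 200}, right in {300, 500}
        assert len(cands) == 6
        assert {(c.start, c.end) for c in cands} == {
            (0, 300), (0, 500), (100, 300), (100, 500), (200, 300), (200, 500)
        }

    def test_donor_acceptor_pairing_includes_middle_exon(self):
        region = Region(contig="c", start=0, end=500)
        ivs = make_intervals([100] * 5, [1.0] * 5)
        cands = enumerate_candidate_exons(
            region, ivs, [(200, "donor"), (300, "acceptor")]
        )
        spans = {(c.start, c.end) for c in cands}
        assert spans == {(0, 200), (0, 500), (300, 500)}


class TestFeasibility:
    def setup_method(self):
        self.region = Region(contig="c", start=0, end=500)
        self.ivs = make_intervals([100] * 5, [10.0] * 5)
        self.boundaries = [(200, "donor"), (300, "acceptor")]
        self.cands = enumerate_candidate_exons(self.region, self.ivs, self.boundaries)
        self.by_span = {(c.start, c.end): i for i, c in enumerate(self.cands)}

    def test_uncovered_donor_is_infeasible(self):
        combo = [self.by_span[(0, 500)]]
        ok, reason = is_feasible_combination(combo, self.cands, self.boundaries, empty_evidence())
        assert not ok and reason == "uncovered_splice_site"

    def test_spliced_read_requires_exon_ending_at_donor(self):
        # read bridging the junction pins blocks to (., 200) and (300, .)
        ev = RegionEvidence(
            requirements=[(150, 200, None, 200), (300, 350, 300, None)],
            pair_points=[], pair_classes={}, n_pairs=0,
        )
        good = [self.by_span[(0, 200)], self.by_span[(300, 500)]]
        ok, _ = is_feasible_combination(good, self.cands, self.boundaries, ev)
        assert ok
        # full-region exon covers the block but has the wrong right edge
        bad = [self.by_span[(0, 500)], self.by_span[(0, 200)], self.by_span[(300, 500)]]
        ev_bad = RegionEvidence(
            requirements=[(150, 250, None, None)],  # unspliced read over the donor
            pair_points=[], pair_classes={}, n_pairs=0,
        )
        ok2, reason = is_feasible_combination(
            [self.by_span[(0, 200)], self.by_span[(300, 500)]],
            self.cands, self.boundaries, ev_bad,
        )
        assert not ok2 and reason == "incompatible_read"

    def test_pair_inner_points_joined_by_exon_chain(self):
        ev = RegionEvidence(
            requirements=[], pair_points=[(150, 350)], pair_classes={}, n_pairs=1,
        )
        combo = [self.by_span[(0, 200)], self.by_span[(300, 500)]]
        ok, _ = is_feasible_combination(combo, self.cands, self.boundaries, ev)
        assert ok
        # overlapping exons cannot chain
        ev2 = RegionEvidence(
            requirements=[], pair_points=[(150, 250)], pair_classes={}, n_pairs=1,
        )
        ok2, reason = is_feasible_combination(combo, self.cands, self.boundaries, ev2)
        assert not ok2 and reason == "disconnected_pair"


class TestLinearProgram:
    def test_single_exon_single_interval_exactly_determined(self):
        ivs = make_intervals([100], [7.0])
        sol = build_and_solve_lp([exon_over(ivs, 0, 0)], ivs)
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(0.0, abs=1e-8)
        assert sol.c[(0, 0)] == pytest.approx(7.0, abs=1e-6)
        assert all(e == pytest.approx(0.0, abs=1e-8) for e in sol.eps)

    def test_two_stacked_exons_consistent_coverage_zero_slack(self):
        ivs = make_intervals([100, 100], [8.0, 8.0])
        members = [exon_over(ivs, 0, 1), exon_over(ivs, 0, 1)]
        sol = build_and_solve_lp(members, ivs)
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(0.0, abs=1e-8)

    def test_inconsistent_coverage_matches_vertex_oracle(self):
        ivs = make_intervals([100, 100], [8.0, 6.0])
        members = [exon_over(ivs, 0, 1), exon_over(ivs, 0, 1)]
        sol = build_and_solve_lp(members, ivs, lower_bound=0.0)
        expected = lp_objective_oracle(
            [(0, 1), (0, 1)], [100.0, 100.0], [8.0, 6.0], lower_bound=0.0
        )
        assert sol.objective == pytest.approx(expected, abs=1e-6)
        assert sol.objective == pytest.approx(2.0, abs=1e-6)

    def test_low_coverage_retries_with_zero_lower_bound(self):
        ivs = make_intervals([100], [0.5])
        sol = build_and_solve_lp([exon_over(ivs, 0, 0)], ivs, lower_bound=1.0)
        assert sol.status == "optimal"
        assert sol.lower_bound_used == 0.0
        assert sol.c[(0, 0)] == pytest.approx(0.5, abs=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 3), st.integers(1, 3))
    def test_objective_invariant_under_translation(self, shift, n_iv, n_ex):
        rng = np.random.default_rng(n_iv * 17 + n_ex)
        lengths = rng.integers(50, 200, n_iv).tolist()
        covs = rng.uniform(0, 20, n_iv).round(3).tolist()
        ranges = [
            tuple(sorted(rng.integers(0, n_iv, 2).tolist())) for _ in range(n_ex)
        ]
        sols = []
        for start in (0, shift):
            ivs = make_intervals(lengths, covs, start=start)
            members = [exon_over(ivs, a, b) for a, b in ranges]
            sols.append(build_and_solve_lp(members, ivs, lower_bound=0.0))
        assert sols[0].status == sols[1].status == "optimal"
        assert sols[0].objective == pytest.approx(sols[1].objective, abs=1e-7)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 8.0), st.integers(1, 3), st.integers(1, 3))
    def test_objective_scales_linearly_with_coverage(self, k, n_iv, n_ex):
        rng = np.random.default_rng(n_iv * 31 + n_ex)
        lengths = rng.integers(50, 200, n_iv).tolist()
        covs = rng.uniform(0, 20, n_iv).round(3).tolist()
        ranges = [
            tuple(sorted(rng.integers(0, n_iv, 2).tolist())) for _ in range(n_ex)
        ]
        ivs1 = make_intervals(lengths, covs)
        ivs2 = make_intervals(lengths, [c * k for c in covs])
        m1 = [exon_over(ivs1, a, b) for a, b in ranges]
        m2 = [exon_over(ivs2, a, b) for a, b in ranges]
        s1 = build_and_solve_lp(m1, ivs1, lower_bound=0.0)
        s2 = build_and_solve_lp(m2, ivs2, lower_bound=0.0)
        assert s2.objective == pytest.approx(k * s1.objective, rel=1e-5, abs=1e-6)


class TestPairPenalty:
    def setup_method(self):
        self.ivs = make_intervals([100, 100, 100], [10.0, 10.0, 10.0])
        self.stats_far = FragmentStats(f_l=300.0, f_sigma=25.0)
        self.stats_near = FragmentStats(f_l=225.0, f_sigma=25.0)
        self.flank_exons = [exon_over(self.ivs, 0, 0), exon_over(self.ivs, 2, 2)]

    def test_achievable_classes_contribute_nothing(self):
        pen = pair_feasibility_penalty(
            self.flank_exons, {(0, 2): 30}, 100, self.stats_near, self.ivs
        )
        assert pen == pytest.approx(0.0)

    def test_missing_middle_exon_penalises_class_fraction(self):
        # without the middle exon the achievable span maxes at 200 < 250
        pen = pair_feasibility_penalty(
            self.flank_exons, {(0, 2): 30}, 100, self.stats_far, self.ivs
        )
        assert pen == pytest.approx(0.30)
        # adding the middle exon makes 300 achievable, inside the window
        with_middle = self.flank_exons + [exon_over(self.ivs, 1, 1)]
        pen2 = pair_feasibility_penalty(
            with_middle, {(0, 2): 30}, 100, self.stats_far, self.ivs
        )
        assert pen2 == pytest.approx(0.0)

    def test_penalties_add_across_classes(self):
        pen = pair_feasibility_penalty(
            self.flank_exons, {(0, 2): 10, (2, 2): 5}, 100, self.stats_far, self.ivs
        )
        assert pen == pytest.approx(0.15)

    def test_single_end_mode_returns_zero(self):
        pen = pair_feasibility_penalty(
            self.flank_exons, {(0, 2): 30}, 100, None, self.ivs
        )
        assert pen == 0.0

    def test_chain_distance_range_dp(self):
        exons = [exon_over(self.ivs, 0, 0), exon_over(self.ivs, 1, 1), exon_over(self.ivs, 2, 2)]
        # from interval 0 start to interval 2 end: direct chain skips middle
        rng = chain_distance_range(exons, 0, 300)
        assert rng == (200, 300)


class TestSelectExonSet:
    def test_fewest_exons_breaks_score_ties(self):
        region = Region(contig="c", start=0, end=300)
        boundaries = [(100, "donor"), (200, "acceptor")]
        ivs = make_intervals([100, 100, 100], [0.0, 0.0, 0.0])
        cands = enumerate_candidate_exons(region, ivs, boundaries)
        chosen, score, fallback = select_exon_set(
            region, ivs, cands, boundaries, empty_evidence(), None
        )
        assert not fallback
        assert {(c.start, c.end) for c in chosen} == {(0, 100), (200, 300)}
        assert score.total == pytest.approx(0.0, abs=1e-8)

    def test_single_feasible_combination_returned(self):
        region = Region(contig="c", start=0, end=100)
        ivs = make_intervals([100], [5.0])
        cands = enumerate_candidate_exons(region, ivs, [])
        chosen, score, fallback = select_exon_set(
            region, ivs, cands, [], empty_evidence(), None
        )
        assert [(c.start, c.end) for c in chosen] == [(0, 100)]
        assert not fallback

    def test_infeasible_region_falls_back_to_whole_region(self):
        region = Region(contig="c", start=0, end=300)
        boundaries = [(100, "donor"), (200, "acceptor")]
        ivs = make_intervals([100, 100, 100], [5.0, 5.0, 5.0])
        cands = enumerate_candidate_exons(region, ivs, boundaries)
        # a read spanning the whole region pinned at both edges cannot
        # coexist with the required donor/acceptor exons
        ev = RegionEvidence(
            requirements=[(0, 300, 100, 200)],  # impossible pinning
            pair_points=[], pair_classes={}, n_pairs=0,
        )
        chosen, score, fallback = select_exon_set(
            region, ivs, cands, boundaries, ev, None
        )
        assert fallback
        assert [(c.start, c.end) for c in chosen] == [(0, 300)]

    def test_skipped_exon_simulation_recovers_true_exons(self, tmp_path):
        from isocover import make_gene_models, simulate_alignments
        from isocover.alignments import detect_regions, parse_alignments
        from isocover.exons import infer_region_exons

        models = make_gene_models(
            seed=11, n_genes=1, isoforms_per_gene=(2, 2), events=("skipped_exon",)
        )
        sam = tmp_path / "skip.sam"
        truth = simulate_alignments(
            models, out_sam=str(sam), depth=30.0, frag_mean=250.0, frag_sd=25.0, seed=11
        )
        store = parse_alignments(str(sam))
        regions = detect_regions(store)
        junctions = store.junction_list(1, 8)
        stats = FragmentStats(250.0, 25.0)
        got = set()
        for region in regions:
            for res in infer_region_exons(region, store, junctions, stats):
                got.update((e.start, e.end) for e in res.exons)
        expected = sorted({exon for t in truth for exon in t.exons})
        # splice-linked boundaries must be exact; the outer edges of the
        # first/last exon are read-sampling limits and may jitter slightly
        splice_bound = {d for t in truth for d, _ in t.introns}
        splice_bound |= {a for t in truth for _, a in t.introns}
        assert len(got) == len(expected)
        for (gs, ge), (es, ee) in zip(sorted(got), expected):
            assert gs == es if es in splice_bound else abs(gs - es) <= 10
            assert ge == ee if ee in splice_bound else abs(ge - ee) <= 10
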