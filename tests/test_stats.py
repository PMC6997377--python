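import itertools
import json
import math

import numpy as np
import pytest

import rescon
from rescon.stats import (
    ClusterResult,
    OverlapResult,
    StructureResult,
    assemble_report,
    cluster_significance,
    dc_contact_significance,
    log10_tail_hypergeom,
    pattern_contact_significance,
    pattern_dc_significance,
    tail_hypergeom,
)


def enumerate_tail_distribution(N, K, n):
    """Exhaustive oracle: P(X >= x) for every x, over all C(N, n) draws."""
    marked = set(range(K))
    counts = [0] * (n + 1)
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        counts[len(marked.intersection(draw))] += 1
    tail = [0.0] * (n + 2)
    for x in range(n, -1, -1):
        tail[x] = tail[x + 1] + counts[x] / total
    return tail[: n + 1]


class TestTailHypergeom:
    def test_closed_form_spot_check(self):
        assert tail_hypergeom(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-9)

    def test_x_zero_is_one(self):
        assert tail_hypergeom(50, 10, 5, 0) == 1.0

    def test_matches_exhaustive_enumeration(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    want = enumerate_tail_distribution(N, K, n)
                    for x in range(n + 1):
                        got = tail_hypergeom(N, K, n, x)
                        assert got == pytest.approx(want[x], abs=1e-10), (N, K, n, x)

    def test_invalid_arguments_rejected(self):
        for bad in [(10, 11, 5, 0), (10, 5, 11, 0), (10, 5, 5, 6), (-1, 0, 0, 0)]:
            with pytest.raises(ValueError):
                tail_hypergeom(*bad)

    def test_log_space_handles_extreme_tails(self):
        lp = log10_tail_hypergeom(100000, 100, 100, 100)
        assert lp < -200 and math.isfinite(lp)


def _scores_from_matrix(mat):
    L = mat.shape[0]
    pairs = {(i + 1, j + 1) for i in range(L) for j in range(i + 1, L)}
    return rescon.CouplingScores(mat, mat.copy(), True, pairs)


def _ranked_matrix(L, rng=None):
    """Score matrix with a strict global ranking (optionally shuffled)."""
    mat = np.zeros((L, L))
    vals = np.arange(L * (L - 1) // 2, 0, -1, dtype=float)
    if rng is not None:
        rng.shuffle(vals)
    k = 0
    for i in range(L):
        for j in range(i + 1, L):
            mat[i, j] = mat[j, i] = vals[k]
            k += 1
    return mat


class TestDcContactSignificance:
    def test_contacts_equal_top20_closed_form(self):
        L = 46  # 1035 pairs
        scores = _scores_from_matrix(_ranked_matrix(L))
        top20 = scores.top_pairs(20)
        contacts = rescon.ContactMap({p: 3.0 for p in top20}, 5.0, 5)
        ladder = (5, 10, 20, 50)
        res = dc_contact_significance(scores, contacts, ladder=ladder)
        want = log10_tail_hypergeom(1035, 20, 20, 20)
        assert res.best_cutoff == 20 and res.marked_in_top == 20
        assert res.log10_raw == pytest.approx(want, rel=1e-9)
        assert res.log10_adjusted == pytest.approx(want + math.log10(4), rel=1e-9)

    def test_disjoint_contacts_p_one(self):
        scores = _scores_from_matrix(_ranked_matrix(10))
        bottom = scores.ranked_pairs()[-3:]
        contacts = rescon.ContactMap({p: 3.0 for p in bottom}, 5.0, 5)
        res = dc_contact_significance(scores, contacts, ladder=(2, 3))
        assert res.adjusted_p == 1.0

    def test_empty_contacts_p_one_with_note(self):
        scores = _scores_from_matrix(_ranked_matrix(8))
        res = dc_contact_significance(scores, rescon.ContactMap({}, 5.0, 5))
        assert res.adjusted_p == 1.0 and res.note

    def test_adding_a_top_pair_contact_never_hurts(self):
        scores = _scores_from_matrix(_ranked_matrix(12))
        top = scores.top_pairs(10)
        c1 = rescon.ContactMap({p: 3.0 for p in top[:4]}, 5.0, 5)
        c2 = rescon.ContactMap({p: 3.0 for p in top[:5]}, 5.0, 5)
        r1 = dc_contact_significance(scores, c1, ladder=(10,))
        r2 = dc_contact_significance(scores, c2, ladder=(10,))
        assert r2.log10_raw <= r1.log10_raw + 1e-12

    def test_null_calibration(self):
        rng = np.random.default_rng(42)
        L = 20
        scores = _scores_from_matrix(_ranked_matrix(L))
        all_pairs = sorted(scores.eligible_pairs)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            idx = rng.choice(len(all_pairs), size=20, replace=False)
            contacts = rescon.ContactMap({all_pairs[i]: 3.0 for i in idx}, 5.0, 5)
            res = dc_contact_significance(scores, contacts)
            hits += res.adjusted_p <= 0.05
        assert hits / n_rep <= 0.07


class TestPatternDcSignificance:
    def test_pattern_at_top_pair_endpoints_significant(self):
        scores = _scores_from_matrix(_ranked_matrix(20))
        top5 = scores.top_pairs(5)
        cols = sorted({c for p in top5 for c in p})
        res = pattern_dc_significance(cols, scores, ladder=(5, 10, 20))
        assert res.adjusted_p < 0.05

    def test_single_column_both_endpoints_mode_p_one(self):
        scores = _scores_from_matrix(_ranked_matrix(10))
        res = pattern_dc_significance([3], scores, require_both_endpoints=True)
        assert res.adjusted_p == 1.0

    def test_insignificant_marked_complementary(self):
        scores = _scores_from_matrix(_ranked_matrix(20))
        bottom_cols = {c for p in scores.ranked_pairs()[-3:] for c in p}
        res = pattern_dc_significance(sorted(bottom_cols), scores, ladder=(3, 5))
        assert "complementary" in (res.note or "")


class TestPatternContactSignificance:
    def test_mutually_contacting_pattern_closed_form(self):
        universe = {(i, j) for i in range(1, 11) for j in range(i + 1, 11)}  # 45
        pattern = [1, 2, 3, 4]
        ppairs = {(i, j) for i in pattern for j in pattern if i < j}  # C(4,2)=6
        contacts = rescon.ContactMap({p: 3.0 for p in ppairs}, 5.0, 5)
        res = pattern_contact_significance(pattern, contacts, universe)
        assert res.log10_raw == pytest.approx(
            log10_tail_hypergeom(45, 6, 6, 6), rel=1e-9
        )
        assert res.log10_adjusted == res.log10_raw  # single test, no ladder

    def test_distant_pattern_p_one(self):
        universe = {(i, j) for i in range(1, 11) for j in range(i + 1, 11)}
        contacts = rescon.ContactMap({(5, 10): 3.0}, 5.0, 5)
        res = pattern_contact_significance([1, 2], contacts, universe)
        assert res.adjusted_p == 1.0

    def test_single_pattern_column_warns_p_one(self):
        universe = {(1, 2)}
        res = pattern_contact_significance([1], rescon.ContactMap({}, 5, 5), universe)
        assert res.adjusted_p == 1.0 and res.note

    def test_matches_random_subset_simulation(self):
        # simulation oracle for the urn model: random n-pair subsets of the
        # mapped-pair universe, tallying draws at least as contact-enriched
        rng = np.random.default_rng(1)
        cols = list(range(1, 13))
        universe = sorted((i, j) for i in cols for j in cols if i < j)  # 66
        contact_idx = rng.choice(len(universe), size=20, replace=False)
        contacts = rescon.ContactMap(
            {universe[i]: 3.0 for i in contact_idx}, 5.0, 5
        )
        pattern = [1, 2, 3, 4, 5]
        res = pattern_contact_significance(pattern, contacts, set(universe))
        ppairs = {p for p in universe if p[0] in pattern and p[1] in pattern}
        x_obs = len(ppairs & contacts.pairs.keys())
        n_draw = 10000
        contact_set = set(contacts.pairs)
        hits = 0
        for _ in range(n_draw):
            draw = rng.choice(len(universe), size=len(ppairs), replace=False)
            x = sum(universe[i] in contact_set for i in draw)
            hits += x >= x_obs
        mc = hits / n_draw
        se = math.sqrt(max(mc * (1 - mc), 1e-9) / n_draw)
        assert abs(res.raw_p - mc) <= 3 * se + 1e-6


class TestClusterSignificance:
    def test_planted_cluster_highly_significant(self, toy_cluster_structure, toy_distance_matrix):
        _, truth = toy_cluster_structure
        res = cluster_significance(
            truth.cluster_members, list(range(1, 151)),
            distance=toy_distance_matrix,
        )
        assert res.adjusted_p < 1e-6
        assert res.center in truth.cluster_members

    def test_null_calibration(self, toy_distance_matrix):
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            pat = (rng.choice(150, size=10, replace=False) + 1).tolist()
            res = cluster_significance(pat, list(range(1, 151)),
                                       distance=toy_distance_matrix)
            hits += res.adjusted_p <= 0.05
        assert hits / n_rep <= 0.07

    def test_saturated_case_p_one(self, toy_distance_matrix):
        res = cluster_significance(
            list(range(1, 151)), list(range(1, 151)), distance=toy_distance_matrix
        )
        assert res.adjusted_p == 1.0

    def test_single_pattern_residue_p_one(self, toy_distance_matrix):
        res = cluster_significance([5], list(range(1, 151)),
                                   distance=toy_distance_matrix)
        assert res.adjusted_p == 1.0 and res.note

    def test_relabeling_invariance(self, toy_distance_matrix):
        members = list(range(40, 50))
        a = cluster_significance(members, list(range(1, 151)),
                                 distance=toy_distance_matrix)
        relabeled = [r + 1000 for r in range(1, 151)]
        b = cluster_significance([m + 1000 for m in members], relabeled,
                                 distance=toy_distance_matrix)
        assert a.log10_adjusted == pytest.approx(b.log10_adjusted)


def _mk_result(sid, p_dc, p_p):
    ov = lambda p: OverlapResult(5, 3, math.log10(p), math.log10(p), (5,))
    cl = ClusterResult(1, 10.0, 5, 3, -2.0, -1.5, 3, 5)
    return StructureResult(sid, "level1", ov(p_dc), ov(1e-2), ov(p_p), cl)


class TestAssembleReport:
    def test_combined_score_ranking(self):
        a = _mk_result("A", 1e-8, 1e-4)
        b = _mk_result("B", 1e-6, 1e-3)
        report = assemble_report([b, a])
        assert [r.structure_id for r in report.ranked()] == ["A", "B"]
        assert report.ranked()[0].combined_score == pytest.approx(12.0)

    def test_single_structure_rank_one(self):
        report = assemble_report([_mk_result("only", 1e-3, 1e-2)])
        assert report.ranked()[0].structure_id == "only"

    def test_json_round_trip_byte_identical(self):
        report = assemble_report([_mk_result("A", 1e-8, 1e-4)], {"seed": 1})
        s1 = report.to_json()
        s2 = report.to_json()
        assert s1 == s2
        payload = json.loads(s1)
        assert payload["ranking"] == ["A"]
        assert 0 < 10 ** payload["results"][0]["s_3d_dc"]["log10_adjusted_p"] <= 1

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            assemble_report([])
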