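import math

import numpy as np
import pytest

import rescon
from rescon.alphabet import AA_INDEX
from rescon.bpps import (
    SamplerConfig,
    _init_state,
    gibbs_sweep,
    pattern_position_llr,
    selective_pressure_heights,
)

from conftest import make_alignment


def brute_force_llr(m_fg, t_fg, m_bg, t_bg, residue_set_size_irrelevant, alpha):
    """Independent evaluation of the contrast LLR from its definition."""

    def ll(m, t):
        if t <= 0:
            return 0.0
        th = (m + alpha) / (t + 2 * alpha)
        return m * math.log(th) + (t - m) * math.log(1 - th)

    return ll(m_fg, t_fg) + ll(m_bg, t_bg) - ll(m_fg + m_bg, t_fg + t_bg)


class TestPatternPositionLLR:
    def _counts(self, m, t, aa="A"):
        c = np.zeros(22)
        c[AA_INDEX[aa]] = m
        c[AA_INDEX["G"]] = t - m
        return c

    def test_matches_independent_formula(self):
        fg = self._counts(50, 50)
        bg = self._counts(0, 50)
        got = pattern_position_llr(fg, bg, {"A"}, 0.5)
        want = brute_force_llr(50, 50, 0, 50, 1, 0.5)
        assert got == pytest.approx(want, abs=1e-9)
        assert got > 20  # strongly discriminating

    def test_no_contrast_is_near_zero(self):
        fg = self._counts(30, 60)
        bg = self._counts(30, 60)
        assert abs(pattern_position_llr(fg, bg, {"A"})) < 1e-6 * 120

    def test_monotone_in_fg_matches(self):
        vals = [
            pattern_position_llr(self._counts(m, 50), self._counts(5, 50), {"A"})
            for m in range(5, 51)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_empty_residue_set_rejected(self):
        with pytest.raises(ValueError):
            pattern_position_llr(self._counts(1, 2), self._counts(1, 2), set())

    def test_gaps_count_as_nonmatches(self):
        fg = np.zeros(22)
        fg[AA_INDEX["A"]] = 10
        fg[AA_INDEX["-"]] = 10
        bg = self._counts(10, 20)
        # gap rows dilute the fg match frequency exactly like mismatches
        assert pattern_position_llr(fg, bg, {"A"}) == pytest.approx(
            brute_force_llr(10, 20, 10, 20, 1, 0.5), abs=1e-9
        )


class TestSampler:
    def test_zero_iteration_sweep_is_identity(self, subgrouped):
        aln, _ = subgrouped
        w = rescon.sequence_weights(aln)
        rng = np.random.default_rng(0)
        state = _init_state(aln, w, SamplerConfig(), rng)
        before = state.in_fg.copy()
        gibbs_sweep(state, 0)
        assert (state.in_fg == before).all() and not state.active

    def test_perfect_pattern_match_prefers_foreground(self):
        # fg rows match an A-pattern at 4 columns, bg rows never do;
        # filler columns are random so redundancy weights stay ~1
        rng = np.random.default_rng(0)
        filler = lambda: "".join(rescon.AA20[c] for c in rng.integers(1, 20, 8))
        rows = [("q", "AAAA" + filler())]
        rows += [(f"f{i}", "AAAA" + filler()) for i in range(14)]
        rows += [(f"b{i}", "WWWW" + filler()) for i in range(15)]
        aln = make_alignment(rows, "q")
        w = rescon.sequence_weights(aln)
        state = _init_state(aln, w, SamplerConfig(), np.random.default_rng(1))
        state.in_fg[:] = [r[0][0] in "qf" for r in rows]
        for col in range(1, 5):
            state.set_active(col, frozenset("A"))
        gibbs_sweep(state, 20)
        # perfectly matching rows stay in the foreground
        assert state.in_fg[1] and not state.in_fg[-1]

    def test_acceptance_statistics_in_open_interval(self, subgrouped):
        aln, _ = subgrouped
        w = rescon.sequence_weights(aln)
        state = _init_state(aln, w, SamplerConfig(), np.random.default_rng(3))
        gibbs_sweep(state, 20)
        assert 0 < state.n_accepted < state.n_proposed


class TestPartitionMSA:
    def test_same_seed_reproducible(self, subgrouped):
        aln, _ = subgrouped
        w = rescon.sequence_weights(aln)
        cfg = SamplerConfig(n_sweeps=60, burn_in=20, seed=9)
        a = rescon.partition_msa(aln, w, cfg)
        b = rescon.partition_msa(aln, w, cfg)
        assert [n.foreground for n in a] == [n.foreground for n in b]
        assert [n.pattern for n in a] == [n.pattern for n in b]

    def test_planted_subgroup_recovery(self, subgrouped):
        aln, truth = subgrouped
        w = rescon.sequence_weights(aln)
        nodes = rescon.partition_msa(aln, w, SamplerConfig(seed=5))
        node = nodes[1]
        assert aln.query_id in node.foreground
        group1 = {i for i, g in truth.group_of.items() if g == 1}
        agree = len(node.foreground & group1) / len(group1)
        assert agree >= 0.95
        planted = {c for c, _ in truth.pattern_columns[1]}
        assert len(planted & set(node.pattern_columns())) >= 7
        llrs = [p.contrast_llr for p in node.pattern]
        assert llrs == sorted(llrs, reverse=True)
        for p in node.pattern:
            assert p.contrast_llr > 0 and p.fg_match_freq >= p.bg_match_freq

    def test_homogeneous_msa_reports_no_signal(self):
        rng = np.random.default_rng(4)
        rows = [
            (f"s{i}", "".join(rescon.AA20[c] for c in rng.integers(0, 20, 60)))
            for i in range(60)
        ]
        aln = make_alignment(rows, "s0")
        w = rescon.sequence_weights(aln)
        nodes = rescon.partition_msa(aln, w, SamplerConfig(n_sweeps=100, seed=1))
        assert nodes[1].pattern == []

    def test_small_effective_count_returns_root_only(self):
        rows = [("q", "ACDEF")] + [(f"s{i}", "ACDEF") for i in range(5)]
        aln = make_alignment(rows, "q")
        w = rescon.sequence_weights(aln)
        nodes = rescon.partition_msa(aln, w, SamplerConfig())
        assert len(nodes) == 1 and nodes[0].level == 0

    def test_root_pattern_respects_conservation_floor(self, subgrouped):
        aln, _ = subgrouped
        w = rescon.sequence_weights(aln)
        cfg = SamplerConfig(conservation_floor=0.45)
        root = rescon.partition_msa(aln, w, cfg)[0]
        prof = rescon.column_frequencies(aln, w)
        for p in root.pattern:
            assert prof.frequencies[p.column - 1, :20].max() >= 0.45

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_levels=0)


class TestSelectivePressure:
    def test_heights_normalized_and_order_isomorphic(self, subgrouped):
        aln, _ = subgrouped
        w = rescon.sequence_weights(aln)
        node = rescon.partition_msa(aln, w, SamplerConfig(seed=5))[1]
        heights = selective_pressure_heights(node)
        hmap = dict(heights)
        llr = {p.column: p.contrast_llr for p in node.pattern}
        assert max(hmap.values()) == pytest.approx(1.0)
        cols = sorted(hmap, key=lambda c: llr[c])
        hs = [hmap[c] for c in cols]
        assert all(b >= a - 1e-12 for a, b in zip(hs, hs[1:]))

    def test_zero_llr_maps_to_zero(self):
        node = rescon.HierarchyNode(
            "n", None, {"a"}, set(),
            [
                rescon.PatternPosition(1, frozenset("A"), 10.0, 1, 0),
                rescon.PatternPosition(2, frozenset("C"), 0.0, 0.5, 0.5),
            ],
            1,
        )
        h = dict(selective_pressure_heights(node))
        assert h[2] == 0.0 and h[1] == 1.0
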