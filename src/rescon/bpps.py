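"""Bayesian partitioning with pattern selection (BPPS-style).

Hierarchically splits an MSA into query-anchored subgroups, each defined by
a set of discriminating pattern positions, via Markov chain Monte Carlo:
sequence memberships are Gibbs-resampled from their conditional posterior
under the current pattern, and pattern-column inclusion is toggled by
Metropolis steps under a per-position geometric size penalty. The point
estimate is the maximum a posteriori state over post-burn-in sweeps.

Each level performs one binary split (foreground vs. the rest) of the parent
foreground. Residue sets per position are subsets of the foreground modal
residue's biochemical class, grown greedily while the contrast score
improves. Records with a gap or ambiguity at a pattern column count as
non-matches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA20, AA_INDEX, CLASS_OF, RESIDUE_CLASSES
from .msa_io import Alignment, WeightVector, column_frequencies, pairwise_identity_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatternPosition:
    column: int                  # 1-based alignment column
    residue_set: frozenset[str]
    contrast_llr: float          # nats
    fg_match_freq: float
    bg_match_freq: float


@dataclass
class HierarchyNode:
    node_id: str
    parent_id: str | None
    foreground: set[str]
    background: set[str]
    pattern: list[PatternPosition]
    level: int

    def pattern_columns(self) -> list[int]:
        return [p.column for p in self.pattern]

    def to_dict(self, aln: Alignment | None = None) -> dict:
        qcoord = aln.column_to_query_coord() if aln is not None else {}
        return {
            "node_id": self.node_id,
            "parent_id": self.parent_id,
            "level": self.level,
            "foreground": sorted(self.foreground),
            "background": sorted(self.background),
            "pattern": [
                {
                    "column": p.column,
                    "query_position": qcoord.get(p.column),
                    "residue_set": "".join(sorted(p.residue_set)),
                    "contrast_llr": round(p.contrast_llr, 4),
                    "fg_match_freq": round(p.fg_match_freq, 4),
                    "bg_match_freq": round(p.bg_match_freq, 4),
                }
                for p in self.pattern
            ],
        }


@dataclass
class SamplerConfig:
    n_sweeps: int = 300
    burn_in: int = 100
    seed: int = 0
    alpha: float = 0.5                       # Dirichlet pseudocount
    theta: float = math.log(10.0)            # per-position pattern-size log penalty
    max_pattern_positions: int = 25
    n_levels: int = 1
    significance_floor: float = 10.0         # nats; reported-position floor
    conservation_floor: float = 0.5          # root-pattern modal-frequency floor

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if min(self.n_sweeps, self.burn_in + 1, self.alpha, self.theta,
               self.max_pattern_positions) <= 0:
            raise ValueError("sampler configuration values must be positive")


def _binom_ll(m: float, t: float, alpha: float) -> float:
    """Weighted binomial log-likelihood at the Dirichlet-smoothed MLE."""
    if t <= 0:
        return 0.0
    theta = (m + alpha) / (t + 2 * alpha)
    return m * math.log(theta) + (t - m) * math.log1p(-theta)


def pattern_position_llr(
    fg_counts: np.ndarray,
    bg_counts: np.ndarray,
    residue_set: frozenset[str] | set[str],
    alpha: float = 0.5,
) -> float:
    """Contrast log-likelihood ratio for one column and residue set.

    ``fg_counts``/``bg_counts`` are weighted per-state count vectors over the
    22 states (20 aa, gap, ambiguity); a record matches iff its residue is in
    ``residue_set``, so gaps and ambiguity count as non-matches.
    LLR = l(fg) + l(bg) - l(pooled) with Dirichlet(alpha)-smoothed binomial
    likelihoods of the match events.
    """
    if not residue_set:
        raise ValueError("empty residue set")
    idx = [AA_INDEX[a] for a in residue_set]
    m_fg, t_fg = float(np.sum(fg_counts[idx])), float(np.sum(fg_counts))
    m_bg, t_bg = float(np.sum(bg_counts[idx])), float(np.sum(bg_counts))
    return (
        _binom_ll(m_fg, t_fg, alpha)
        + _binom_ll(m_bg, t_bg, alpha)
        - _binom_ll(m_fg + m_bg, t_fg + t_bg, alpha)
    )


def _llr_from_matches(m_fg, t_fg, m_bg, t_bg, alpha) -> float:
    return (
        _binom_ll(m_fg, t_fg, alpha)
        + _binom_ll(m_bg, t_bg, alpha)
        - _binom_ll(m_fg + m_bg, t_fg + t_bg, alpha)
    )


@dataclass
class SamplerState:
    """Mutable MCMC state for one binary split."""

    aln: Alignment
    weights: np.ndarray
    in_fg: np.ndarray                        # bool per record
    active: dict[int, frozenset[str]]        # column -> residue set
    rng: np.random.Generator
    alpha: float
    theta: float
    max_positions: int
    query_idx: int
    match: dict[int, np.ndarray] = field(default_factory=dict)  # column -> bool per record
    n_proposed: int = 0
    n_accepted: int = 0

    def match_vector(self, col: int, residue_set: frozenset[str]) -> np.ndarray:
        codes = self.aln.matrix()[:, col - 1]
        sel = np.zeros(22, dtype=bool)
        for a in residue_set:
            sel[AA_INDEX[a]] = True
        return sel[codes]

    def set_active(self, col: int, residue_set: frozenset[str]) -> None:
        self.active[col] = residue_set
        self.match[col] = self.match_vector(col, residue_set)

    def column_llr(self, col: int) -> float:
        x = self.match[col]
        w = self.weights
        m_fg = float((w * x)[self.in_fg].sum())
        t_fg = float(w[self.in_fg].sum())
        m_bg = float((w * x)[~self.in_fg].sum())
        t_bg = float(w[~self.in_fg].sum())
        return _llr_from_matches(m_fg, t_fg, m_bg, t_bg, self.alpha)

    def joint_score(self) -> float:
        return sum(self.column_llr(c) for c in self.active) - self.theta * len(self.active)


def _best_residue_set(state: SamplerState, col: int) -> frozenset[str] | None:
    """Greedy residue-set search: foreground modal residue, then members of
    its biochemical class in decreasing foreground frequency while the LLR
    improves."""
    w = state.weights
    codes = state.aln.matrix()[:, col - 1]
    fg_w = w * state.in_fg
    fg_counts = np.bincount(codes, weights=fg_w, minlength=22)
    if fg_counts[:20].sum() <= 0:
        return None
    modal = int(fg_counts[:20].argmax())
    modal_aa = AA20[modal]
    members = sorted(
        RESIDUE_CLASSES[CLASS_OF[modal_aa]],
        key=lambda a: -fg_counts[AA_INDEX[a]],
    )
    all_counts = np.bincount(codes, weights=w, minlength=22)
    bg_counts = all_counts - fg_counts

    def llr_of(s: set[str]) -> float:
        return pattern_position_llr(fg_counts, bg_counts, s, state.alpha)

    current = {modal_aa}
    best = llr_of(current)
    for aa in members:
        if aa in current:
            continue
        trial = current | {aa}
        v = llr_of(trial)
        if v > best:
            current, best = trial, v
        else:
            break
    # accepted positions must be foreground-enriched
    idx = [AA_INDEX[a] for a in current]
    t_fg, t_bg = fg_counts.sum(), bg_counts.sum()
    f_fg = fg_counts[idx].sum() / t_fg if t_fg > 0 else 0.0
    f_bg = bg_counts[idx].sum() / t_bg if t_bg > 0 else 0.0
    if best <= 0 or f_fg < f_bg:
        return None
    return frozenset(current)


def gibbs_sweep(state: SamplerState, n: int = 1) -> SamplerState:
    """Run ``n`` full sweeps in place: membership Gibbs resampling for every
    record, then a Metropolis inclusion toggle for every column."""
    aln = state.aln
    w = state.weights
    alpha = state.alpha
    for _ in range(n):
        # --- membership resampling (leave-one-out, incremental counts) ---
        if state.active:
            cols = sorted(state.active)
            WX = np.column_stack([w * state.match[c] for c in cols])  # (n, A)
            m_all = WX.sum(axis=0)
            t_all = float(w.sum())
            m_fg = WX[state.in_fg].sum(axis=0)
            t_fg = float(w[state.in_fg].sum())
            unif = state.rng.random(aln.n_records)
            for i in state.rng.permutation(aln.n_records):
                if i == state.query_idx:
                    continue
                wi = w[i]
                if state.in_fg[i]:
                    mf, tf = m_fg - WX[i], t_fg - wi
                else:
                    mf, tf = m_fg, t_fg
                mb = m_all - mf - WX[i]
                tb = t_all - tf - wi
                p_fg = (mf + alpha) / (tf + 2 * alpha)
                p_bg = (mb + alpha) / (tb + 2 * alpha)
                xi = WX[i] > 0
                log_odds = math.log((tf + 1.0) / (tb + 1.0)) + float(
                    np.where(xi, np.log(p_fg / p_bg),
                             np.log((1 - p_fg) / (1 - p_bg))).sum()
                )
                go_fg = unif[i] < 1.0 / (1.0 + math.exp(-np.clip(log_odds, -500, 500)))
                if go_fg != state.in_fg[i]:
                    state.in_fg[i] = go_fg
                    if go_fg:
                        m_fg, t_fg = mf + WX[i], tf + wi
                    else:
                        m_fg, t_fg = mf, tf
        # --- pattern-column toggles ------------------------------------
        for col in state.rng.permutation(aln.n_columns) + 1:
            col = int(col)
            state.n_proposed += 1
            if col in state.active:
                delta = state.theta - state.column_llr(col)
                if delta >= 0 or state.rng.random() < math.exp(delta):
                    del state.active[col]
                    del state.match[col]
                    state.n_accepted += 1
            else:
                if len(state.active) >= state.max_positions:
                    continue
                rset = _best_residue_set(state, col)
                if rset is None:
                    continue
                state.set_active(col, rset)
                delta = state.column_llr(col) - state.theta
                if delta >= 0 or state.rng.random() < math.exp(delta):
                    state.n_accepted += 1
                else:
                    del state.active[col]
                    del state.match[col]
    return state


def _init_state(
    aln: Alignment, w: WeightVector, config: SamplerConfig, rng: np.random.Generator
) -> SamplerState:
    """Foreground seeded with the query and its 10% nearest neighbors by
    pairwise identity (query-lineage anchoring)."""
    ident = pairwise_identity_matrix(aln)
    qi = aln.query_index
    k = max(2, int(round(0.10 * aln.n_records)))
    order = np.argsort(-ident[qi])
    in_fg = np.zeros(aln.n_records, dtype=bool)
    in_fg[order[:k]] = True
    in_fg[qi] = True
    return SamplerState(
        aln=aln,
        weights=w.weights,
        in_fg=in_fg,
        active={},
        rng=rng,
        alpha=config.alpha,
        theta=config.theta,
        max_positions=config.max_pattern_positions,
        query_idx=qi,
    )


def _state_pattern(state: SamplerState, floor: float) -> list[PatternPosition]:
    out = []
    w = state.weights
    for col, rset in state.active.items():
        x = state.match[col]
        t_fg = float(w[state.in_fg].sum())
        t_bg = float(w[~state.in_fg].sum())
        m_fg = float((w * x)[state.in_fg].sum())
        m_bg = float((w * x)[~state.in_fg].sum())
        llr = _llr_from_matches(m_fg, t_fg, m_bg, t_bg, state.alpha)
        if llr < floor:
            continue
        out.append(
            PatternPosition(
                column=col,
                residue_set=rset,
                contrast_llr=llr,
                fg_match_freq=m_fg / t_fg if t_fg else 0.0,
                bg_match_freq=m_bg / t_bg if t_bg else 0.0,
            )
        )
    out.sort(key=lambda p: (-p.contrast_llr, p.column))
    return out


def _root_node(aln: Alignment, w: WeightVector, config: SamplerConfig) -> HierarchyNode:
    """Level-0 node: the whole MSA against an implicit background of
    unrelated sequences; pattern = columns conserved above the floor, scored
    against a same-size uniform-composition pseudo-background."""
    profile = column_frequencies(aln, w)
    pattern = []
    total = w.effective_count
    for col0 in range(aln.n_columns):
        freqs = profile.frequencies[col0, :20]
        modal = int(freqs.argmax())
        f = float(freqs[modal])
        if f < config.conservation_floor:
            continue
        m_fg = f * total
        m_bg = total / 20.0
        llr = _llr_from_matches(m_fg, total, m_bg, total, config.alpha)
        pattern.append(
            PatternPosition(col0 + 1, frozenset(AA20[modal]), llr, f, 1 / 20)
        )
    pattern.sort(key=lambda p: (-p.contrast_llr, p.column))
    return HierarchyNode("root", None, set(aln.ids), set(), pattern, 0)


def partition_msa(
    aln: Alignment, w: WeightVector, config: SamplerConfig
) -> list[HierarchyNode]:
    """Hierarchically partition the MSA into query-lineage subgroups.

    Returns nodes for levels 0..n_levels; level 0 is the root. Each deeper
    node performs one MAP binary split of its parent's foreground. The full
    trajectory is fixed by ``config.seed``.
    """
    nodes = [_root_node(aln, w, config)]
    if w.effective_count < 10:
        logger.warning(
            "effective count %.1f < 10: returning root-only hierarchy",
            w.effective_count,
        )
        return nodes

    parent = nodes[0]
    for level in range(1, config.n_levels + 1):
        sub_ids = sorted(parent.foreground)
        if len(sub_ids) < 10:
            logger.warning("level %d: parent foreground too small; stopping", level)
            break
        sub = aln.subset(sub_ids)
        idx = [aln.ids.index(r) for r in sub.ids]
        sub_w = WeightVector(w.weights[idx])
        rng = np.random.default_rng((config.seed, level))
        state = _init_state(sub, sub_w, config, rng)

        best_score = -math.inf
        best = None
        gibbs_sweep(state, config.burn_in)
        for _ in range(config.n_sweeps - config.burn_in):
            gibbs_sweep(state, 1)
            score = state.joint_score()
            if score > best_score:
                best_score = score
                best = (state.in_fg.copy(), dict(state.active))
        if best is None:
            best = (state.in_fg.copy(), dict(state.active))
        state.in_fg, = (best[0],)
        state.active = {}
        state.match = {}
        for col, rset in best[1].items():
            state.set_active(col, rset)
        pattern = _state_pattern(state, config.significance_floor)
        if not pattern:
            logger.info("level %d: no subgroup signal", level)
        fg_ids = {sub.ids[i] for i in np.nonzero(state.in_fg)[0]}
        node = HierarchyNode(
            node_id=f"level{level}",
            parent_id=parent.node_id,
            foreground=fg_ids,
            background=set(sub_ids) - fg_ids,
            pattern=pattern,
            level=level,
        )
        nodes.append(node)
        parent = node
    return nodes


def selective_pressure_heights(node: HierarchyNode) -> list[tuple[int, float]]:
    """Semi-logarithmic bar heights: log10(1 + LLR), rescaled to [0, 1] by
    the node maximum."""
    if not node.pattern:
        raise ValueError("node has no pattern positions")
    raw = [(p.column, math.log10(1.0 + max(p.contrast_llr, 0.0))) for p in node.pattern]
    peak = max(h for _, h in raw)
    if peak <= 0:
        return [(c, 0.0) for c, _ in raw]
    return [(c, h / peak) for c, h in raw]


def hierarchy_to_json(nodes: list[HierarchyNode], aln: Alignment | None = None) -> str:
    import json

    return json.dumps(
        {"nodes": [n.to_dict(aln) for n in nodes]}, indent=2, sort_keys=True
    )
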