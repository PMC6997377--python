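"""Significance of correlations among patterns, couplings, and 3D contacts.

All four statistics are ball-in-urn (cumulative hypergeometric tail) tests,
computed in log space. Searches over a cutoff ladder, cluster centers, and
radii are Bonferroni-adjusted by the number of alternatives examined; the
tests are therefore conservative. The per-structure headline score combines
the coupling-contact and pattern-contact significances as
``-log10(p_3d_dc) - log10(p_3d_p)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .dca import CouplingScores
from .structure import ContactMap

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


def tail_hypergeom(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n)."""
    return float(math.exp(log10_tail_hypergeom(N, K, n, x) * LN10))


def log10_tail_hypergeom(N: int, K: int, n: int, x: int) -> float:
    """log10 P(X >= x), underflow-safe."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= x <= n):
        raise ValueError(f"invalid hypergeometric arguments N={N} K={K} n={n} x={x}")
    if x == 0:
        return 0.0
    return float(hypergeom.logsf(x - 1, N, K, n) / LN10)


@dataclass
class OverlapResult:
    """Min-over-ladder hypergeometric overlap test."""

    best_cutoff: int
    marked_in_top: int
    log10_raw: float
    log10_adjusted: float
    ladder: tuple[int, ...]
    per_cutoff: dict[int, float] = field(default_factory=dict)  # k -> log10 p
    note: str | None = None

    @property
    def raw_p(self) -> float:
        return 10.0 ** self.log10_raw

    @property
    def adjusted_p(self) -> float:
        return 10.0 ** self.log10_adjusted

    def to_dict(self) -> dict:
        return {
            "best_cutoff": self.best_cutoff,
            "marked_in_top": self.marked_in_top,
            "log10_raw_p": round(self.log10_raw, 6),
            "log10_adjusted_p": round(self.log10_adjusted, 6),
            "ladder": list(self.ladder),
            "note": self.note,
        }


@dataclass
class ClusterResult:
    """Min-over-(center, radius) spatial clustering test."""

    center: int | None            # query coordinate of the argmin center
    radius: float | None
    ball_size: int
    pattern_in_ball: int
    log10_raw: float
    log10_adjusted: float
    n_centers: int
    n_radii: int
    note: str | None = None

    @property
    def raw_p(self) -> float:
        return 10.0 ** self.log10_raw

    @property
    def adjusted_p(self) -> float:
        return 10.0 ** self.log10_adjusted

    def to_dict(self) -> dict:
        return {
            "center": self.center,
            "radius": self.radius,
            "ball_size": self.ball_size,
            "pattern_in_ball": self.pattern_in_ball,
            "log10_raw_p": round(self.log10_raw, 6),
            "log10_adjusted_p": round(self.log10_adjusted, 6),
            "n_centers": self.n_centers,
            "n_radii": self.n_radii,
            "note": self.note,
        }


def _adjust(log10_raw: float, n_tests: int) -> float:
    return min(0.0, log10_raw + math.log10(max(n_tests, 1)))


DEFAULT_LADDER = (5, 10, 20, 50, 100, 200)


def _ladder_overlap(
    ranked: list[tuple[int, int]],
    marked: set[tuple[int, int]],
    N: int,
    ladder: tuple[int, ...],
) -> OverlapResult:
    K = len(marked)
    if K == 0 or N == 0:
        return OverlapResult(0, 0, 0.0, 0.0, tuple(ladder), note="empty marked set")
    ks = sorted({min(k, len(ranked)) for k in ladder if k > 0})
    best_k, best_x, best_lp = ks[0], 0, 0.0
    per = {}
    for k in ks:
        topk = set(ranked[:k])
        x = len(topk & marked)
        lp = log10_tail_hypergeom(N, K, k, x)
        per[k] = lp
        if lp < best_lp:
            best_k, best_x, best_lp = k, x, lp
    if best_lp == 0.0:
        best_x = len(set(ranked[: best_k]) & marked)
    return OverlapResult(
        best_cutoff=best_k,
        marked_in_top=best_x,
        log10_raw=best_lp,
        log10_adjusted=_adjust(best_lp, len(ks)),
        ladder=tuple(ks),
        per_cutoff=per,
    )


def dc_contact_significance(
    scores: CouplingScores,
    contacts: ContactMap,
    ladder: tuple[int, ...] | None = None,
    universe: set[tuple[int, int]] | None = None,
) -> OverlapResult:
    """Significance of the overlap between top DC-scores and 3D contacts.

    The pair universe is the intersection of the score-eligible pairs and
    the mapped-column pairs (``universe``, defaulting to score eligibility).
    """
    if universe is None:
        universe = scores.eligible_pairs
    else:
        universe = universe & scores.eligible_pairs
    ranked = [p for p in scores.ranked_pairs() if p in universe]
    marked = {p for p in contacts.pairs if p in universe}
    if not marked:
        logger.warning("dc_contact_significance: empty contact set; p = 1")
    if ladder is None:
        ladder = DEFAULT_LADDER + (len(ranked),)
    return _ladder_overlap(ranked, marked, len(universe), ladder)


def pattern_dc_significance(
    pattern_cols: list[int] | set[int],
    scores: CouplingScores,
    ladder: tuple[int, ...] | None = None,
    require_both_endpoints: bool = False,
) -> OverlapResult:
    """Significance of the correlation between pattern residues and top
    DC-scores; an insignificant value means the two constraint types are
    complementary rather than redundant."""
    cols = set(pattern_cols)
    if require_both_endpoints:
        marked = {p for p in scores.eligible_pairs if p[0] in cols and p[1] in cols}
    else:
        marked = {p for p in scores.eligible_pairs if p[0] in cols or p[1] in cols}
    if not cols:
        logger.warning("pattern_dc_significance: empty pattern; p = 1")
    ranked = scores.ranked_pairs()
    if ladder is None:
        ladder = DEFAULT_LADDER + (len(ranked),)
    res = _ladder_overlap(ranked, marked, len(scores.eligible_pairs), ladder)
    if res.log10_adjusted > math.log10(0.05):
        res.note = "complementary constraints (no significant pattern-DC overlap)"
    return res


def pattern_contact_significance(
    pattern_cols: list[int] | set[int],
    contacts: ContactMap,
    universe: set[tuple[int, int]],
) -> OverlapResult:
    """Enrichment of pattern-pattern column pairs within the contact set,
    against the universe of mapped column pairs (single test, no ladder)."""
    cols = set(pattern_cols)
    pattern_pairs = {p for p in universe if p[0] in cols and p[1] in cols}
    marked = {p for p in contacts.pairs if p in universe}
    N, K, n = len(universe), len(marked), len(pattern_pairs)
    if n == 0:
        logger.warning("pattern_contact_significance: <2 mapped pattern columns; p = 1")
        return OverlapResult(0, 0, 0.0, 0.0, (), note="fewer than 2 mapped pattern columns")
    x = len(pattern_pairs & marked)
    lp = log10_tail_hypergeom(N, K, n, x)
    return OverlapResult(n, x, lp, lp, (n,))


def cluster_significance(
    pattern_residues: list[int] | set[int],
    all_mapped_residues: list[int],
    distance: np.ndarray | None = None,
    distance_fn=None,
    radii: tuple[float, ...] = (8.0, 10.0, 12.0, 16.0, 20.0),
    centers: list[int] | None = None,
) -> ClusterResult:
    """Spatial clustering of pattern residues on the structure.

    Residues are identified by query coordinate. Distances come either from
    ``distance`` (a matrix indexed like ``all_mapped_residues``) or from
    ``distance_fn(r1, r2)``. For each candidate center (default: the pattern
    residues) and radius, the ball of mapped residues around the center is
    drawn as the urn sample and the pattern residues are the marked balls;
    the reported p is the Bonferroni-adjusted minimum over the search.
    """
    mapped = list(all_mapped_residues)
    pat = sorted(set(pattern_residues) & set(mapped))
    if len(pat) < 2:
        logger.warning("cluster_significance: <2 mapped pattern residues; p = 1")
        return ClusterResult(None, None, 0, len(pat), 0.0, 0.0, 0, len(radii),
                             note="fewer than 2 mapped pattern residues")
    pos = {r: i for i, r in enumerate(mapped)}
    if distance is None:
        if distance_fn is None:
            raise ValueError("need a distance matrix or distance function")
        distance = np.zeros((len(mapped), len(mapped)))
        for i, a in enumerate(mapped):
            for j in range(i + 1, len(mapped)):
                distance[i, j] = distance[j, i] = distance_fn(a, mapped[j])
    if centers is None:
        centers = pat
    N, K = len(mapped), len(pat)
    pat_idx = np.array([pos[r] for r in pat])

    best = (0.0, None, None, 0, 0)  # (log10 p, center, radius, ball, in_ball)
    for c in centers:
        drow = distance[pos[c]]
        for r in radii:
            in_ball = drow <= r
            n_ball = int(in_ball.sum())
            x = int(in_ball[pat_idx].sum())
            lp = log10_tail_hypergeom(N, K, n_ball, x)
            if lp < best[0]:
                best = (lp, c, r, n_ball, x)
    lp, c, r, n_ball, x = best
    return ClusterResult(
        center=c,
        radius=r,
        ball_size=n_ball,
        pattern_in_ball=x,
        log10_raw=lp,
        log10_adjusted=_adjust(lp, len(centers) * len(radii)),
        n_centers=len(centers),
        n_radii=len(radii),
    )


@dataclass
class StructureResult:
    structure_id: str
    node_id: str
    s_3d_dc: OverlapResult
    s_dc_p: OverlapResult
    s_3d_p: OverlapResult
    s_cl_p: ClusterResult

    @property
    def combined_score(self) -> float:
        """-log10(p_3d_dc) - log10(p_3d_p): ranks structures by how well
        couplings and patterns agree with their 3D contacts."""
        return -self.s_3d_dc.log10_adjusted - self.s_3d_p.log10_adjusted

    def to_dict(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "node_id": self.node_id,
            "s_3d_dc": self.s_3d_dc.to_dict(),
            "s_dc_p": self.s_dc_p.to_dict(),
            "s_3d_p": self.s_3d_p.to_dict(),
            "s_cl_p": self.s_cl_p.to_dict(),
            "combined_score": round(self.combined_score, 6),
        }


@dataclass
class ConstraintReport:
    results: list[StructureResult]
    provenance: dict = field(default_factory=dict)
    schema_version: str = "1.0"

    def ranked(self) -> list[StructureResult]:
        return sorted(self.results, key=lambda r: (-r.combined_score, r.structure_id))

    def to_json(self) -> str:
        payload = {
            "schema_version": self.schema_version,
            "provenance": self.provenance,
            "ranking": [r.structure_id for r in self.ranked()],
            "results": [r.to_dict() for r in self.ranked()],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def assemble_report(
    results: list[StructureResult], provenance: dict | None = None
) -> ConstraintReport:
    if not results:
        raise ValueError("no structure results to assemble")
    return ConstraintReport(results, provenance or {})
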