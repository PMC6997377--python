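"""Direct coupling analysis via pseudo-likelihood Potts-model fitting.

Fits an L-site, 21-state Potts model (20 amino acids + gap; ambiguity folded
into gap) to a weighted sub-alignment by minimizing the L2-regularized
negative weighted pseudo-log-likelihood, scores column pairs by the
Frobenius norm of the zero-sum-gauged 20x20 coupling block with average
product correction (APC), and implements the subsampling rank-stability,
lineage-specificity, and co-occurrence-deficit protocols.

The per-site conditional likelihoods are fit jointly but without a symmetry
constraint; the coupling tensor reported is the average of the two
site-conditional estimates, the convention of pseudo-likelihood DCA tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .alphabet import GAP_CODE, N_AA, Q, UNKNOWN_CODE
from .msa_io import Alignment, DegenerateInputError, WeightVector, column_frequencies, sequence_weights

logger = logging.getLogger(__name__)


@dataclass
class PottsModel:
    h: np.ndarray               # (L, Q) fields
    J: np.ndarray               # (L, L, Q, Q), symmetrized, zero diagonal blocks
    lambda_h: float
    lambda_J: float
    grad_norm: float
    n_iterations: int
    converged: bool

    @property
    def L(self) -> int:
        return self.h.shape[0]


@dataclass
class CouplingScores:
    score: np.ndarray           # (L, L) APC-corrected (or raw) scores, sym, 0 diag
    raw: np.ndarray             # (L, L) pre-APC Frobenius scores
    apc_applied: bool
    eligible_pairs: set[tuple[int, int]]  # 1-based (i < j) column pairs

    @property
    def L(self) -> int:
        return self.score.shape[0]

    def ranked_pairs(self) -> list[tuple[int, int]]:
        """Eligible pairs sorted by descending score; ties broken
        lexicographically on (i, j) so ranks are deterministic."""
        return sorted(
            self.eligible_pairs,
            key=lambda p: (-self.score[p[0] - 1, p[1] - 1], p[0], p[1]),
        )

    def top_pairs(self, k: int) -> list[tuple[int, int]]:
        return self.ranked_pairs()[:k]


@dataclass
class SubsampleSummary:
    """Per-pair top-k membership percentages over seeded subsample refits."""

    top_percent: dict[tuple[int, int], dict[int, float]]
    top_ks: tuple[int, ...]
    n_subsamples: int
    subsample_size: int
    seed: int
    L: int
    reduced_budget: bool = True

    def percent(self, pair: tuple[int, int], k: int) -> float:
        i, j = min(pair), max(pair)
        return self.top_percent.get((i, j), {}).get(k, 0.0)


def _encode_potts(aln: Alignment) -> np.ndarray:
    """Integer codes with ambiguity folded into the gap state."""
    mat = aln.matrix().astype(np.int64).copy()
    mat[mat == UNKNOWN_CODE] = GAP_CODE
    return mat


def _pll_objective(x, X1, w, L, q, mask, lam_h, lam_J, true_idx):
    """Negative weighted pseudo-log-likelihood + L2 penalty, with gradient.

    X1: one-hot (n, L*q) float32; mask: (L*q, L*q) zeros on diagonal blocks.
    """
    n = X1.shape[0]
    h = x[: L * q].astype(np.float32)
    W = (x[L * q:].reshape(L * q, L * q) * mask).astype(np.float32)

    logits = X1 @ W.T + h[None, :]            # (n, L*q)
    logits = logits.reshape(n * L, q)
    m = logits.max(axis=1, keepdims=True)
    ez = np.exp(logits - m)
    Z = ez.sum(axis=1)
    logZ = (m[:, 0] + np.log(Z)).reshape(n, L)
    P = (ez / Z[:, None]).reshape(n, L * q)

    wrep = np.repeat(w, L)
    ll_true = logits[np.arange(n * L), true_idx]
    nll = float((wrep * (logZ.reshape(-1) - ll_true)).sum())

    R = (P - X1) * w[:, None].astype(np.float32)  # (n, L*q)
    grad_h = R.sum(axis=0).astype(np.float64)
    grad_W = (R.T @ X1).astype(np.float64) * mask

    f = nll + lam_h * float((h.astype(np.float64) ** 2).sum()) \
        + 0.5 * lam_J * float((W.astype(np.float64) ** 2).sum())
    grad_h += 2.0 * lam_h * h
    grad_W += lam_J * W
    return f, np.concatenate([grad_h, grad_W.reshape(-1)])


def fit_plm(
    aln: Alignment,
    w: WeightVector,
    lambda_h: float = 0.01,
    lambda_J: float | None = None,
    tol: float = 1e-4,
    max_iter: int = 150,
    seed: int = 0,
) -> PottsModel:
    """Fit the Potts model by L-BFGS-B on the weighted pseudo-likelihood.

    ``lambda_J`` defaults to ``0.2 * (L - 1)``. ``seed`` is accepted for
    interface symmetry; the optimization itself is deterministic (zero
    initialization).
    """
    L = aln.n_columns
    if L < 2:
        raise DegenerateInputError("need at least two columns")
    if w.effective_count < 1:
        raise DegenerateInputError("effective count below 1")
    if lambda_J is None:
        lambda_J = 0.2 * (L - 1)
    q = Q
    mat = _encode_potts(aln)
    n = mat.shape[0]

    X1 = np.zeros((n, L * q), dtype=np.float32)
    flat = np.arange(L) * q + mat
    X1[np.repeat(np.arange(n), L), flat.reshape(-1)] = 1.0
    true_idx = mat.reshape(-1)  # state code per (record, site) in the (n*L, q) view

    mask = np.ones((L * q, L * q))
    for i in range(L):
        mask[i * q:(i + 1) * q, i * q:(i + 1) * q] = 0.0
    weights = w.weights.astype(np.float32)

    x0 = np.zeros(L * q + (L * q) ** 2)
    res = minimize(
        _pll_objective,
        x0,
        args=(X1, weights, L, q, mask, lambda_h, lambda_J, true_idx),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol * max(1.0, w.effective_count),
                 "ftol": 1e-12},
    )
    if not np.isfinite(res.fun):
        raise FloatingPointError(f"non-finite objective: {res}")

    h = res.x[: L * q].reshape(L, q)
    W = (res.x[L * q:].reshape(L * q, L * q) * mask).reshape(L, q, L, q)
    W = W.transpose(0, 2, 1, 3)                       # (L, L, q, q)
    J = 0.5 * (W + W.transpose(1, 0, 3, 2))           # average of both conditionals
    for i in range(L):
        J[i, i] = 0.0
    grad_norm = float(np.linalg.norm(res.jac))
    return PottsModel(h, J, lambda_h, lambda_J, grad_norm, res.nit,
                      converged=bool(res.success))


def score_couplings(
    model: PottsModel,
    apc: bool = True,
    gap_frequency: np.ndarray | None = None,
    max_gap_frequency: float = 0.5,
) -> CouplingScores:
    """Frobenius-norm coupling scores with average product correction.

    Each 20x20 amino-acid block of J is put in the zero-sum gauge before the
    norm is taken; gap-state rows/columns never enter. Columns whose gap
    frequency exceeds ``max_gap_frequency`` are excluded from the eligible
    pair set (they produce spurious couplings).
    """
    L = model.L
    B = model.J[:, :, :N_AA, :N_AA]
    B = (
        B
        - B.mean(axis=2, keepdims=True)
        - B.mean(axis=3, keepdims=True)
        + B.mean(axis=(2, 3), keepdims=True)
    )
    raw = np.sqrt((B ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(raw, 0.0)
    raw = 0.5 * (raw + raw.T)

    if gap_frequency is not None:
        eligible_cols = np.nonzero(np.asarray(gap_frequency) <= max_gap_frequency)[0]
    else:
        eligible_cols = np.arange(L)
    elig = np.zeros(L, dtype=bool)
    elig[eligible_cols] = True

    score = raw.copy()
    if apc:
        sub = raw[np.ix_(eligible_cols, eligible_cols)]
        m = len(eligible_cols)
        if m >= 2:
            col_mean = sub.sum(axis=0) / (m - 1)
            all_mean = sub.sum() / (m * (m - 1))
            corr = sub - np.outer(col_mean, col_mean) / all_mean
            np.fill_diagonal(corr, 0.0)
            score[np.ix_(eligible_cols, eligible_cols)] = corr

    pairs = {
        (i + 1, j + 1)
        for i in range(L)
        for j in range(i + 1, L)
        if elig[i] and elig[j]
    }
    return CouplingScores(score, raw, apc, pairs)


def dca_scores(
    aln: Alignment,
    w: WeightVector | None = None,
    apc: bool = True,
    max_gap_frequency: float = 0.5,
    **fit_kwargs,
) -> CouplingScores:
    """Convenience pipeline: weights -> fit -> APC scores."""
    if w is None:
        w = sequence_weights(aln)
    model = fit_plm(aln, w, **fit_kwargs)
    gaps = column_frequencies(aln, w).gap_frequency()
    return score_couplings(model, apc=apc, gap_frequency=gaps,
                           max_gap_frequency=max_gap_frequency)


def subsample_ranks(
    aln: Alignment,
    n_subsamples: int = 1000,
    subsample_size: int = 1000,
    top_ks: tuple[int, ...] = (20, 10, 5, 2),
    seed: int = 0,
    fit_max_iter: int = 50,
    fit_tol: float = 1e-3,
) -> SubsampleSummary:
    """Rank stability of DC-scores under repeated random subsampling.

    For each seeded draw (without replacement) of ``subsample_size`` records,
    weights are recomputed, the model refit at a reduced optimizer budget,
    and every pair's membership in the top-k scores tallied for each k.
    """
    rng = np.random.default_rng(seed)
    n = aln.n_records
    size = subsample_size
    if size > n:
        logger.warning("subsample_size %d > %d records; using full alignment", size, n)
        size = n
    ks = tuple(sorted(top_ks, reverse=True))
    counts: dict[tuple[int, int], dict[int, int]] = {}
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=size, replace=False)
        ids = [aln.records[i].id for i in sorted(idx)]
        if aln.query_id not in ids:
            ids[0] = aln.query_id
        sub = aln.subset(ids)
        scores = dca_scores(sub, max_iter=fit_max_iter, tol=fit_tol)
        ranked = scores.ranked_pairs()
        for k in ks:
            for pair in ranked[:k]:
                counts.setdefault(pair, {}).setdefault(k, 0)
                counts[pair][k] += 1
    pct = {
        pair: {k: round(100.0 * kc.get(k, 0) / n_subsamples, 1) for k in ks}
        for pair, kc in counts.items()
    }
    return SubsampleSummary(pct, ks, n_subsamples, size, seed, aln.n_columns)


def specificity_flag(
    pair: tuple[int, int],
    fg_summary: SubsampleSummary,
    bg_summaries: list[SubsampleSummary],
    k: int = 20,
) -> bool:
    """Lineage-specificity screen: a pair is specific iff it never appears in
    the top-k of any background subsampling analysis (not even once)."""
    if not bg_summaries:
        raise ValueError("specificity screen undefined without backgrounds")
    for bg in bg_summaries:
        if bg.L != fg_summary.L:
            raise ValueError(
                f"column-frame mismatch: background L={bg.L}, foreground L={fg_summary.L}"
            )
    return all(bg.percent(pair, k) == 0.0 for bg in bg_summaries)


def cooccurrence_deficit(
    aln: Alignment, w: WeightVector, pair: tuple[int, int]
) -> tuple[float, bool]:
    """Ratio of the weighted joint frequency of the two columns' modal
    residues to the product of their marginals; a ratio below 1 marks a pair
    whose modal combination is depleted and cannot drive the DC-score."""
    i, j = pair
    profile = column_frequencies(aln, w)
    freqs = profile.frequencies
    mi = int(freqs[i - 1, :N_AA].argmax())
    mj = int(freqs[j - 1, :N_AA].argmax())
    pi, pj = freqs[i - 1, mi], freqs[j - 1, mj]
    if pi <= 0 or pj <= 0:
        raise DegenerateInputError(f"no modal non-gap residue at column {i if pi <= 0 else j}")
    mat = aln.matrix()
    ok = mat[:, [i - 1, j - 1]] != UNKNOWN_CODE
    wts = w.weights * ok.all(axis=1)
    total = wts.sum()
    if total <= 0:
        raise DegenerateInputError("no records observed at both columns")
    joint = float((wts * (mat[:, i - 1] == mi) * (mat[:, j - 1] == mj)).sum() / total)
    ratio = joint / (pi * pj)
    return float(ratio), bool(ratio < 1.0)


def write_scores_tsv(scores: CouplingScores, aln: Alignment | None, path,
                     summary: SubsampleSummary | None = None) -> None:
    qcoord = aln.column_to_query_coord() if aln is not None else {}
    ks = summary.top_ks if summary is not None else ()
    with open(path, "w") as fh:
        header = "col_i\tcol_j\tquery_i\tquery_j\traw\tapc"
        header += "".join(f"\ttop{k}_pct" for k in ks)
        fh.write(header + "\n")
        for i, j in scores.ranked_pairs():
            line = (f"{i}\t{j}\t{qcoord.get(i, '')}\t{qcoord.get(j, '')}\t"
                    f"{scores.raw[i - 1, j - 1]:.5f}\t{scores.score[i - 1, j - 1]:.5f}")
            line += "".join(f"\t{summary.percent((i, j), k):.1f}" for k in ks)
            fh.write(line + "\n")
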