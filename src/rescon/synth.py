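"""Seeded synthetic-data generators.

Three generators emit data with the statistical structure each analysis
stage assumes: Potts-sampled alignments with planted directly coupled column
pairs, subgroup-patterned alignments with planted discriminating columns,
and toy single-chain structures with planted spatial clusters. Each returns
the data together with a :class:`PlantedTruth` record sufficient to score
the downstream stage without re-derivation. Every generator is a pure
function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA20, N_AA
from .msa_io import Alignment, Record
from .structure import Residue, StructureModel


@dataclass
class PlantedTruth:
    group_of: dict[str, int] = field(default_factory=dict)
    pattern_columns: dict[int, list[tuple[int, str]]] = field(default_factory=dict)
    coupled_pairs: list[tuple[int, int]] = field(default_factory=list)
    cluster_members: list[int] = field(default_factory=list)
    cluster_center: tuple[float, float, float] | None = None
    cluster_radius: float | None = None


class GeneratorError(RuntimeError):
    pass


def _softmax_sample(logits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one categorical per row of ``logits`` (n, q)."""
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random((logits.shape[0], 1))
    return (p.cumsum(axis=1) < u).sum(axis=1)


def sample_potts(
    L: int,
    n: int,
    planted_pairs: list[tuple[int, int]],
    coupling_strength: float = 2.0,
    q: int = 20,
    seed: int = 0,
    burn_in_sweeps: int = 300,
    query_id: str = "potts_q",
) -> tuple[Alignment, PlantedTruth]:
    """Gibbs-sample ``n`` sequences from a Potts model with planted couplings.

    Fields are zero; the coupling block of each planted pair (1-based column
    indices) is ``coupling_strength`` on the matched-state diagonal and zero
    elsewhere, favoring identical states at the two columns. Sampling runs
    ``n`` independent single-site Gibbs chains in parallel from random
    initial states, burned in for ``burn_in_sweeps`` full sweeps; emitted
    samples are therefore exactly independent across records.
    """
    if L < 2 or n < 1:
        raise ValueError("need L >= 2 and n >= 1")
    rng = np.random.default_rng(seed)
    pairs0 = [(i - 1, j - 1) for i, j in planted_pairs]
    for i, j in pairs0:
        if not (0 <= i < L and 0 <= j < L and i != j):
            raise ValueError(f"invalid planted pair {(i + 1, j + 1)}")

    neighbors: dict[int, list[int]] = {i: [] for i in range(L)}
    for i, j in pairs0:
        neighbors[i].append(j)
        neighbors[j].append(i)

    X = rng.integers(0, q, size=(n, L))
    states = np.arange(q)
    for _ in range(burn_in_sweeps):
        for i in range(L):
            logits = np.zeros((n, q))
            for j in neighbors[i]:
                # matched-state diagonal coupling: J[a,b] = s * [a == b]
                logits += coupling_strength * (states[None, :] == X[:, j, None])
            X[:, i] = _softmax_sample(logits, rng)

    records = []
    for r in range(n):
        rid = query_id if r == 0 else f"potts_{r:05d}"
        records.append(Record(rid, "".join(AA20[c] for c in X[r])))
    aln = Alignment(records, query_id)
    truth = PlantedTruth(coupled_pairs=sorted(tuple(sorted(p)) for p in planted_pairs))
    return aln, truth


def make_subgrouped_msa(
    group_sizes: list[int],
    L: int,
    pattern_cols_per_group: int = 8,
    fg_conservation: float = 0.9,
    background: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[Alignment, PlantedTruth]:
    """Emit an MSA of i.i.d. background columns with planted subgroup patterns.

    Each group owns a disjoint set of ``pattern_cols_per_group`` columns; at
    those columns its members carry the planted residue with probability
    ``fg_conservation`` and otherwise draw from the background composition
    (uniform over the 20 amino acids by default). The query is the first
    record of group 1.
    """
    n_groups = len(group_sizes)
    if n_groups * pattern_cols_per_group > L:
        raise ValueError("not enough columns for disjoint group patterns")
    rng = np.random.default_rng(seed)
    comp = np.full(N_AA, 1.0 / N_AA) if background is None else np.asarray(background)
    comp = comp / comp.sum()

    cols = rng.permutation(L)[: n_groups * pattern_cols_per_group]
    pattern_cols = {
        g + 1: sorted(int(c) + 1 for c in cols[g * pattern_cols_per_group:(g + 1) * pattern_cols_per_group])
        for g in range(n_groups)
    }
    planted_res = {
        g: [(c, AA20[rng.integers(0, N_AA)]) for c in cols_g]
        for g, cols_g in pattern_cols.items()
    }

    n_total = sum(group_sizes)
    X = rng.choice(N_AA, size=(n_total, L), p=comp)
    group_of_row = np.repeat(np.arange(1, n_groups + 1), group_sizes)
    for g in range(1, n_groups + 1):
        rows = np.nonzero(group_of_row == g)[0]
        for col1, aa in planted_res[g]:
            hit = rng.random(rows.size) < fg_conservation
            X[rows[hit], col1 - 1] = AA20.index(aa)

    records = []
    truth = PlantedTruth(pattern_columns=planted_res)
    query_id = "g1_s0000"
    for r in range(n_total):
        rid = f"g{group_of_row[r]}_s{r:04d}"
        records.append(Record(rid, "".join(AA20[c] for c in X[r])))
        truth.group_of[rid] = int(group_of_row[r])
    return Alignment(records, query_id), truth


def make_toy_structure(
    n_residues: int,
    geometry: str = "extended_helix",
    planted_cluster: tuple[list[int], float] | None = None,
    seed: int = 0,
    structure_id: str = "toy",
    chain_id: str = "A",
    max_retries: int = 2000,
) -> tuple[StructureModel, PlantedTruth]:
    """Build a one-pseudo-atom-per-residue toy chain with an optional planted
    spatial cluster.

    Geometries: ``extended_helix`` (1.5 A rise, 100 deg turn, 2.3 A radius)
    or ``random_walk`` (3.8 A steps, self-avoidance by rejection). When a
    planted cluster ``(members, radius)`` is given (1-based residue indices),
    those residues are relocated uniformly inside a ball of that radius
    centered at the first member's original position.
    """
    rng = np.random.default_rng(seed)
    if geometry == "extended_helix":
        t = np.arange(n_residues)
        theta = np.deg2rad(100.0) * t
        coords = np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t]
        )
    elif geometry == "random_walk":
        coords = np.zeros((n_residues, 3))
        for i in range(1, n_residues):
            for attempt in range(max_retries):
                step = rng.normal(size=3)
                step *= 3.8 / np.linalg.norm(step)
                cand = coords[i - 1] + step
                if i < 2 or np.linalg.norm(coords[: i - 1] - cand, axis=1).min() > 3.0:
                    coords[i] = cand
                    break
            else:
                raise GeneratorError("self-avoiding walk failed after retries")
    else:
        raise ValueError(f"unknown geometry: {geometry!r}")

    truth = PlantedTruth()
    if planted_cluster is not None:
        members, radius = planted_cluster
        if not all(1 <= m <= n_residues for m in members):
            raise ValueError("cluster members outside residue range")
        center = coords[members[0] - 1].copy()
        for m in members:
            # uniform in ball: normalized gaussian direction, r ~ R * U^(1/3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            coords[m - 1] = center + d * radius * rng.random() ** (1 / 3)
        truth.cluster_members = sorted(members)
        truth.cluster_center = tuple(float(x) for x in center)
        truth.cluster_radius = float(radius)

    aas = [AA20[c] for c in rng.integers(0, N_AA, size=n_residues)]
    residues = [
        Residue(
            auth_number=i + 1,
            insertion_code="",
            amino_acid=aas[i],
            atom_names=["CA"],
            coords=coords[i:i + 1].copy(),
        )
        for i in range(n_residues)
    ]
    return StructureModel(structure_id, chain_id, residues), truth


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def write_pdb(model: StructureModel, path) -> None:
    """Write a minimal single-chain PDB file (pseudo-atoms as CA)."""
    with open(path, "w") as fh:
        serial = 1
        for res in model.residues:
            res3 = _AA3.get(res.amino_acid, "UNK")
            for name, (x, y, z) in zip(res.atom_names, res.coords):
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s}{res3:>4s} {model.chain_id}"
                    f"{res.auth_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00           {name[0]:>2s}\n"
                )
                serial += 1
        fh.write("END\n")
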