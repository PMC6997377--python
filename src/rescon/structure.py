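"""Structure parsing, column-to-residue mapping, and contact maps."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .alphabet import GAP_CODE

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    pass


class MappingError(ValueError):
    pass


@dataclass
class Residue:
    auth_number: int
    insertion_code: str
    amino_acid: str  # one-letter code, 'X' for unknown
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3), heavy atoms only, Angstrom

    def atom(self, name: str) -> np.ndarray | None:
        try:
            return self.coords[self.atom_names.index(name)]
        except ValueError:
            return None


@dataclass
class StructureModel:
    structure_id: str
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body transformed copy (testing aid)."""
        new = []
        for r in self.residues:
            new.append(
                Residue(r.auth_number, r.insertion_code, r.amino_acid,
                        list(r.atom_names), r.coords @ rotation.T + translation)
            )
        return StructureModel(self.structure_id, self.chain_id, new)


@dataclass
class ColumnResidueMap:
    """Bijective correspondence between alignment columns and residue indices.

    ``column_to_residue`` maps 1-based alignment columns to 0-based indices
    into ``StructureModel.residues``; mismatched (non-identical) aligned
    positions are listed in ``mismatches``.
    """

    column_to_residue: dict[int, int]
    coverage: float
    mismatches: list[int] = field(default_factory=list)

    @property
    def residue_to_column(self) -> dict[int, int]:
        return {v: k for k, v in self.column_to_residue.items()}

    @property
    def mapped_columns(self) -> list[int]:
        return sorted(self.column_to_residue)


@dataclass
class ContactMap:
    """Unordered mapped-column pairs in 3D contact, with minimal distances."""

    pairs: dict[tuple[int, int], float]  # (col_i < col_j) -> min distance (A)
    cutoff: float
    min_separation: int

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


_WATER = {"HOH", "WAT", "DOD"}


def parse_structure(path, chain: str, structure_id: str | None = None) -> StructureModel:
    """Parse a PDB or mmCIF file into a single-chain :class:`StructureModel`.

    Hydrogens and waters are dropped; alternate locations are resolved to the
    highest-occupancy conformer (ties broken toward altloc 'A').
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = [ch.name for ch in model]
    if chain not in chains:
        raise StructureError(
            f"chain {chain!r} not found in {path}; available chains: {chains}"
        )

    residues = []
    for res in model[chain]:
        if res.name in _WATER:
            continue
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        one = info.one_letter_code.upper()
        if not one.isalpha():
            one = "X"
        by_name: dict[str, tuple[float, str, np.ndarray]] = {}
        for atom in res:
            if atom.is_hydrogen():
                continue
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            alt = atom.altloc or "A"
            prev = by_name.get(atom.name)
            # keep highest occupancy; on ties prefer the alphabetically
            # first altloc (so 'A' wins)
            if prev is None or (atom.occ, prev[1]) > (prev[0], alt):
                by_name[atom.name] = (atom.occ, alt, pos)
        if not by_name:
            continue
        names = list(by_name)
        coords = np.array([by_name[n][2] for n in names])
        residues.append(
            Residue(res.seqid.num, res.seqid.icode.strip(), one, names, coords)
        )
    sid = structure_id or st.name or str(path)
    return StructureModel(sid, chain, residues)


def map_columns(
    aln,
    structure: StructureModel,
    min_coverage: float = 0.30,
    mismatch_tolerance: float = 0.05,
) -> ColumnResidueMap:
    """Map alignment columns onto structure residues by global pairwise
    alignment (identity scoring, affine gaps, free end gaps) of the query's
    ungapped sequence against the structure's residue sequence."""
    qrow = aln.matrix()[aln.query_index]
    qcols = np.nonzero(qrow != GAP_CODE)[0] + 1  # 1-based alignment columns
    qseq = "".join(aln.query.row[c - 1] for c in qcols)
    sseq = structure.sequence
    if not qseq or not sseq:
        raise MappingError("empty query or structure sequence")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -0.5
    try:  # free end gaps (attribute names changed across Biopython releases)
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    alignment = aligner.align(qseq, sseq)[0]

    pairs: list[tuple[int, int]] = []  # (query ungapped idx, residue idx)
    for (qs, qe), (ss, se) in zip(*alignment.aligned):
        pairs.extend(zip(range(qs, qe), range(ss, se)))

    identical = [(qi, si) for qi, si in pairs if qseq[qi] == sseq[si]]
    coverage = len(identical) / len(qseq)
    if coverage < min_coverage:
        raise MappingError(
            f"structure {structure.structure_id}: mapping coverage "
            f"{coverage:.2f} below {min_coverage:.2f}"
        )
    n_mismatch = len(pairs) - len(identical)
    if pairs and n_mismatch / len(pairs) > mismatch_tolerance:
        logger.warning(
            "%d/%d mapped positions mismatch the query; keeping identical "
            "positions only", n_mismatch, len(pairs),
        )
        kept = identical
        mismatches: list[int] = []
    else:
        kept = pairs
        mismatches = [int(qcols[qi]) for qi, si in pairs if qseq[qi] != sseq[si]]

    col_to_res = {int(qcols[qi]): si for qi, si in kept}
    return ColumnResidueMap(col_to_res, coverage, mismatches)


def residue_distance(
    structure: StructureModel, r1: int, r2: int, mode: str = "min_heavy"
) -> float:
    """Distance (A) between residues ``r1`` and ``r2`` (0-based indices)."""
    a, b = structure.residues[r1], structure.residues[r2]
    if mode == "min_heavy":
        diff = a.coords[:, None, :] - b.coords[None, :, :]
        return float(np.sqrt((diff ** 2).sum(axis=2)).min())
    if mode == "c_beta":
        pts = []
        for res in (a, b):
            p = res.atom("CB")
            if p is None:
                p = res.atom("CA")
            if p is None:
                raise StructureError(
                    f"residue {res.auth_number} has neither CB nor CA"
                )
            pts.append(p)
        return float(np.linalg.norm(pts[0] - pts[1]))
    raise ValueError(f"unknown mode: {mode!r}")


def _min_distance_matrix(structure: StructureModel, indices: list[int]) -> np.ndarray:
    """Minimal heavy-atom distance matrix among the listed residues."""
    coords = [structure.residues[i].coords for i in indices]
    m = len(indices)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            diff = coords[i][:, None, :] - coords[j][None, :, :]
            D[i, j] = D[j, i] = np.sqrt((diff ** 2).sum(axis=2)).min()
    return D


def compute_contacts(
    structure: StructureModel,
    cmap: ColumnResidueMap,
    aln=None,
    cutoff: float = 5.0,
    min_separation: int = 5,
    mode: str = "min_heavy",
) -> ContactMap:
    """Contacts among mapped columns: minimal heavy-atom distance <= cutoff
    and query-coordinate separation >= ``min_separation``.

    Separation uses query coordinates when ``aln`` is given (1-based ungapped
    positions of the query), otherwise alignment columns.
    """
    if not cmap.column_to_residue:
        raise MappingError("empty column-residue map")
    cols = cmap.mapped_columns
    res_idx = [cmap.column_to_residue[c] for c in cols]
    if mode == "min_heavy":
        D = _min_distance_matrix(structure, res_idx)
    else:
        m = len(res_idx)
        D = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                D[i, j] = D[j, i] = residue_distance(structure, res_idx[i], res_idx[j], mode)

    qcoord = aln.column_to_query_coord() if aln is not None else {c: c for c in cols}
    pairs = {}
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            ci, cj = cols[i], cols[j]
            if abs(qcoord[ci] - qcoord[cj]) < min_separation:
                continue
            if D[i, j] <= cutoff:
                pairs[(ci, cj)] = float(D[i, j])
    return ContactMap(pairs, cutoff, min_separation)


def compute_trans_contacts(
    structure_a: StructureModel,
    map_a: ColumnResidueMap,
    structure_b: StructureModel,
    map_b: ColumnResidueMap,
    cutoff: float = 5.0,
) -> ContactMap:
    """Inter-chain (trans) contacts between two mapped chains; the sequence
    separation rule is waived across chains."""
    pairs = {}
    for ca, ra in map_a.column_to_residue.items():
        A = structure_a.residues[ra].coords
        for cb, rb in map_b.column_to_residue.items():
            if cb == ca:
                continue  # degenerate column pair
            B = structure_b.residues[rb].coords
            d = float(np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)).min())
            if d <= cutoff:
                key = (min(ca, cb), max(ca, cb))
                pairs[key] = min(d, pairs.get(key, np.inf))
    return ContactMap(pairs, cutoff, 0)


def write_contacts_tsv(contacts: ContactMap, aln, path) -> None:
    qcoord = aln.column_to_query_coord() if aln is not None else {}
    with open(path, "w") as fh:
        fh.write("col_i\tcol_j\tquery_i\tquery_j\tdistance\n")
        for (i, j), d in sorted(contacts.pairs.items()):
            fh.write(f"{i}\t{j}\t{qcoord.get(i, '')}\t{qcoord.get(j, '')}\t{d:.3f}\n")
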