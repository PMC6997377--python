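"""Read, validate, filter, and weight multiple sequence alignments.

Columns are 1-based throughout the toolkit; query coordinates are 1-based
ungapped indices into the query row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import AlignIO, SeqIO

from .alphabet import (
    AA_INDEX,
    ALPHABET,
    GAP,
    GAP_CODE,
    N_AA,
    UNKNOWN,
    UNKNOWN_CODE,
    decode,
)

logger = logging.getLogger(__name__)


class AlignmentFormatError(ValueError):
    """Raised for ragged rows, empty files, or invalid alphabets."""


class DegenerateInputError(ValueError):
    """Raised when an operation receives an input it cannot act on."""


@dataclass(frozen=True)
class Record:
    id: str
    row: str
    taxon_label: str | None = None


@dataclass
class Alignment:
    """An MSA with a designated query row and purge-protected structure ids."""

    records: list[Record]
    query_id: str
    structure_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentFormatError("empty alignment")
        ncol = len(self.records[0].row)
        for rec in self.records:
            if len(rec.row) != ncol:
                raise AlignmentFormatError(
                    f"ragged alignment: record '{rec.id}' has length "
                    f"{len(rec.row)}, expected {ncol}"
                )
            bad = set(rec.row) - set(ALPHABET)
            if bad:
                raise AlignmentFormatError(
                    f"record '{rec.id}' contains invalid characters {sorted(bad)}"
                )
        n_query = sum(1 for r in self.records if r.id == self.query_id)
        if n_query != 1:
            raise AlignmentFormatError(
                f"query id '{self.query_id}' matches {n_query} records, expected 1"
            )
        self._matrix: np.ndarray | None = None

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0].row)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def query(self) -> Record:
        return next(r for r in self.records if r.id == self.query_id)

    @property
    def query_index(self) -> int:
        return next(i for i, r in enumerate(self.records) if r.id == self.query_id)

    def matrix(self) -> np.ndarray:
        """Integer-coded (n_records, n_columns) matrix (cached)."""
        if self._matrix is None:
            self._matrix = np.vstack(
                [np.frombuffer(r.row.encode(), np.uint8) for r in self.records]
            )
            lut = np.full(128, UNKNOWN_CODE, dtype=np.int8)
            for ch, i in AA_INDEX.items():
                lut[ord(ch)] = i
            self._matrix = lut[self._matrix]
        return self._matrix

    def query_columns(self) -> np.ndarray:
        """1-based alignment columns where the query row is non-gap."""
        codes = self.matrix()[self.query_index]
        return np.nonzero(codes != GAP_CODE)[0] + 1

    def column_to_query_coord(self) -> dict[int, int]:
        """Map 1-based alignment column -> 1-based query residue position."""
        return {int(c): i + 1 for i, c in enumerate(self.query_columns())}

    def subset(self, ids: set[str] | list[str]) -> "Alignment":
        keep = set(ids)
        recs = [r for r in self.records if r.id in keep]
        return Alignment(recs, self.query_id, self.structure_ids)


def _normalize_row(raw: str) -> tuple[str, int]:
    """Uppercase, '.'->'-', unknown characters -> 'X'; returns (row, n_mapped)."""
    row = raw.upper().replace(".", GAP)
    n_unknown = 0
    out = []
    valid = set(ALPHABET)
    for ch in row:
        if ch in valid:
            out.append(ch)
        else:
            out.append(UNKNOWN)
            n_unknown += 1
    return "".join(out), n_unknown


def read_alignment(
    path,
    query_id: str,
    fmt: str = "fasta",
    structure_ids: set[str] | None = None,
    taxon_token: str = "taxon=",
) -> Alignment:
    """Read an aligned FASTA or Stockholm file.

    The taxon label is parsed from the first description token starting with
    ``taxon_token`` (e.g. ``taxon=Proteobacteria``), when present.
    """
    if fmt == "fasta":
        seqrecs = list(SeqIO.parse(str(path), "fasta"))
    elif fmt == "stockholm":
        seqrecs = list(AlignIO.read(str(path), "stockholm"))
    else:
        raise ValueError(f"unsupported format: {fmt!r}")
    if not seqrecs:
        raise AlignmentFormatError(f"empty input: {path}")

    lengths = {len(sr.seq) for sr in seqrecs}
    if len(lengths) > 1:
        expected = len(seqrecs[0].seq)
        bad = next(sr for sr in seqrecs if len(sr.seq) != expected)
        raise AlignmentFormatError(
            f"ragged alignment: record '{bad.id}' has length {len(bad.seq)}, "
            f"expected {expected}"
        )

    records = []
    total_unknown = 0
    for sr in seqrecs:
        row, n_unknown = _normalize_row(str(sr.seq))
        total_unknown += n_unknown
        taxon = None
        for tok in (sr.description or "").split():
            if tok.startswith(taxon_token):
                taxon = tok[len(taxon_token):]
                break
        records.append(Record(sr.id, row, taxon))
    if total_unknown:
        logger.warning("mapped %d unknown characters to 'X'", total_unknown)
    return Alignment(records, query_id, frozenset(structure_ids or ()))


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rec in aln.records:
            desc = f" taxon={rec.taxon_label}" if rec.taxon_label else ""
            fh.write(f">{rec.id}{desc}\n{rec.row}\n")


@dataclass(frozen=True)
class WeightVector:
    weights: np.ndarray

    @property
    def effective_count(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class ColumnProfile:
    """Weighted per-column frequencies over 21 states (20 aa + gap).

    'X' contributes no mass; each column is renormalized over observed states.
    """

    frequencies: np.ndarray  # (n_columns, 21)

    @property
    def modal_state(self) -> np.ndarray:
        return self.frequencies.argmax(axis=1)

    @property
    def modal_residue(self) -> list[str]:
        return [ALPHABET[s] for s in self.modal_state]

    @property
    def modal_frequency(self) -> np.ndarray:
        return self.frequencies.max(axis=1)

    def gap_frequency(self) -> np.ndarray:
        return self.frequencies[:, GAP_CODE]


def remove_fragments(aln: Alignment, max_deletion_fraction: float = 0.25) -> Alignment:
    """Drop fragment records with too many deletions relative to the query.

    A record's deletion fraction is the share of gap characters it carries in
    the columns where the query is non-gap. Records strictly above the
    threshold are removed; the query itself never is.
    """
    mat = aln.matrix()
    qcols = aln.query_columns() - 1
    if qcols.size == 0:
        raise DegenerateInputError("query row is all gaps")
    del_frac = (mat[:, qcols] == GAP_CODE).mean(axis=1)
    keep = [
        rec
        for rec, f in zip(aln.records, del_frac)
        if f <= max_deletion_fraction or rec.id == aln.query_id
    ]
    n_removed = aln.n_records - len(keep)
    if n_removed:
        logger.info("remove_fragments: removed %d of %d records", n_removed, aln.n_records)
    return Alignment(keep, aln.query_id, aln.structure_ids)


def pairwise_identity_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise identity over mutually non-gap columns, normalized by the
    shorter non-gap length of the two rows."""
    mat = aln.matrix()
    n = aln.n_records
    is_res = mat < N_AA  # amino-acid positions only ('X' and '-' excluded)
    nongap = is_res.sum(axis=1)
    ident = np.eye(n)
    for i in range(n):
        both = is_res[i] & is_res
        matches = ((mat == mat[i]) & both).sum(axis=1)
        denom = np.minimum(nongap[i], nongap).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(denom > 0, matches / denom, 0.0)
        ident[i] = row
        ident[i, i] = 1.0
    return ident


def purge_redundant(aln: Alignment, max_identity: float = 0.95) -> Alignment:
    """Collapse near-identical records by greedy single-linkage clustering.

    One representative (first in input order) is kept per cluster of records
    linked at pairwise identity >= ``max_identity``; the query and any record
    whose id is in ``structure_ids`` are always retained.
    """
    ident = pairwise_identity_matrix(aln)
    n = aln.n_records
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in np.nonzero(ident[i] >= max_identity)[0]:
            if j <= i:
                continue
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    seen_root: set[int] = set()
    keep = []
    protected = set(aln.structure_ids) | {aln.query_id}
    for i, rec in enumerate(aln.records):
        root = find(i)
        if root not in seen_root:
            seen_root.add(root)
            keep.append(rec)
        elif rec.id in protected:
            keep.append(rec)
    return Alignment(keep, aln.query_id, aln.structure_ids)


def sequence_weights(aln: Alignment, cluster_identity: float = 0.80) -> WeightVector:
    """Redundancy weights: 1 / (number of records within ``cluster_identity``
    of the record, inclusive of itself)."""
    if aln.n_records == 0:
        raise DegenerateInputError("empty alignment")
    ident = pairwise_identity_matrix(aln)
    counts = (ident >= cluster_identity).sum(axis=1)
    return WeightVector(1.0 / counts)


def column_frequencies(aln: Alignment, w: WeightVector) -> ColumnProfile:
    if len(w.weights) != aln.n_records:
        raise ValueError("weight vector length does not match record count")
    if w.effective_count <= 0:
        raise DegenerateInputError("zero effective count")
    mat = aln.matrix()
    freqs = np.zeros((aln.n_columns, 21))
    for state in range(21):
        freqs[:, state] = ((mat == state) * w.weights[:, None]).sum(axis=0)
    totals = freqs.sum(axis=1)
    if np.any(totals <= 0):
        raise DegenerateInputError("column with no observed states (all 'X')")
    return ColumnProfile(freqs / totals[:, None])


def frequency_digit(freq: float) -> int:
    """Conservation digit in integer tenths: floor(10*f), capped at 9."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency out of range: {freq}")
    return min(int(freq * 10), 9)
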