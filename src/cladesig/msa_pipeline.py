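"""Per-family alignment, conserved-block trimming, and concatenation.

The built-in aligner is a deterministic progressive aligner (k-mer
distances, UPGMA guide tree, profile-profile Needleman-Wunsch with
BLOSUM62/11/1); externally produced aligned FASTA can be imported
through :mod:`cladesig.sequence_io` for fidelity to other tools.  The
block filter keeps contiguous well-conserved, gap-poor stretches of
columns, in the spirit of relaxed Gblocks-style trimming, and the
concatenation step builds the supermatrix with an explicit partition
map so every column is traceable to its source family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._align import (ALPHABET, BLOSUM62, GAP, GAP_EXTEND, GAP_OPEN, N_AA,
                     encode, profile_nw)
from .core_families import ProteinFamily
from .sequence_io import SequenceRecord

_GAP_CODE = len(ALPHABET)  # 21: gap in the profile encoding


@dataclass
class Msa:
    """A multiple sequence alignment; all rows equal length, no all-gap
    column."""

    records: list[SequenceRecord]
    family_id: str | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        length = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != length:
                raise ValueError(
                    f"record {rec.id!r} has length {len(rec.residues)}, "
                    f"expected {length}")
        cols = self.column_matrix()
        all_gap = np.all(cols == _GAP_CODE, axis=0)
        if np.any(all_gap):
            raise ValueError(
                f"all-gap column at position {int(np.where(all_gap)[0][0]) + 1}")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    def column_matrix(self) -> np.ndarray:
        """Rows x columns uint8 codes (gap encoded as 21)."""
        out = np.empty((len(self.records), self.length), dtype=np.uint8)
        table = {c: i for i, c in enumerate(ALPHABET)}
        table[GAP] = _GAP_CODE
        for r, rec in enumerate(self.records):
            out[r] = [table[c] for c in rec.residues]
        return out


@dataclass(frozen=True)
class TrimParams:
    """Relaxed block-trimming parameters.

    A column is conserved iff its modal non-gap residue (``X`` never
    counts) occurs in strictly more than ``conserved_min_fraction`` of
    all rows and its gap fraction is at most ``max_gap_fraction``.
    Runs of more than ``max_nonconserved_contig`` consecutive
    non-conserved columns split the alignment; surviving blocks must
    begin and end on conserved columns and span at least ``min_block``
    columns.
    """

    conserved_min_fraction: float = 0.50
    max_gap_fraction: float = 0.50
    max_nonconserved_contig: int = 8
    min_block: int = 5


@dataclass
class TrimmedMsa:
    source: Msa
    kept_columns: list[int]  # 1-based, strictly increasing
    records: list[SequenceRecord]

    @property
    def length(self) -> int:
        return len(self.kept_columns)

    @property
    def family_id(self) -> str | None:
        return self.source.family_id


@dataclass
class Supermatrix:
    records: list[SequenceRecord]  # one per genome, taxon == genome id
    partitions: list[tuple[str, int, int]]  # (family_id, start, end) 1-based

    def __post_init__(self) -> None:
        total = self.length
        pos = 1
        for fam, start, end in self.partitions:
            if start != pos or end < start:
                raise ValueError(
                    f"partition {fam!r} ({start}-{end}) does not tile the "
                    f"supermatrix at column {pos}")
            pos = end + 1
        if self.partitions and pos != total + 1:
            raise ValueError("partitions do not cover the full supermatrix")

    @property
    def length(self) -> int:
        return len(self.records[0].residues) if self.records else 0


# ---------------------------------------------------------------------------
# progressive alignment

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile(rows: np.ndarray) -> np.ndarray:
    """Column frequency profile over residue codes 0..20 (X included,
    gaps excluded but normalised by total row count)."""
    n, length = rows.shape
    prof = np.zeros((length, N_AA + 1), dtype=np.float64)
    for c in range(N_AA + 1):
        prof[:, c] = np.sum(rows == c, axis=0)
    return prof / n


def _merge(rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """Align two sub-alignments by profile-profile NW and merge rows."""
    pa = _profile(rows_a)
    pb = _profile(rows_b)
    S = pa @ BLOSUM62 @ pb.T
    _, cols = profile_nw(np.ascontiguousarray(S), GAP_OPEN, GAP_EXTEND)
    na, nb = rows_a.shape[0], rows_b.shape[0]
    out = np.full((na + nb, len(cols)), _GAP_CODE, dtype=np.uint8)
    i = j = 0
    for c, code in enumerate(cols):
        if code == 0:  # diag
            out[:na, c] = rows_a[:, i]
            out[na:, c] = rows_b[:, j]
            i += 1
            j += 1
        elif code == 1:  # column from a only
            out[:na, c] = rows_a[:, i]
            i += 1
        else:  # column from b only
            out[na:, c] = rows_b[:, j]
            j += 1
    return out


def align_family(family: ProteinFamily, guide=None) -> Msa:
    """Progressively align one family's members.

    Leaf order is genome id ascending.  The guide tree is UPGMA on
    pairwise 3-mer distances unless a dendropy tree with genome-labelled
    leaves is supplied.
    """
    genomes = sorted(family.members)
    if len(genomes) < 2:
        raise ValueError(
            f"family {family.family_id!r} has fewer than 2 members")
    seqs = [family.members[g] for g in genomes]
    rows = {i: encode(s.residues).reshape(1, -1) for i, s in enumerate(seqs)}
    order = _merge_order(seqs, guide, genomes)
    members: dict[int, list[int]] = {i: [i] for i in range(len(seqs))}
    nxt = len(seqs)
    for left, right in order:
        merged = _merge(rows.pop(left), rows.pop(right))
        rows[nxt] = merged
        members[nxt] = members.pop(left) + members.pop(right)
        nxt += 1
    final = rows.popitem()[1]
    row_order = members[nxt - 1] if order else [0]
    aligned = {}
    table = ALPHABET + GAP
    for pos, seq_idx in enumerate(row_order):
        aligned[seq_idx] = "".join(table[c] for c in final[pos])
    records = [SequenceRecord(seqs[i].id, seqs[i].taxon, aligned[i])
               for i in range(len(seqs))]
    return Msa(records=records, family_id=family.family_id)


def _merge_order(seqs, guide, genomes) -> list[tuple[int, int]]:
    """Sequence of (cluster_a, cluster_b) merges; clusters 0..n-1 are
    leaves in input order, merge i creates cluster n+i."""
    n = len(seqs)
    if guide is not None:
        return _merge_order_from_tree(guide, genomes)
    if n == 2:
        return [(0, 1)]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[i].residues,
                                               seqs[j].residues)
    Z = linkage(squareform(d, checks=False), method="average")
    return [(int(a), int(b)) for a, b, _, _ in Z]


def _merge_order_from_tree(guide, genomes) -> list[tuple[int, int]]:
    index = {g: i for i, g in enumerate(genomes)}
    merges: list[tuple[int, int]] = []
    counter = [len(genomes)]

    def visit(node) -> int:
        children = node.child_nodes()
        if not children:
            label = node.taxon.label if node.taxon else None
            if label not in index:
                raise ValueError(f"guide tree leaf {label!r} is not a member")
            return index[label]
        ids = [visit(c) for c in children]
        cur = ids[0]
        for other in ids[1:]:
            merges.append((cur, other))
            cur = counter[0]
            counter[0] += 1
        return cur

    visit(guide.seed_node)
    return merges


# ---------------------------------------------------------------------------
# trimming

def conserved_columns(msa: Msa, params: TrimParams) -> np.ndarray:
    """Boolean mask of conserved columns under the trimming rule."""
    cols = msa.column_matrix()
    n_rows = cols.shape[0]
    gap_frac = np.mean(cols == _GAP_CODE, axis=0)
    counts = np.stack([np.sum(cols == c, axis=0) for c in range(N_AA)])
    modal = counts.max(axis=0)  # X (code 20) never counts as modal
    return (modal / n_rows > params.conserved_min_fraction) & \
        (gap_frac <= params.max_gap_fraction)


def trim_blocks(msa: Msa, params: TrimParams | None = None) -> TrimmedMsa:
    """Keep contiguous conserved blocks; may keep zero columns."""
    params = params or TrimParams()
    cons = conserved_columns(msa, params)
    length = msa.length
    # identify splitter runs: > max_nonconserved_contig consecutive
    # non-conserved columns
    splitter = np.zeros(length, dtype=bool)
    run_start = None
    for i in range(length + 1):
        if i < length and not cons[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start > params.max_nonconserved_contig:
                splitter[run_start:i] = True
            run_start = None
    kept: list[int] = []
    seg_start = 0
    for i in range(length + 1):
        if i == length or splitter[i]:
            if seg_start < i:
                kept.extend(_trim_segment(cons, seg_start, i, params))
            seg_start = i + 1
    records = [SequenceRecord(r.id, r.taxon,
                              "".join(r.residues[c - 1] for c in kept))
               for r in msa.records]
    return TrimmedMsa(source=msa, kept_columns=kept, records=records)


def _trim_segment(cons: np.ndarray, start: int, end: int,
                  params: TrimParams) -> list[int]:
    """Shrink segment [start, end) to begin/end on conserved columns;
    return kept 1-based indices (empty if too short)."""
    lo, hi = start, end - 1
    while lo <= hi and not cons[lo]:
        lo += 1
    while hi >= lo and not cons[hi]:
        hi -= 1
    if lo > hi or hi - lo + 1 < params.min_block:
        return []
    return list(range(lo + 1, hi + 2))


# ---------------------------------------------------------------------------
# concatenation

def concatenate(trimmed: list[TrimmedMsa], genomes: list[str]) -> Supermatrix:
    """Concatenate trimmed family alignments into a supermatrix.

    Families are laid out in family_id-ascending order; a genome absent
    from a family is padded with gaps across that family's partition.
    Rows are keyed by record taxon (the genome id).
    """
    ordered = sorted(trimmed, key=lambda t: t.family_id or "")
    row_parts: dict[str, list[str]] = {g: [] for g in genomes}
    partitions: list[tuple[str, int, int]] = []
    pos = 1
    for tm in ordered:
        width = tm.length
        if width == 0:
            continue
        seen: set[str] = set()
        by_genome: dict[str, str] = {}
        for rec in tm.records:
            if rec.taxon in seen:
                raise ValueError(
                    f"family {tm.family_id!r}: duplicate row for genome "
                    f"{rec.taxon!r}")
            seen.add(rec.taxon)
            if rec.taxon in row_parts:
                by_genome[rec.taxon] = rec.residues
        for g in genomes:
            row_parts[g].append(by_genome.get(g, GAP * width))
        partitions.append((tm.family_id or "?", pos, pos + width - 1))
        pos += width
    records = [SequenceRecord(g, g, "".join(row_parts[g])) for g in genomes]
    return Supermatrix(records=records, partitions=partitions)
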