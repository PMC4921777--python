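"""Readers and writers for every external format the pipeline touches.

This is the only module that performs file I/O: FASTA (plain and
aligned), newick trees, tab-separated group maps, id→taxon sidecar maps,
and 12/13-column tabular homology-search hit tables.  All readers are
order-preserving and all writers are byte-stable for identical input, so
downstream determinism reduces to input order plus documented
tie-breaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from ._align import ALPHABET, GAP

_UNALIGNED_CHARS = frozenset(ALPHABET)
_ALIGNED_CHARS = _UNALIGNED_CHARS | {GAP}


class SequenceIOError(ValueError):
    """Malformed sequence input (duplicate ids, bad characters, ...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence with its genome-of-origin label.

    ``residues`` is uppercase over ``ACDEFGHIKLMNPQRSTVWY`` plus ``X``
    for unknown residues, and additionally ``-`` when the record is part
    of an alignment.
    """

    id: str
    taxon: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceIOError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


def validate_residues(record: SequenceRecord, aligned: bool = False) -> None:
    allowed = _ALIGNED_CHARS if aligned else _UNALIGNED_CHARS
    for pos, ch in enumerate(record.residues, start=1):
        if ch not in allowed:
            raise SequenceIOError(
                f"illegal character {ch!r} at position {pos} in record "
                f"{record.id!r}")
    if not record.residues:
        raise SequenceIOError(f"record {record.id!r} has an empty sequence")


@dataclass
class ProteomeSet:
    """Per-genome collections of unaligned protein sequences."""

    genomes: dict[str, list[SequenceRecord]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for genome, records in self.genomes.items():
            for rec in records:
                if rec.id in seen:
                    raise SequenceIOError(
                        f"duplicate sequence id {rec.id!r} in genomes "
                        f"{seen[rec.id]!r} and {genome!r}")
                seen[rec.id] = genome

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def all_records(self) -> list[SequenceRecord]:
        return [rec for recs in self.genomes.values() for rec in recs]

    def require_pipeline_ready(self) -> None:
        if self.n_genomes < 2:
            raise SequenceIOError(
                f"a pipeline run needs at least 2 genomes, got {self.n_genomes}")


@dataclass
class GroupAssignment:
    """Named, disjoint taxon sets defining ingroup/outgroup membership.

    ``outgroup`` defaults to every assigned taxon outside the focal
    group; an explicit set may be supplied instead.
    """

    groups: dict[str, set[str]]
    focal_group: str
    outgroup: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.focal_group not in self.groups:
            raise SequenceIOError(
                f"focal group {self.focal_group!r} is not a defined group")
        if not self.outgroup:
            self.outgroup = {t for name, taxa in self.groups.items()
                             if name != self.focal_group for t in taxa}
        focal = self.focal
        overlap = focal & self.outgroup
        if overlap:
            raise SequenceIOError(
                f"focal group and outgroup overlap: {sorted(overlap)}")
        if not focal or not self.outgroup:
            raise SequenceIOError("focal group and outgroup must be non-empty")

    @property
    def focal(self) -> set[str]:
        return self.groups[self.focal_group]

    def membership(self, taxon: str) -> str:
        """'focal', 'outgroup' or 'unassigned'."""
        if taxon in self.focal:
            return "focal"
        if taxon in self.outgroup:
            return "outgroup"
        return "unassigned"


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12/13-column tabular homology-search result."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise SequenceIOError(
                f"hit {self.query_id!r}->{self.subject_id!r}: "
                f"q_start {self.q_start} > q_end {self.q_end}")
        if self.evalue < 0:
            raise SequenceIOError(
                f"hit {self.query_id!r}->{self.subject_id!r}: "
                f"negative evalue {self.evalue}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, aligned: bool = False,
               taxon_map: Mapping[str, str] | None = None,
               default_taxon: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    The id is the first whitespace-delimited header token.  The taxon
    label is looked up in ``taxon_map`` (id → taxon); records absent
    from the map fall back to ``default_taxon``, which itself defaults
    to the file's stem — the genome-per-file convention.
    """
    path = Path(path)
    if default_taxon is None:
        default_taxon = path.stem
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rec_id = header.split()[0] if header.split() else ""
        if not rec_id:
            raise SequenceIOError(f"{path}: empty FASTA header")
        if rec_id in seen:
            raise SequenceIOError(f"{path}: duplicate sequence id {rec_id!r}")
        seen.add(rec_id)
        taxon = (taxon_map or {}).get(rec_id, default_taxon)
        rec = SequenceRecord(rec_id, taxon, "".join(chunks).upper())
        validate_residues(rec, aligned=aligned)
        records.append(rec)

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            elif line.strip():
                if header is None:
                    raise SequenceIOError(f"{path}: sequence before first header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise SequenceIOError(f"{path}: no FASTA records found")
    if aligned:
        length = len(records[0].residues)
        for rec in records:
            if len(rec.residues) != length:
                raise SequenceIOError(
                    f"{path}: aligned record {rec.id!r} has length "
                    f"{len(rec.residues)}, expected {length}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                wrap: int = 60) -> None:
    """Write records as FASTA with fixed line wrapping (byte-stable)."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.taxon}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i:i + wrap] + "\n")


def read_proteomes(paths: Sequence[str | Path],
                   taxon_map: Mapping[str, str] | None = None) -> ProteomeSet:
    """Read one FASTA file per genome; genome id = file stem."""
    genomes: dict[str, list[SequenceRecord]] = {}
    for p in paths:
        p = Path(p)
        genome = p.stem
        if genome in genomes:
            raise SequenceIOError(f"duplicate genome id {genome!r}")
        genomes[genome] = read_fasta(p, taxon_map=taxon_map,
                                     default_taxon=genome)
    return ProteomeSet(genomes)


# ---------------------------------------------------------------------------
# taxon and group maps

def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Tab-separated ``id<TAB>taxon`` sidecar map."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SequenceIOError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}")
            out[parts[0]] = parts[1]
    return out


def read_group_map(path: str | Path, focal_group: str) -> GroupAssignment:
    """Tab-separated ``taxon<TAB>group`` clade definitions.

    A taxon listed under two different groups is an error; taxa absent
    from the file are treated as unassigned downstream.
    """
    groups: dict[str, set[str]] = {}
    assigned: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SequenceIOError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}")
            taxon, group = parts
            if taxon in assigned and assigned[taxon] != group:
                raise SequenceIOError(
                    f"{path}:{lineno}: taxon {taxon!r} listed in groups "
                    f"{assigned[taxon]!r} and {group!r}")
            assigned[taxon] = group
            groups.setdefault(group, set()).add(taxon)
    if not groups:
        raise SequenceIOError(f"{path}: empty group map")
    return GroupAssignment(groups=groups, focal_group=focal_group)


def write_group_map(groups: Mapping[str, Iterable[str]],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for group in sorted(groups):
            for taxon in sorted(groups[group]):
                fh.write(f"{taxon}\t{group}\n")


# ---------------------------------------------------------------------------
# hit tables

_HIT_COLS = 12


def read_hit_table(path: str | Path,
                   taxon_map: Mapping[str, str] | None = None
                   ) -> list[HitRecord]:
    """Read a 12-column tab-separated hit table (13th column = subject
    taxon, overriding ``taxon_map``).

    Subjects whose taxon cannot be resolved are kept with
    ``subject_taxon=None`` and reported in a single :class:`UserWarning`
    so callers can decide whether unresolved taxa are fatal.
    """
    hits: list[HitRecord] = []
    unresolved: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (_HIT_COLS, _HIT_COLS + 1):
                raise SequenceIOError(
                    f"{path}:{lineno}: expected {_HIT_COLS} or "
                    f"{_HIT_COLS + 1} columns, got {len(parts)}")
            try:
                taxon: str | None
                if len(parts) == _HIT_COLS + 1:
                    taxon = parts[12]
                else:
                    taxon = (taxon_map or {}).get(parts[1])
                hit = HitRecord(
                    query_id=parts[0], subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]), gap_opens=int(parts[5]),
                    q_start=int(parts[6]), q_end=int(parts[7]),
                    s_start=int(parts[8]), s_end=int(parts[9]),
                    evalue=float(parts[10]), bitscore=float(parts[11]),
                    subject_taxon=taxon)
            except ValueError as exc:
                raise SequenceIOError(f"{path}:{lineno}: {exc}") from exc
            if hit.subject_taxon is None:
                unresolved.append(hit.subject_id)
            hits.append(hit)
    if unresolved:
        uniq = sorted(set(unresolved))
        warnings.warn(
            f"{path}: {len(uniq)} subject ids without a taxon mapping: "
            f"{', '.join(uniq[:10])}{'...' if len(uniq) > 10 else ''}",
            UserWarning, stacklevel=2)
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits in the 13-column dialect (taxon column included)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                str(h.alignment_length), str(h.mismatches),
                str(h.gap_opens), str(h.q_start), str(h.q_end),
                str(h.s_start), str(h.s_end), f"{h.evalue:.3g}",
                f"{h.bitscore:.1f}", h.subject_taxon or ""]) + "\n")


# ---------------------------------------------------------------------------
# newick

def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True, real_value_format_specifier=".9f")
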