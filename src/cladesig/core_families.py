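"""Greedy identity clustering of proteomes into shared protein families.

Families are built by seeded greedy clustering in the UCLUST spirit:
sequences are visited in deterministic order (length descending, id
ascending as tie-break) and each joins the first existing seed it
matches, or founds a new seed.  A match requires a minimum fraction of
identical positions in one global alignment *and* a minimum alignment
coverage of both sequences.  The core set for supermatrix construction
is then the families present in at least a given fraction of genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import BLOSUM62, GAP_EXTEND, GAP_OPEN, encode, global_alignment_stats
from .sequence_io import ProteomeSet, SequenceRecord


@dataclass(frozen=True)
class IdentityResult:
    """Identity/coverage summary of one pairwise global alignment.

    identity: identical columns / alignment columns, both restricted to
    the non-terminal region (terminal-gap runs excluded from the
    denominator; internal gap columns count against identity).
    coverage: per-sequence fraction of residues inside the non-terminal
    region.  score: alignment score in BLOSUM62 units.
    """

    identity: float
    coverage: tuple[float, float]
    score: float


@dataclass
class ProteinFamily:
    family_id: str
    seed_id: str
    members: dict[str, SequenceRecord]  # genome id -> chosen record
    rejected_paralogs: dict[str, list[str]] = field(default_factory=dict)
    n_genomes_total: int = 0

    @property
    def presence_fraction(self) -> float:
        return len(self.members) / self.n_genomes_total

    @property
    def size(self) -> int:
        return len(self.members)


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> IdentityResult:
    """Global-alignment identity, coverage and score for two sequences."""
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    score, ident, cov_a, cov_b = global_alignment_stats(
        encode(a.residues), encode(b.residues), BLOSUM62, GAP_OPEN, GAP_EXTEND)
    return IdentityResult(identity=ident, coverage=(cov_a, cov_b), score=score)


def cluster_proteomes(proteomes: ProteomeSet, id_threshold: float = 0.50,
                      cov_threshold: float = 0.50) -> list[ProteinFamily]:
    """Greedy seeded clustering of all sequences into protein families.

    Sequences are processed longest-first (id ascending on ties).  A
    sequence joins the earliest-created seed with identity >=
    ``id_threshold`` and coverage of *both* sequences >=
    ``cov_threshold``; otherwise it becomes a new seed.  When a genome
    contributes several matching sequences to one family, the member
    with the highest alignment score to the seed is kept and the others
    are recorded under ``rejected_paralogs``.
    """
    for name, t in (("id_threshold", id_threshold),
                    ("cov_threshold", cov_threshold)):
        if not 0 < t <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {t}")
    n_genomes = proteomes.n_genomes
    seq_genome = {rec.id: g for g, recs in proteomes.genomes.items()
                  for rec in recs}
    order = sorted(proteomes.all_records(),
                   key=lambda r: (-len(r.residues), r.id))
    encoded = {rec.id: encode(rec.residues) for rec in order}

    families: list[ProteinFamily] = []
    seeds: list[SequenceRecord] = []
    # best score of the kept member per (family index, genome)
    kept_score: dict[tuple[int, str], float] = {}

    for rec in order:
        rec_enc = encoded[rec.id]
        genome = seq_genome[rec.id]
        placed = False
        for fi, seed in enumerate(seeds):
            # exact necessary condition: coverage of the longer sequence
            # can never exceed the length ratio
            la, lb = len(seed.residues), len(rec.residues)
            if min(la, lb) / max(la, lb) < cov_threshold:
                continue
            score, ident, cov_s, cov_r = global_alignment_stats(
                encoded[seed.id], rec_enc, BLOSUM62, GAP_OPEN, GAP_EXTEND)
            if ident >= id_threshold and cov_s >= cov_threshold \
                    and cov_r >= cov_threshold:
                fam = families[fi]
                key = (fi, genome)
                if genome not in fam.members:
                    fam.members[genome] = rec
                    kept_score[key] = score
                elif score > kept_score[key]:
                    fam.rejected_paralogs.setdefault(genome, []).append(
                        fam.members[genome].id)
                    fam.members[genome] = rec
                    kept_score[key] = score
                else:
                    fam.rejected_paralogs.setdefault(genome, []).append(rec.id)
                placed = True
                break
        if not placed:
            fi = len(seeds)
            seeds.append(rec)
            families.append(ProteinFamily(
                family_id=f"F{fi + 1:05d}", seed_id=rec.id,
                members={genome: rec}, n_genomes_total=n_genomes))
            kept_score[(fi, genome)] = float(
                np.sum(BLOSUM62[rec_enc, rec_enc]))  # self score
    return families


def select_core_families(families: list[ProteinFamily],
                         presence_threshold: float = 0.80
                         ) -> list[ProteinFamily]:
    """Families present in at least ``presence_threshold`` of genomes,
    sorted by family id."""
    if not 0 < presence_threshold <= 1:
        raise ValueError(
            f"presence_threshold must be in (0, 1], got {presence_threshold}")
    kept = [f for f in families if f.presence_fraction >= presence_threshold]
    return sorted(kept, key=lambda f: f.family_id)


def family_table_rows(families: list[ProteinFamily]) -> list[tuple]:
    """Tab-separated report rows: family, seed, genome, member, identity,
    coverage of the member against the seed."""
    rows = []
    for fam in sorted(families, key=lambda f: f.family_id):
        seed = fam.members[next(g for g, r in fam.members.items()
                                if r.id == fam.seed_id)] \
            if any(r.id == fam.seed_id for r in fam.members.values()) else None
        for genome in sorted(fam.members):
            rec = fam.members[genome]
            if seed is None or rec.id == fam.seed_id:
                ident, cov = 1.0, 1.0
            else:
                res = pairwise_identity(seed, rec)
                ident, cov = res.identity, min(res.coverage)
            rows.append((fam.family_id, fam.seed_id, genome, rec.id,
                         f"{ident:.4f}", f"{cov:.4f}"))
    return rows
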