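"""Conserved signature protein (CSP) calling.

A CSP is a protein whose significant homologs are confined to one
monophyletic group: every significant hit outside the focal group (up
to a configured exception count) disqualifies the query.  Verdicts are
computed from a homology-search hit table; a built-in all-vs-all
Smith-Waterman search (:func:`mini_search`) provides a self-contained
desk-scale search so the whole screen can run without external tools.
Specificity is always relative to the supplied comparison universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._align import BLOSUM62, GAP_EXTEND, GAP_OPEN, encode, \
    smith_waterman_full, smith_waterman_score
from .sequence_io import GroupAssignment, HitRecord, ProteomeSet, SequenceRecord

# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1,
# as published for protein BLAST; used only to map raw scores onto a
# familiar bitscore/e-value scale.  The e-value surrogate is a strictly
# monotone transform of the raw score for fixed search-space size:
#   bits = (lambda * S - ln K) / ln 2,   E = m * n * 2 ** (-bits)
KA_LAMBDA = 0.267
KA_K = 0.041


def bitscore(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue(raw_score: float, query_len: int, db_residues: int) -> float:
    return query_len * db_residues * 2.0 ** (-bitscore(raw_score))


@dataclass
class CspCall:
    query_id: str
    group: str
    n_in_hits: int
    n_out_hits: int
    worst_in_evalue: float | None
    best_out_evalue: float | None
    verdict: str  # specific / not_specific / orphan


def call_csps(hits: list[HitRecord], groups: GroupAssignment,
              evalue_threshold: float = 1e-5,
              max_exceptions: int = 0) -> list[CspCall]:
    """Per-query group-specificity verdicts from a hit table.

    Self-hits are excluded; a hit is significant when its e-value is at
    or below the threshold.  A query is *specific* when its significant
    out-group hits number at most ``max_exceptions``, *orphan* when it
    has no significant non-self hits at all, else *not_specific*.
    Queries are reported in first-appearance order.
    """
    unresolvable = sorted({h.subject_taxon if h.subject_taxon else h.subject_id
                           for h in hits
                           if h.subject_id != h.query_id and
                           (h.subject_taxon is None or
                            groups.membership(h.subject_taxon) == "unassigned")})
    if unresolvable:
        raise ValueError(
            f"{len(unresolvable)} subject taxa not assignable to the focal "
            f"group or outgroup: {unresolvable[:10]}")
    order: list[str] = []
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.query_id not in by_query:
            by_query[h.query_id] = []
            order.append(h.query_id)
        if h.subject_id == h.query_id:
            continue
        by_query[h.query_id].append(h)
    calls = []
    for q in order:
        sig = [h for h in by_query[q] if h.evalue <= evalue_threshold]
        in_hits = [h for h in sig if groups.membership(h.subject_taxon) == "focal"]
        out_hits = [h for h in sig if groups.membership(h.subject_taxon) == "outgroup"]
        if not sig:
            verdict = "orphan"
        elif len(out_hits) <= max_exceptions:
            verdict = "specific"
        else:
            verdict = "not_specific"
        calls.append(CspCall(
            query_id=q, group=groups.focal_group,
            n_in_hits=len(in_hits), n_out_hits=len(out_hits),
            worst_in_evalue=max((h.evalue for h in in_hits), default=None),
            best_out_evalue=min((h.evalue for h in out_hits), default=None),
            verdict=verdict))
    return calls


def mini_search(queries: list[SequenceRecord], targets: ProteomeSet,
                score_threshold: float = 60.0) -> list[HitRecord]:
    """All-vs-all Smith-Waterman local search (BLOSUM62, 11/1).

    A hit is emitted when the raw local score reaches
    ``score_threshold``; its e-value is the documented monotone
    surrogate computed from the score, the query length and the total
    residue count of the target set.  Deterministic; hits are ordered by
    query, then ascending e-value, then subject id.
    """
    if not queries or not targets.genomes:
        raise ValueError("mini_search needs non-empty queries and targets")
    target_list = [(genome, rec) for genome, recs in
                   sorted(targets.genomes.items()) for rec in recs]
    db_residues = sum(len(rec.residues) for _, rec in target_list)
    encoded_targets = [(genome, rec, encode(rec.residues))
                       for genome, rec in target_list]
    hits: list[HitRecord] = []
    for query in queries:
        q = encode(query.residues)
        qhits = []
        for genome, rec, t in encoded_targets:
            score = smith_waterman_score(q, t, BLOSUM62, GAP_OPEN, GAP_EXTEND)
            if score < score_threshold:
                continue
            (score, qs, qe, ss, se, n_id, n_cols, n_mm,
             n_go) = smith_waterman_full(q, t, BLOSUM62, GAP_OPEN, GAP_EXTEND)
            qhits.append(HitRecord(
                query_id=query.id, subject_id=rec.id,
                percent_identity=100.0 * n_id / n_cols if n_cols else 0.0,
                alignment_length=n_cols, mismatches=n_mm, gap_opens=n_go,
                q_start=qs, q_end=qe, s_start=ss, s_end=se,
                evalue=evalue(score, len(query.residues), db_residues),
                bitscore=bitscore(score), subject_taxon=genome))
        qhits.sort(key=lambda h: (h.evalue, h.subject_id))
        hits.extend(qhits)
    return hits


def csp_report_rows(calls: list[CspCall],
                    lengths: dict[str, int] | None = None) -> list[tuple]:
    """Report rows (id, length, function, specificity) for specific and
    orphan queries; function is a passthrough placeholder."""
    rows = []
    for call in calls:
        if call.verdict != "specific":
            continue
        rows.append((call.query_id,
                     str((lengths or {}).get(call.query_id, "")),
                     "unknown, hypothetical", call.group))
    return rows
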