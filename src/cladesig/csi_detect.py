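"""Conserved signature indel (CSI) detection.

A CSI is an insertion or deletion of defined length, present in every
member of a focal clade and absent from all outgroup taxa (up to
configured exception counts), and embedded in a well-conserved region:
both flanks must contain a minimum number of conserved alignment
columns within a fixed window.  Such shared indels are interpreted as
rare genetic events in the clade's common ancestor and serve as
molecular markers for the clade.

The scan works directly on a protein multiple sequence alignment:

1. enumerate maximal gap-pattern intervals in which the focal group
   carries residues and the outgroup is gapped (insertion pattern) or
   the reverse (deletion pattern);
2. require at least ``min_conserved_per_flank`` conserved columns in
   the ``flank_window`` columns on each side;
3. report each candidate with its size range, polarity, flank evidence,
   violating taxa, and its residue-coordinate region in a chosen
   reference sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._align import ALPHABET, GAP, N_AA
from .msa_pipeline import Msa, _GAP_CODE
from .sequence_io import GroupAssignment


@dataclass(frozen=True)
class CsiParams:
    """Tunable thresholds of the CSI scan.

    flank_window: columns inspected on each side of a candidate indel.
    min_conserved_per_flank: conserved columns required per side.
    conserved_column_min_fraction: fraction of all scored rows that must
    share the modal non-gap residue for a column to count as conserved
    (``X`` never counts toward the modal residue).
    conserved_column_max_gap_fraction: maximum gap fraction of a
    conserved column.
    max_indel_size: widest indel interval considered.
    max_ingroup_exceptions / max_outgroup_exceptions: taxa allowed to
    violate the presence/absence pattern on each side.
    require_length_difference: a signature indel is a length
    polymorphism, so the carrier side must hold more residues than the
    gap side (median counts) over the candidate plus its flank windows;
    this rejects reciprocal gap pairs produced by alignment slippage,
    which shift residues without changing segment length.
    display_window: reference residues shown in rendered excerpts.
    """

    flank_window: int = 20
    min_conserved_per_flank: int = 5
    conserved_column_min_fraction: float = 0.8
    conserved_column_max_gap_fraction: float = 0.2
    max_indel_size: int = 30
    max_ingroup_exceptions: int = 0
    max_outgroup_exceptions: int = 0
    require_length_difference: bool = True
    display_window: int = 80

    def __post_init__(self) -> None:
        if self.flank_window < self.min_conserved_per_flank:
            raise ValueError("flank_window must be >= min_conserved_per_flank")
        if not 60 <= self.display_window <= 100:
            raise ValueError("display_window must lie within [60, 100]")
        for name in ("flank_window", "min_conserved_per_flank",
                     "max_indel_size", "max_ingroup_exceptions",
                     "max_outgroup_exceptions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CsiCandidate:
    """One detected conserved signature indel."""

    alignment_interval: tuple[int, int]  # 1-based inclusive columns
    size_range: tuple[int, int]          # residues on the character-bearing side
    polarity: str                        # insertion / deletion / ambiguous
    flank_conserved: tuple[int, int]
    ingroup_violators: list[str] = field(default_factory=list)
    outgroup_violators: list[str] = field(default_factory=list)
    region: tuple[int, int] | None = None
    family_id: str | None = None
    reference_id: str | None = None

    @property
    def size_label(self) -> str:
        lo, hi = self.size_range
        kind = "ins" if self.polarity == "insertion" else \
            "del" if self.polarity == "deletion" else "indel"
        if lo == hi:
            return f"{lo} aa {kind}"
        return f"{lo}–{hi} aa {kind}"


def _split_rows(msa: Msa, groups: GroupAssignment):
    """Row indices of focal/outgroup taxa; warns about unassigned rows."""
    focal_rows, out_rows, unassigned = [], [], []
    for idx, rec in enumerate(msa.records):
        side = groups.membership(rec.taxon)
        if side == "focal":
            focal_rows.append(idx)
        elif side == "outgroup":
            out_rows.append(idx)
        else:
            unassigned.append(rec.taxon)
    if unassigned:
        warnings.warn(
            f"excluding {len(unassigned)} unassigned rows: "
            f"{sorted(set(unassigned))}", UserWarning, stacklevel=3)
    if len(focal_rows) < 2 or len(out_rows) < 2:
        raise ValueError(
            f"need >= 2 focal and >= 2 outgroup rows present, got "
            f"{len(focal_rows)} focal / {len(out_rows)} outgroup")
    return focal_rows, out_rows


def conserved_mask(cols: np.ndarray, scored_rows: list[int],
                   params: CsiParams) -> np.ndarray:
    """Conserved-column mask over all scored rows.

    A column is conserved iff its modal non-gap, non-X residue reaches
    ``conserved_column_min_fraction`` of the scored rows and its gap
    fraction does not exceed ``conserved_column_max_gap_fraction``.
    """
    sub = cols[scored_rows]
    n = sub.shape[0]
    counts = np.stack([np.sum(sub == c, axis=0) for c in range(N_AA)])
    modal = counts.max(axis=0)
    gap_frac = np.mean(sub == _GAP_CODE, axis=0)
    return (modal / n >= params.conserved_column_min_fraction) & \
        (gap_frac <= params.conserved_column_max_gap_fraction)


def _pattern_ok(gap: np.ndarray, focal_rows, out_rows, lo: int, hi: int,
                pattern: str, params: CsiParams):
    """Does interval [lo, hi] (0-based inclusive) satisfy the
    insertion/deletion gap pattern?  Returns (ok, in_violators,
    out_violators) as row-index lists."""
    window = gap[:, lo:hi + 1]
    has_res = ~np.all(window, axis=1)   # row has >=1 residue in interval
    all_gap = np.all(window, axis=1)
    if pattern == "insertion":
        in_bad = [r for r in focal_rows if not has_res[r]]
        out_bad = [r for r in out_rows if not all_gap[r]]
    else:
        in_bad = [r for r in focal_rows if not all_gap[r]]
        out_bad = [r for r in out_rows if not has_res[r]]
    ok = len(in_bad) <= params.max_ingroup_exceptions and \
        len(out_bad) <= params.max_outgroup_exceptions
    return ok, in_bad, out_bad


def find_csi_candidates(msa: Msa, groups: GroupAssignment,
                        params: CsiParams | None = None
                        ) -> list[CsiCandidate]:
    """Scan an alignment for clade-specific conserved indels.

    Candidate intervals are maximal column spans (1 to
    ``max_indel_size`` wide) matching the insertion or deletion gap
    pattern; overlapping candidates of the same pattern collapse to the
    widest one (leftmost on ties).  Each must show the required
    conserved-column counts in both flanks.  Results are sorted by left
    column.
    """
    params = params or CsiParams()
    focal_rows, out_rows = _split_rows(msa, groups)
    scored = focal_rows + out_rows
    cols = msa.column_matrix()
    gap = cols == _GAP_CODE
    cons = conserved_mask(cols, scored, params)
    length = msa.length
    candidates: list[CsiCandidate] = []
    for pattern in ("insertion", "deletion"):
        # necessary condition: every column of a passing interval is
        # gapped in all but at most the tolerated number of rows on the
        # all-gap side, so only runs of such columns need scanning
        gap_side = out_rows if pattern == "insertion" else focal_rows
        tol = params.max_outgroup_exceptions if pattern == "insertion" \
            else params.max_ingroup_exceptions
        gappy = np.sum(gap[gap_side], axis=0) >= len(gap_side) - tol
        passing: list[tuple[int, int, list[int], list[int]]] = []
        for run_lo, run_hi in _true_runs(gappy):
            for lo in range(run_lo, run_hi + 1):
                for hi in range(lo, min(lo + params.max_indel_size,
                                        run_hi + 1)):
                    ok, in_bad, out_bad = _pattern_ok(
                        gap, focal_rows, out_rows, lo, hi, pattern, params)
                    if ok:
                        passing.append((lo, hi, in_bad, out_bad))
        maximal = [iv for iv in passing
                   if not any(o is not iv and o[0] <= iv[0] and iv[1] <= o[1]
                              for o in passing)]
        # collapse overlapping candidates of one pattern to the widest
        maximal.sort(key=lambda iv: (iv[0], -(iv[1] - iv[0])))
        chosen: list[tuple[int, int, list[int], list[int]]] = []
        for iv in maximal:
            if chosen and iv[0] <= chosen[-1][1]:
                if iv[1] - iv[0] > chosen[-1][1] - chosen[-1][0]:
                    chosen[-1] = iv
                continue
            chosen.append(iv)
        for lo, hi, in_bad, out_bad in chosen:
            flank = _flank_counts(cons, lo, hi, params)
            if flank[0] < params.min_conserved_per_flank or \
                    flank[1] < params.min_conserved_per_flank:
                continue
            carrier_rows = focal_rows if pattern == "insertion" else out_rows
            gapside_rows = out_rows if pattern == "insertion" else focal_rows
            bad = set(in_bad) | set(out_bad)
            sizes = [int(np.sum(~gap[r, lo:hi + 1])) for r in carrier_rows
                     if r not in bad]
            sizes = [s for s in sizes if s > 0]
            if not sizes:
                continue
            if params.require_length_difference:
                wlo = max(0, lo - params.flank_window)
                whi = min(length - 1, hi + params.flank_window)
                carrier_n = [int(np.sum(~gap[r, wlo:whi + 1]))
                             for r in carrier_rows if r not in bad]
                gapside_n = [int(np.sum(~gap[r, wlo:whi + 1]))
                             for r in gapside_rows if r not in bad]
                if np.median(carrier_n) - np.median(gapside_n) < 1:
                    continue
            candidates.append(CsiCandidate(
                alignment_interval=(lo + 1, hi + 1),
                size_range=(min(sizes), max(sizes)),
                polarity=pattern,
                flank_conserved=flank,
                ingroup_violators=sorted(msa.records[r].taxon for r in in_bad),
                outgroup_violators=sorted(msa.records[r].taxon for r in out_bad),
                family_id=msa.family_id))
    candidates.sort(key=lambda c: (c.alignment_interval, c.polarity))
    return candidates


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive 0-based pairs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def _flank_counts(cons: np.ndarray, lo: int, hi: int,
                  params: CsiParams) -> tuple[int, int]:
    left = cons[max(0, lo - params.flank_window):lo]
    right = cons[hi + 1:hi + 1 + params.flank_window]
    return int(left.sum()), int(right.sum())


def classify_polarity(candidate: CsiCandidate, msa: Msa,
                      groups: GroupAssignment,
                      external_refs=None) -> str:
    """Insertion/deletion call, optionally checked against external
    reference rows (aligned records from taxa outside the comparison).

    If every external reference matches the outgroup's state the
    pattern call stands; any disagreement makes the call ambiguous.
    """
    if not external_refs:
        return candidate.polarity
    lo, hi = candidate.alignment_interval
    states = []
    for rec in external_refs:
        window = rec.residues[lo - 1:hi]
        states.append("gapped" if set(window) <= {GAP} else "bearing")
    outgroup_state = "gapped" if candidate.polarity == "insertion" \
        else "bearing"
    if all(s == outgroup_state for s in states):
        return candidate.polarity
    return "ambiguous"


def map_region(candidate: CsiCandidate, msa: Msa, reference_id: str,
               params: CsiParams | None = None,
               groups: GroupAssignment | None = None) -> tuple[int, int]:
    """Residue-coordinate span of the signature region in a reference row.

    start = ungapped reference position of the first conserved column in
    the left flank window; end = position of the last conserved column
    in the right flank window; both 1-based inclusive.  If the reference
    is gapped at a conserved column, the nearest following (start) or
    preceding (end) residue position is used.
    """
    params = params or CsiParams()
    ref = next((r for r in msa.records if r.id == reference_id), None)
    if ref is None:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    if groups is not None:
        focal_rows, out_rows = _split_rows(msa, groups)
        scored = focal_rows + out_rows
    else:
        scored = list(range(len(msa.records)))
    cons = conserved_mask(msa.column_matrix(), scored, params)
    lo, hi = candidate.alignment_interval[0] - 1, candidate.alignment_interval[1] - 1
    left = [c for c in range(max(0, lo - params.flank_window), lo) if cons[c]]
    right = [c for c in range(hi + 1, min(len(cons), hi + 1 + params.flank_window))
             if cons[c]]
    if not left or not right:
        raise ValueError("no conserved flank columns to anchor the region")
    for cols_ in (range(max(0, lo - params.flank_window), lo),
                  range(hi + 1, min(len(cons), hi + 1 + params.flank_window))):
        if all(ref.residues[c] == GAP for c in cols_):
            raise ValueError(
                f"reference {reference_id!r} is all-gap in a flank window")
    # prefix residue counts: residues in columns 1..c
    prefix = np.cumsum([ch != GAP for ch in ref.residues])
    start_col, end_col = left[0], right[-1]
    if ref.residues[start_col] == GAP:
        start = int(prefix[start_col]) + 1
    else:
        start = int(prefix[start_col])
    end = int(prefix[end_col])
    return start, end


# ---------------------------------------------------------------------------
# publication-style excerpt rendering

def format_signature_alignment(msa: Msa, candidate: CsiCandidate,
                               reference_id: str,
                               params: CsiParams | None = None) -> str:
    """Render a dash-identity excerpt around a candidate.

    The reference is printed in full on the top line, prefixed with the
    1-based coordinate of its first displayed residue.  Every other row
    shows ``-`` where identical to the top line, the residue where
    different, and ``.`` where gapped.  A marker line of ``v`` delimits
    the candidate interval.  The number of displayed reference residues
    is ``params.display_window`` clamped to what the alignment allows.
    """
    params = params or CsiParams()
    ref = next((r for r in msa.records if r.id == reference_id), None)
    if ref is None:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    lo, hi = candidate.alignment_interval[0] - 1, candidate.alignment_interval[1] - 1
    # expand columns outward until display_window reference residues shown
    left, right = lo, hi
    def shown() -> int:
        return sum(1 for c in range(left, right + 1) if ref.residues[c] != GAP)
    while shown() < params.display_window and (left > 0 or right < msa.length - 1):
        if left > 0:
            left -= 1
        if shown() >= params.display_window:
            break
        if right < msa.length - 1:
            right += 1
    ref_start = sum(1 for c in range(left) if ref.residues[c] != GAP) + 1
    width = max(len(rec.id) for rec in msa.records) + 2
    lines = []
    marker = " " * (width + 3) + "".join(
        "v" if lo <= c <= hi else " " for c in range(left, right + 1))
    lines.append(marker)
    top = ref.residues[left:right + 1]
    lines.append(f"{ref.id:<{width - 2}}{ref_start:>4} {top}")
    for rec in msa.records:
        if rec.id == reference_id:
            continue
        body = []
        for c in range(left, right + 1):
            ch = rec.residues[c]
            if ch == GAP:
                body.append(".")
            elif ch == top[c - left]:
                body.append("-")
            else:
                body.append(ch)
        lines.append(f"{rec.id:<{width - 2}}     {''.join(body)}")
    return "\n".join(lines) + "\n"


def decode_signature_alignment(block: str) -> dict[str, str]:
    """Invert :func:`format_signature_alignment`: id -> sub-alignment row
    (with ``-`` for gaps), reconstructed against the top line."""
    lines = [ln for ln in block.splitlines() if ln.strip()]
    marker, top_line, rest = lines[0], lines[1], lines[2:]
    parts = top_line.rsplit(" ", 1)
    top = parts[1]
    head = parts[0].rsplit(" ", 1)
    ref_id = head[0].strip()
    out = {ref_id: top}
    col0 = len(top_line) - len(top)
    for ln in rest:
        rid = ln[:col0].strip()
        body = ln[col0:]
        row = []
        for i, ch in enumerate(body):
            if ch == ".":
                row.append(GAP)
            elif ch == "-":
                row.append(top[i])
            else:
                row.append(ch)
        out[rid] = "".join(row)
    return out
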