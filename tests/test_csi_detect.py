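import random

import numpy as np
import pytest

from cladesig.csi_detect import (CsiParams, classify_polarity,
                                 decode_signature_alignment,
                                 find_csi_candidates,
                                 format_signature_alignment, map_region)
from cladesig.msa_pipeline import Msa
from cladesig.sequence_io import GroupAssignment, SequenceRecord

from conftest import indel_msa, random_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# independent exhaustive oracle: tests every interval directly against the
# stated predicate, with no shortcuts shared with the implementation

def oracle_find(msa, groups, params):
    rows = [(r.taxon, r.residues) for r in msa.records
            if groups.membership(r.taxon) != "unassigned"]
    focal = [i for i, (t, _) in enumerate(rows)
             if groups.membership(t) == "focal"]
    out = [i for i, (t, _) in enumerate(rows)
           if groups.membership(t) == "outgroup"]
    length = len(rows[0][1])

    def interval_ok(lo, hi, pattern):
        in_bad, out_bad = [], []
        for r, (_, seq) in enumerate(rows):
            window = seq[lo:hi + 1]
            has_res = any(c != "-" for c in window)
            if pattern == "insertion":
                if r in focal and not has_res:
                    in_bad.append(r)
                if r in out and has_res:
                    out_bad.append(r)
            else:
                if r in focal and has_res:
                    in_bad.append(r)
                if r in out and not has_res:
                    out_bad.append(r)
        return (len(in_bad) <= params.max_ingroup_exceptions and
                len(out_bad) <= params.max_outgroup_exceptions)

    def conserved(col):
        residues = [seq[col] for _, seq in rows]
        n = len(residues)
        gaps = residues.count("-")
        counts = {}
        for ch in residues:
            if ch not in ("-", "X"):
                counts[ch] = counts.get(ch, 0) + 1
        modal = max(counts.values()) if counts else 0
        return (modal / n >= params.conserved_column_min_fraction and
                gaps / n <= params.conserved_column_max_gap_fraction)

    results = []
    for pattern in ("insertion", "deletion"):
        passing = [(lo, hi) for lo in range(length)
                   for hi in range(lo, min(lo + params.max_indel_size, length))
                   if interval_ok(lo, hi, pattern)]
        maximal = [iv for iv in passing
                   if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1]
                              for o in passing)]
        maximal.sort(key=lambda iv: (iv[0], -(iv[1] - iv[0])))
        chosen = []
        for iv in maximal:
            if chosen and iv[0] <= chosen[-1][1]:
                if iv[1] - iv[0] > chosen[-1][1] - chosen[-1][0]:
                    chosen[-1] = iv
                continue
            chosen.append(iv)
        for lo, hi in chosen:
            left = sum(1 for c in range(max(0, lo - params.flank_window), lo)
                       if conserved(c))
            right = sum(1 for c in range(hi + 1,
                                         min(length, hi + 1 + params.flank_window))
                        if conserved(c))
            if left < params.min_conserved_per_flank or \
                    right < params.min_conserved_per_flank:
                continue
            carriers = focal if pattern == "insertion" else out
            gapside = out if pattern == "insertion" else focal
            sizes = [sum(1 for c in rows[r][1][lo:hi + 1] if c != "-")
                     for r in carriers]
            sizes = [s for s in sizes if s > 0]
            if not sizes:
                continue
            if params.require_length_difference:
                wlo = max(0, lo - params.flank_window)
                whi = min(length - 1, hi + params.flank_window)

                def count(r):
                    return sum(1 for c in rows[r][1][wlo:whi + 1]
                               if c != "-")
                if (np.median([count(r) for r in carriers])
                        - np.median([count(r) for r in gapside])) < 1:
                    continue
            results.append(((lo + 1, hi + 1), pattern,
                            (min(sizes), max(sizes))))
    return sorted(results)


def random_msa(rng, n_in, n_out, length):
    """Random alignment with a conserved backbone and random gap blocks."""
    base = random_protein(rng, length)
    records = []
    for i in range(n_in + n_out):
        chars = list(base)
        # substitution noise
        for pos in range(length):
            if rng.random() < 0.08:
                chars[pos] = rng.choice(AA)
        # random gap blocks
        for _ in range(rng.randint(0, 3)):
            start = rng.randrange(length)
            width = rng.randint(1, 12)
            for c in range(start, min(length, start + width)):
                chars[c] = "-"
        side = "IN" if i < n_in else "OUT"
        records.append(SequenceRecord(f"s{i}", f"{side}{i}", "".join(chars)))
    try:
        return Msa(records)
    except ValueError:  # an all-gap column was drawn; rare, skip
        return None


@pytest.fixture
def base80():
    return random_protein(random.Random(7), 80)


class TestFindCandidates:
    def test_four_aa_insertion_detected(self, base80, two_group_assignment):
        """The canonical case: a 4-residue clade-specific insertion in a
        conserved region (the elongation-factor-style signature)."""
        base = base80[:40] + "WCGP" + base80[44:]
        msa = Msa(indel_msa(base, (41, 44), pattern="insertion"))
        cands = find_csi_candidates(msa, two_group_assignment)
        assert len(cands) == 1
        c = cands[0]
        assert c.alignment_interval == (41, 44)
        assert c.size_range == (4, 4)
        assert c.polarity == "insertion"
        assert c.flank_conserved[0] >= 5 and c.flank_conserved[1] >= 5

    def test_outgroup_exception_semantics(self, base80, two_group_assignment):
        base = base80[:40] + "WCGP" + base80[44:]
        records = indel_msa(base, (41, 44))
        # out3 also carries residues in the interval
        records[-1] = SequenceRecord("out3", "OUT3", base)
        msa = Msa(records)
        strict = find_csi_candidates(msa, two_group_assignment, CsiParams())
        assert strict == []
        lax = find_csi_candidates(
            msa, two_group_assignment,
            CsiParams(max_outgroup_exceptions=1))
        assert len(lax) == 1
        assert lax[0].outgroup_violators == ["OUT3"]

    def test_unassigned_rows_excluded_with_warning(self, base80,
                                                   two_group_assignment):
        base = base80[:40] + "WCGP" + base80[44:]
        records = indel_msa(base, (41, 44))
        records.append(SequenceRecord("mystery", "UNKNOWN", base))
        msa = Msa(records)
        with pytest.warns(UserWarning, match="UNKNOWN"):
            cands = find_csi_candidates(msa, two_group_assignment)
        assert len(cands) == 1

    def test_too_few_rows_per_side_rejected(self, base80):
        base = base80[:40] + "WCGP" + base80[44:]
        ga = GroupAssignment(groups={"in": {"IN0"}, "out": {"OUT0", "OUT1"}},
                             focal_group="in")
        msa = Msa(indel_msa(base, (41, 44), n_in=1, n_out=2))
        with pytest.raises(ValueError, match="2 focal"):
            find_csi_candidates(msa, ga)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle_on_random_msas(self, seed):
        """Quantified oracle equivalence on random gap-block alignments."""
        rng = random.Random(seed)
        params = CsiParams(min_conserved_per_flank=3, flank_window=10)
        checked = 0
        while checked < 50:
            n_in = rng.randint(2, 8)
            n_out = rng.randint(2, 7)
            msa = random_msa(rng, n_in, n_out, rng.randint(40, 100))
            if msa is None:
                continue
            ga = GroupAssignment(
                groups={"in": {f"IN{i}" for i in range(n_in)},
                        "out": {f"OUT{i}" for i in range(n_in, n_in + n_out)}},
                focal_group="in")
            got = sorted((c.alignment_interval, c.polarity, c.size_range)
                         for c in find_csi_candidates(msa, ga, params))
            assert got == oracle_find(msa, ga, params)
            checked += 1

    def test_swap_symmetry(self, base80):
        """Exchanging focal and outgroup turns each insertion into a
        deletion over the same interval."""
        base = base80[:40] + "WCGPKY" + base80[46:]
        records = indel_msa(base, (41, 46))
        msa = Msa(records)
        ga_fwd = GroupAssignment(
            groups={"in": {f"IN{i}" for i in range(6)},
                    "out": {f"OUT{i}" for i in range(4)}}, focal_group="in")
        ga_rev = GroupAssignment(
            groups={"in": {f"IN{i}" for i in range(6)},
                    "out": {f"OUT{i}" for i in range(4)}}, focal_group="out")
        fwd = find_csi_candidates(msa, ga_fwd)
        rev = find_csi_candidates(msa, ga_rev)
        assert [(c.alignment_interval, c.polarity) for c in fwd] == \
            [((41, 46), "insertion")]
        assert [(c.alignment_interval, c.polarity) for c in rev] == \
            [((41, 46), "deletion")]

    def test_raising_strictness_never_adds_candidates(self, base80):
        rng = random.Random(12)
        ga = GroupAssignment(
            groups={"in": {f"IN{i}" for i in range(5)},
                    "out": {f"OUT{i}" for i in range(5, 10)}},
            focal_group="in")
        baseline = CsiParams(min_conserved_per_flank=3,
                             conserved_column_min_fraction=0.6)
        stricter = [
            CsiParams(min_conserved_per_flank=6,
                      conserved_column_min_fraction=0.6),
            CsiParams(min_conserved_per_flank=3,
                      conserved_column_min_fraction=0.9),
        ]
        for _ in range(20):
            msa = random_msa(rng, 5, 5, 60)
            if msa is None:
                continue
            base_set = {(c.alignment_interval, c.polarity)
                        for c in find_csi_candidates(msa, ga, baseline)}
            for params in stricter:
                strict_set = {(c.alignment_interval, c.polarity)
                              for c in find_csi_candidates(msa, ga, params)}
                assert strict_set <= base_set


class TestPolarity:
    def test_pattern_calls(self, base80, two_group_assignment):
        base = base80[:40] + "WCGP" + base80[44:]
        ins = Msa(indel_msa(base, (41, 44), pattern="insertion"))
        dele = Msa(indel_msa(base, (41, 44), pattern="deletion"))
        ci = find_csi_candidates(ins, two_group_assignment)[0]
        cd = find_csi_candidates(dele, two_group_assignment)[0]
        assert ci.polarity == "insertion"
        assert cd.polarity == "deletion"
        assert classify_polarity(ci, ins, two_group_assignment) == "insertion"
        assert classify_polarity(cd, dele, two_group_assignment) == "deletion"

    def test_external_references_agreeing_keep_the_call(
            self, base80, two_group_assignment):
        base = base80[:40] + "WCGP" + base80[44:]
        gapped = base80[:40] + "----" + base80[44:]
        msa = Msa(indel_msa(base, (41, 44)))
        c = find_csi_candidates(msa, two_group_assignment)[0]
        refs = [SequenceRecord("e1", "EXT1", gapped),
                SequenceRecord("e2", "EXT2", gapped)]
        assert classify_polarity(c, msa, two_group_assignment, refs) == \
            "insertion"

    def test_split_external_references_make_ambiguous(
            self, base80, two_group_assignment):
        base = base80[:40] + "WCGP" + base80[44:]
        gapped = base80[:40] + "----" + base80[44:]
        msa = Msa(indel_msa(base, (41, 44)))
        c = find_csi_candidates(msa, two_group_assignment)[0]
        refs = [SequenceRecord("e1", "EXT1", gapped),
                SequenceRecord("e2", "EXT2", base)]
        assert classify_polarity(c, msa, two_group_assignment, refs) == \
            "ambiguous"


class TestMapRegion:
    def test_gapless_reference_region_equals_columns(self, base80,
                                                     two_group_assignment):
        base = base80[:40] + "WCGP" + base80[44:]
        msa = Msa(indel_msa(base, (41, 44)))
        c = find_csi_candidates(msa, two_group_assignment)[0]
        assert map_region(c, msa, "in0") == (21, 64)

    def test_reference_gaps_shift_coordinates(self, two_group_assignment):
        rng = random.Random(9)
        base = random_protein(rng, 100)
        base = base[:40] + "WCGP" + base[44:]
        records = indel_msa(base, (41, 44))
        # put 5 gaps into the reference before the left flank
        ref = records[0]
        residues = "-----" + ref.residues[5:]
        records[0] = SequenceRecord(ref.id, ref.taxon, residues)
        msa = Msa(records)
        c = find_csi_candidates(
            msa, two_group_assignment,
            CsiParams(conserved_column_min_fraction=0.7))[0]
        start, end = map_region(c, msa, "in0",
                                CsiParams(conserved_column_min_fraction=0.7))
        # gap-count arithmetic: 5 leading gaps shift start from 21 to 16
        assert (start, end) == (16, 59)

    def test_reference_all_gap_flank_rejected(self, base80,
                                              two_group_assignment):
        base = base80[:40] + "WCGP" + base80[44:]
        records = indel_msa(base, (41, 44))
        ref = records[0]
        records[0] = SequenceRecord(ref.id, ref.taxon,
                                    "-" * 40 + ref.residues[40:])
        msa = Msa(records)
        c = find_csi_candidates(msa, two_group_assignment,
                                CsiParams(conserved_column_min_fraction=0.7))[0]
        with pytest.raises(ValueError, match="all-gap"):
            map_region(c, msa, "in0",
                       CsiParams(conserved_column_min_fraction=0.7))


class TestExcerpt:
    def test_identical_rows_render_as_dashes(self, two_group_assignment):
        rng = random.Random(4)
        base = random_protein(rng, 120)
        base = base[:60] + "WCGP" + base[64:]
        msa = Msa(indel_msa(base, (61, 64), n_in=6, n_out=4))
        c = find_csi_candidates(msa, two_group_assignment)[0]
        block = format_signature_alignment(msa, c, "in0")
        lines = block.splitlines()
        in1_line = next(l for l in lines if l.startswith("in1"))
        assert set(in1_line.split()[-1]) == {"-"}

    def test_round_trip_reproduces_subalignment(self, two_group_assignment):
        rng = random.Random(5)
        base = random_protein(rng, 150)
        base = base[:70] + "WCGPKY" + base[76:]
        records = indel_msa(base, (71, 76), n_in=6, n_out=4)
        # add row variation so the excerpt isn't all dashes
        mutated = list(records[2].residues)
        for pos in (10, 80, 100):
            mutated[pos] = "W" if mutated[pos] != "W" else "Y"
        records[2] = SequenceRecord("in2", "IN2", "".join(mutated))
        msa = Msa(records)
        c = find_csi_candidates(msa, two_group_assignment)[0]
        block = format_signature_alignment(msa, c, "in0")
        decoded = decode_signature_alignment(block)
        top = decoded["in0"]
        # locate the displayed window in the source alignment
        full = {r.id: r.residues for r in msa.records}
        start = full["in0"].replace("-", "").find(top.replace("-", ""))
        col0 = full["in0"].find(top)
        assert col0 >= 0
        for rid, row in decoded.items():
            assert row == full[rid][col0:col0 + len(top)]

    def test_displayed_reference_span_within_bounds(self, two_group_assignment):
        rng = random.Random(6)
        base = random_protein(rng, 200)
        base = base[:90] + "WCGP" + base[94:]
        msa = Msa(indel_msa(base, (91, 94)))
        c = find_csi_candidates(msa, two_group_assignment)[0]
        for window in (60, 80, 100):
            block = format_signature_alignment(
                msa, c, "in0", CsiParams(display_window=window))
            top = block.splitlines()[1].rsplit(" ", 1)[1]
            n_res = sum(1 for ch in top if ch != "-")
            assert 60 <= n_res <= 100


def test_display_window_bounds_validated():
    with pytest.raises(ValueError):
        CsiParams(display_window=50)
    with pytest.raises(ValueError):
        CsiParams(display_window=120)
    with pytest.raises(ValueError):
        CsiParams(flank_window=3, min_conserved_per_flank=5)
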