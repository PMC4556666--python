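"""Scan and filter checks against exhaustive, independently coded oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedmap.homozygosity import (
    ConsistencyRuleSet,
    apply_consistency_filter,
    evidence_matrix,
    gene_overlap,
    region_report,
    round_half_up,
    shared_homozygosity_scan,
)
from pedmap.model import GenotypeMatrix, PedmapError

from conftest import make_map, make_multi_map, matrix_from_rows

HOM1, HET, HOM2, MISS = 0, 1, 2, -1


# ---------------------------------------------------------------------------
# exhaustive window-enumeration oracle (independent, naive loops)
# ---------------------------------------------------------------------------

def brute_force_scan(gm: GenotypeMatrix, affected_ids, min_markers, max_missing_run):
    """Enumerate every candidate window and keep the maximal valid ones."""
    tab = gm.marker_map.table
    rows = [list(gm.row(i)) for i in affected_ids]
    n = len(tab)

    def is_break(j):
        seen = set()
        for row in rows:
            c = row[j]
            if c == HET:
                return True
            if c in (HOM1, HOM2):
                seen.add(c)
        if len(seen) > 1:
            return True
        # long missing run in any individual
        for row in rows:
            if row[j] == MISS:
                lo = j
                while lo > 0 and row[lo - 1] == MISS and tab["chrom"][lo - 1] == tab["chrom"][j]:
                    lo -= 1
                hi = j
                while hi < n - 1 and row[hi + 1] == MISS and tab["chrom"][hi + 1] == tab["chrom"][j]:
                    hi += 1
                if hi - lo + 1 > max_missing_run:
                    return True
        return False

    def state(j):
        if is_break(j):
            return "break"
        if any(row[j] == MISS for row in rows):
            return "neutral"
        return "shared"

    states = [state(j) for j in range(n)]
    found = []
    for i in range(n):
        for j in range(i, n):
            if tab["chrom"][i] != tab["chrom"][j]:
                continue
            if states[i] != "shared" or states[j] != "shared":
                continue
            if any(states[k] == "break" for k in range(i, j + 1)):
                continue
            # maximality: no valid extension in either direction
            if i > 0 and tab["chrom"][i - 1] == tab["chrom"][i] and states[i - 1] != "break":
                if any(states[k] == "shared" for k in range(0, i)
                       if tab["chrom"][k] == tab["chrom"][i]
                       and all(states[q] != "break" for q in range(k, i))):
                    continue
            if j < n - 1 and tab["chrom"][j + 1] == tab["chrom"][j] and states[j + 1] != "break":
                if any(states[k] == "shared" for k in range(j + 1, n)
                       if tab["chrom"][k] == tab["chrom"][j]
                       and all(states[q] != "break" for q in range(j + 1, k + 1))):
                    continue
            shared_idx = [k for k in range(i, j + 1) if states[k] == "shared"]
            if len(shared_idx) >= min_markers:
                found.append((tab["chrom"][i], int(tab["pos"][i]), int(tab["pos"][j]),
                              tuple(shared_idx)))
    return sorted(set(found))


class TestScanOracle:
    @pytest.mark.parametrize("min_markers", [1, 2, 3, 5])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration(self, min_markers, seed):
        rng = np.random.default_rng(seed)
        mm = make_multi_map({"A1": 60, "C2": 60})
        n_aff = rng.integers(1, 4)
        calls = rng.choice([-1, 0, 1, 2], size=(n_aff, 120),
                           p=[0.05, 0.43, 0.09, 0.43]).astype(np.int8)
        gm = matrix_from_rows({f"a{k}": calls[k].tolist() for k in range(n_aff)}, mm)
        ids = list(gm.individual_ids)
        segs = shared_homozygosity_scan(gm, ids, min_markers=min_markers,
                                        max_missing_run=2, merge_gap_bp=0)
        got = sorted((s.chrom, s.start_bp, s.end_bp, s.marker_indices) for s in segs)
        expected = brute_force_scan(gm, ids, min_markers, max_missing_run=2)
        assert got == expected

    def test_larger_random_matrices_against_oracle(self):
        rng = np.random.default_rng(99)
        mm = make_multi_map({"B1": 500})
        calls = rng.choice([-1, 0, 1, 2], size=(4, 500),
                           p=[0.04, 0.45, 0.06, 0.45]).astype(np.int8)
        gm = matrix_from_rows({f"a{k}": calls[k].tolist() for k in range(4)}, mm)
        ids = list(gm.individual_ids)
        for min_markers in (1, 4):
            segs = shared_homozygosity_scan(gm, ids, min_markers=min_markers,
                                            max_missing_run=3, merge_gap_bp=0)
            got = sorted((s.chrom, s.start_bp, s.end_bp, s.marker_indices) for s in segs)
            assert got == brute_force_scan(gm, ids, min_markers, 3)


class TestScanBasics:
    def test_fully_heterozygous_affected_yields_nothing(self):
        mm = make_map(30)
        gm = matrix_from_rows({"a1": [HOM1] * 30, "a2": [HET] * 30}, mm)
        assert shared_homozygosity_scan(gm, ["a1", "a2"], min_markers=1) == []

    def test_opposite_homozygotes_do_not_share(self):
        mm = make_map(30)
        gm = matrix_from_rows({"a1": [HOM1] * 30, "a2": [HOM2] * 30}, mm)
        assert shared_homozygosity_scan(gm, ["a1", "a2"], min_markers=1) == []

    def test_missing_is_neutral_but_cannot_flank(self):
        mm = make_map(7)
        row = [MISS, HOM1, HOM1, MISS, HOM1, MISS, MISS]
        gm = matrix_from_rows({"a1": row}, mm)
        (seg,) = shared_homozygosity_scan(gm, ["a1"], min_markers=1, max_missing_run=5)
        assert seg.marker_indices == (1, 2, 4)
        assert seg.start_bp == mm.table["pos"][1] and seg.end_bp == mm.table["pos"][4]

    def test_long_missing_run_breaks_segment(self):
        mm = make_map(9)
        row = [HOM1, HOM1, MISS, MISS, MISS, HOM1, HOM1, HOM1, HOM1]
        gm = matrix_from_rows({"a1": row}, mm)
        segs = shared_homozygosity_scan(gm, ["a1"], min_markers=1, max_missing_run=2,
                                        merge_gap_bp=0)
        assert [s.marker_indices for s in segs] == [(0, 1), (5, 6, 7, 8)]

    def test_invariant_to_individual_order(self):
        rng = np.random.default_rng(5)
        mm = make_map(80)
        calls = rng.choice([0, 1, 2], size=(3, 80)).astype(np.int8)
        g1 = matrix_from_rows({"x": calls[0].tolist(), "y": calls[1].tolist(),
                               "z": calls[2].tolist()}, mm)
        g2 = matrix_from_rows({"z": calls[2].tolist(), "x": calls[0].tolist(),
                               "y": calls[1].tolist()}, mm)
        s1 = shared_homozygosity_scan(g1, ["x", "y", "z"], min_markers=1)
        s2 = shared_homozygosity_scan(g2, ["z", "y", "x"], min_markers=1)
        assert [(s.chrom, s.start_bp, s.end_bp) for s in s1] == \
               [(s.chrom, s.start_bp, s.end_bp) for s in s2]

    def test_absent_affected_id_rejected(self):
        mm = make_map(5)
        gm = matrix_from_rows({"a1": [0] * 5}, mm)
        with pytest.raises(PedmapError):
            shared_homozygosity_scan(gm, ["ghost"])


def six_region_fixture():
    """Six single-chromosome shared segments; relative genotypes are built
    so that exactly the F2 segment survives all three relative rules."""
    chroms = ["A3", "B3", "C1", "C2", "D1", "F2"]
    mm = make_multi_map({c: 6 for c in chroms})
    n = len(mm)
    aff = [HOM1] * n                      # affecteds share allele1 everywhere
    sire = [HET] * n
    dam = [HET] * n
    sib = [HET] * n
    gma = [HET] * n

    def block(chrom):
        sl = mm.chrom_slice(chrom)
        return list(range(sl.start, sl.stop))

    for j in block("A3"):
        sire[j] = HOM1     # sire homozygous for signature -> would be affected
    dam[block("B3")[2]] = HOM2          # dam lacks shared allele at one marker
    for j in block("C1"):
        sib[j] = HOM1      # healthy littermate homozygous for signature
    gma[block("C2")[4]] = HOM2          # grandmother lacks shared allele
    for j in block("D1"):
        gma[j] = HOM1      # grandmother homozygous for signature
    gm = matrix_from_rows(
        {"AFF1": aff, "AFF2": aff, "SIRE": sire, "DAM": dam, "SIB": sib, "GMA": gma}, mm
    )
    rules = ConsistencyRuleSet(
        obligate_carrier_ids=("SIRE", "DAM"),
        declared_carrier_ids=("GMA",),
        unaffected_ids=("SIB",),
    )
    return gm, rules


class TestConsistencyFilter:
    def test_six_regions_reduce_to_one(self):
        """Mirrors the study's 6-shared/1-consistent reduction pattern."""
        gm, rules = six_region_fixture()
        segs = shared_homozygosity_scan(gm, ["AFF1", "AFF2"], min_markers=3,
                                        merge_gap_bp=0)
        assert len(segs) == 6
        regions = apply_consistency_filter(segs, gm, rules)
        consistent = [r for r in regions if r.status == "consistent"]
        assert len(consistent) == 1
        assert consistent[0].segment.chrom == "F2"
        # the filter only removes: every consistent region is a scanned segment
        assert all(r.segment in segs for r in regions)

    def test_carrier_homozygous_for_signature_excluded(self):
        mm = make_map(5)
        gm = matrix_from_rows({"A": [HOM1] * 5, "P": [HOM1] * 5}, mm)
        segs = shared_homozygosity_scan(gm, ["A"], min_markers=1)
        rules = ConsistencyRuleSet(obligate_carrier_ids=("P",))
        (region,) = apply_consistency_filter(segs, gm, rules)
        assert region.status == "excluded"
        assert "homozygous for the shared signature" in region.verdicts[0].reason

    @pytest.mark.parametrize("tolerance,expected", [(0, "excluded"), (1, "consistent")])
    def test_tolerance_boundary(self, tolerance, expected):
        """tolerance=1 forgives exactly one allele-dropout marker."""
        mm = make_map(6)
        carrier = [HET, HET, HOM2, HET, HET, HET]   # one marker lacking allele1
        gm = matrix_from_rows({"A": [HOM1] * 6, "P": carrier}, mm)
        segs = shared_homozygosity_scan(gm, ["A"], min_markers=1)
        rules = ConsistencyRuleSet(obligate_carrier_ids=("P",), tolerance=tolerance)
        (region,) = apply_consistency_filter(segs, gm, rules)
        assert region.status == expected

    def test_unaffected_relative_only_blocked_by_full_signature(self):
        mm = make_map(5)
        # unaffected relative lacks the allele entirely at one marker: fine
        gm = matrix_from_rows({"A": [HOM1] * 5, "U": [HET, HOM2, HET, HET, HET]}, mm)
        segs = shared_homozygosity_scan(gm, ["A"], min_markers=1)
        rules = ConsistencyRuleSet(unaffected_ids=("U",))
        (region,) = apply_consistency_filter(segs, gm, rules)
        assert region.status == "consistent"

    def test_empty_rule_set_passes_all_with_warning(self, caplog):
        import logging
        mm = make_map(4)
        gm = matrix_from_rows({"A": [HOM1] * 4}, mm)
        segs = shared_homozygosity_scan(gm, ["A"], min_markers=1)
        with caplog.at_level(logging.WARNING):
            regions = apply_consistency_filter(segs, gm, ConsistencyRuleSet())
        assert all(r.status == "consistent" for r in regions)
        assert "empty consistency rule set" in caplog.text


class TestRegionReport:
    def test_study_region_span(self):
        """The chromosome C2 candidate boundaries give a 3.9 Mb span."""
        assert 140984522 - 137108027 == 3_876_495
        assert round_half_up(3_876_495 / 1e6, 1) == 3.9

    def test_zero_span(self):
        assert round_half_up(0.0, 1) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 2 * 10**8), st.integers(0, 10**7))
    def test_span_equals_subtraction(self, start, extent):
        from pedmap.homozygosity import CandidateRegion, SharedSegment
        seg = SharedSegment("C2", start, start + extent, (0,), (0,))
        region = CandidateRegion(seg, (), "consistent")
        row = region_report([region]).iloc[0]
        assert row["span_bp"] == extent
        assert row["span_mb"] == round_half_up(extent / 1e6, 1)


class TestGeneOverlap:
    def _regions(self):
        from pedmap.homozygosity import CandidateRegion, SharedSegment
        seg = SharedSegment("C2", 137_108_027, 140_984_522, (0,), (0,))
        return [CandidateRegion(seg, (), "consistent")]

    def test_gene_inside_region_distance_zero(self):
        genes = pd.DataFrame([{"gene": "X", "chrom": "C2",
                               "start": 138_000_000, "end": 138_100_000}])
        out = gene_overlap(self._regions(), genes, slop_bp=0)
        assert out.loc[0, "distance_bp"] == 0

    def test_nearby_gene_within_slop(self):
        """A gene 3.9 Mb away is reported when slop covers the gap."""
        genes = pd.DataFrame([{"gene": "COLQ", "chrom": "C2",
                               "start": 133_071_353, "end": 133_208_027}])
        out = gene_overlap(self._regions(), genes, slop_bp=4_000_000)
        assert out.loc[0, "distance_bp"] == 3_900_000
        assert gene_overlap(self._regions(), genes, slop_bp=3_000_000).empty

    def test_distances_match_brute_force(self):
        rng = np.random.default_rng(8)
        regions = self._regions()
        seg = regions[0].segment
        genes = pd.DataFrame({
            "gene": [f"g{k}" for k in range(200)],
            "chrom": rng.choice(["C2", "A1"], size=200),
            "start": rng.integers(1, 3 * 10**8, size=200),
        })
        genes["end"] = genes["start"] + rng.integers(1, 10**6, size=200)
        out = gene_overlap(regions, genes, slop_bp=10**9)
        for rec in out.itertuples(index=False):
            g = genes[genes["gene"] == rec.gene].iloc[0]
            if g.start > seg.end_bp:
                expected = g.start - seg.end_bp
            elif g.end < seg.start_bp:
                expected = seg.start_bp - g.end
            else:
                expected = 0
            assert rec.distance_bp == expected
        assert set(out["gene"]) == set(genes.loc[genes["chrom"] == "C2", "gene"])


def test_evidence_matrix_states():
    mm = make_map(4)
    gm = matrix_from_rows({"a1": [HOM1, HET, MISS, HOM2],
                           "a2": [HOM1, HOM1, HOM1, HOM2]}, mm)
    ev = evidence_matrix(gm, ["a1", "a2"])
    assert ev["state"].tolist() == ["shared_hom", "break", "neutral", "shared_hom"]
    assert ev["signature_allele"].tolist() == ["A", ".", ".", "G"]
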