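"""Shared-homozygosity scan and relative-consistency filtering.

The mapping strategy for a recessive disease in a small pedigree: find
chromosomal runs where every affected individual is homozygous for the same
allele (the shared haplotype signature), then discard runs that are
inconsistent with the genotypes of informative relatives — obligate or
declared carriers must carry the shared allele without being homozygous for
the whole signature, and unaffected relatives must not be homozygous for the
signature across the run (either would contradict their phenotype under
autosomal-recessive inheritance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .model import HET, HOM1, HOM2, MISSING, GenotypeMatrix, PedmapError

logger = logging.getLogger(__name__)

# per-marker states of the affected-sharing classification
BREAK, NEUTRAL, SHARED = -1, 0, 1


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SharedSegment:
    """A maximal run of markers shared-homozygous across all affecteds."""

    chrom: str
    start_bp: int
    end_bp: int
    marker_indices: tuple[int, ...]      # global indices of shared markers
    signature: tuple[int, ...]           # HOM1/HOM2 code per shared marker

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise PedmapError("segment start after end")
        if len(self.marker_indices) != len(self.signature):
            raise PedmapError("signature length mismatch")

    @property
    def n_markers(self) -> int:
        return len(self.marker_indices)

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class RelativeVerdict:
    individual_id: str
    rule: str                      # "carrier" | "unaffected"
    passed: bool
    first_fail_marker: str | None = None
    reason: str = ""


@dataclass(frozen=True)
class CandidateRegion:
    segment: SharedSegment
    verdicts: tuple[RelativeVerdict, ...]
    status: str                    # "consistent" | "excluded"

    def __post_init__(self) -> None:
        expected = "consistent" if all(v.passed for v in self.verdicts) else "excluded"
        if self.status != expected:
            raise PedmapError("region status inconsistent with verdicts")


@dataclass
class ConsistencyRuleSet:
    """Relative rules applied to each shared segment.

    Carriers (obligate or declared) must carry the shared allele at every
    non-missing signature marker (up to ``tolerance`` forgiven violations)
    and must not be homozygous for the signature across the whole segment.
    Unaffected relatives are checked only against whole-segment signature
    homozygosity. Missing calls are uninformative and skipped.
    """

    obligate_carrier_ids: tuple[str, ...] = ()
    declared_carrier_ids: tuple[str, ...] = ()
    unaffected_ids: tuple[str, ...] = ()
    tolerance: int = 0

    def all_ids(self) -> tuple[str, ...]:
        return self.obligate_carrier_ids + self.declared_carrier_ids + self.unaffected_ids

    def validate(self, affected_ids: list[str]) -> None:
        overlap = set(self.all_ids()) & set(affected_ids)
        if overlap:
            raise PedmapError(f"rule individuals overlap affected set: {sorted(overlap)}")


def classify_markers(
    genotypes: GenotypeMatrix,
    affected_ids: list[str],
    max_missing_run: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker sharing state across the affected individuals.

    Returns ``(state, signature)`` arrays over all markers: state is BREAK
    where any affected is heterozygous, where non-missing affecteds are
    homozygous for different alleles, or inside a missing run longer than
    ``max_missing_run`` in any affected; NEUTRAL where a missing call keeps
    the marker uninformative; SHARED (with the homozygous class recorded in
    ``signature``) where every affected is homozygous for the same allele.
    """
    if not affected_ids:
        raise PedmapError("at least one affected individual required")
    aff = np.vstack([genotypes.row(i) for i in affected_ids])
    chroms = genotypes.marker_map.table["chrom"].to_numpy()
    n = aff.shape[1]

    het_any = (aff == HET).any(axis=0)
    hom1_any = (aff == HOM1).any(axis=0)
    hom2_any = (aff == HOM2).any(axis=0)
    missing_any = (aff == MISSING).any(axis=0)
    breaks = het_any | (hom1_any & hom2_any)

    # long missing runs become breaks: a gap wider than max_missing_run
    # consecutive markers (per individual, per chromosome) may hide a
    # heterozygous stretch and must not be bridged silently
    chrom_codes = pd.factorize(chroms)[0]
    miss = aff == MISSING
    for row in miss:
        # run boundaries where missingness or chromosome changes
        key = np.where(row, chrom_codes, -1)
        change = np.flatnonzero(np.concatenate(([True], key[1:] != key[:-1], [True])))
        for lo, hi in zip(change[:-1], change[1:]):
            if row[lo] and hi - lo > max_missing_run:
                breaks[lo:hi] = True

    state = np.full(n, NEUTRAL, dtype=np.int8)
    signature = np.full(n, MISSING, dtype=np.int8)
    state[breaks] = BREAK
    shared = ~breaks & ~missing_any
    state[shared] = SHARED
    signature[shared & hom1_any] = HOM1
    signature[shared & hom2_any] = HOM2
    return state, signature


def shared_homozygosity_scan(
    genotypes: GenotypeMatrix,
    affected_ids: list[str],
    min_markers: int = 20,
    max_missing_run: int = 5,
    merge_gap_bp: int = 1_000_000,
) -> list[SharedSegment]:
    """Maximal runs of shared homozygosity across the affected individuals.

    A run is a maximal stretch of SHARED/NEUTRAL markers starting and
    ending on a SHARED marker; it is reported when it contains at least
    ``min_markers`` SHARED markers. Adjacent runs on the same chromosome
    separated by less than ``merge_gap_bp`` whose facing signature classes
    agree are merged before the size filter. Output is sorted by
    (chromosome label, start bp) and invariant to individual ordering.
    """
    state, signature = classify_markers(genotypes, affected_ids, max_missing_run)
    tab = genotypes.marker_map.table
    pos = tab["pos"].to_numpy()
    raw: list[SharedSegment] = []
    for chrom in genotypes.marker_map.chromosomes:
        sl = genotypes.marker_map.chrom_slice(chrom)
        s = state[sl]
        # stretches of non-BREAK markers
        is_open = s != BREAK
        edges = np.flatnonzero(np.diff(np.concatenate(([0], is_open.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            shared_local = np.flatnonzero(s[lo:hi] == SHARED) + lo
            if shared_local.size == 0:
                continue
            first, last = int(shared_local[0]), int(shared_local[-1])
            idx = tuple(int(sl.start + j) for j in shared_local)
            raw.append(
                SharedSegment(
                    chrom=chrom,
                    start_bp=int(pos[sl.start + first]),
                    end_bp=int(pos[sl.start + last]),
                    marker_indices=idx,
                    signature=tuple(int(signature[j]) for j in idx),
                )
            )
    kept = [seg for seg in raw if seg.n_markers >= max(min_markers, 1)]
    merged = _merge_segments(kept, pos, merge_gap_bp)
    return sorted(merged, key=lambda s: (s.chrom, s.start_bp))


def _merge_segments(
    segments: list[SharedSegment], pos: np.ndarray, merge_gap_bp: int
) -> list[SharedSegment]:
    if merge_gap_bp <= 0:
        return segments
    out: list[SharedSegment] = []
    for seg in sorted(segments, key=lambda s: (s.chrom, s.start_bp)):
        if (
            out
            and out[-1].chrom == seg.chrom
            and seg.start_bp - out[-1].end_bp < merge_gap_bp
            and out[-1].signature[-1] == seg.signature[0]
        ):
            prev = out.pop()
            out.append(
                SharedSegment(
                    chrom=prev.chrom,
                    start_bp=prev.start_bp,
                    end_bp=seg.end_bp,
                    marker_indices=prev.marker_indices + seg.marker_indices,
                    signature=prev.signature + seg.signature,
                )
            )
        else:
            out.append(seg)
    return out


def _check_relative(
    calls: np.ndarray,
    seg: SharedSegment,
    rule: str,
    tolerance: int,
    marker_ids: np.ndarray,
) -> RelativeVerdict:
    sig = np.asarray(seg.signature, dtype=np.int8)
    idx = np.asarray(seg.marker_indices, dtype=np.int64)
    c = calls[idx]
    nonmissing = c != MISSING
    matches_sig = (c == sig) & nonmissing
    opposite = np.where(sig == HOM1, HOM2, HOM1).astype(np.int8)
    lacks_allele = (c == opposite) & nonmissing

    # (b) homozygous for the signature at every non-missing marker: would
    # be affected, contradicting the phenotype
    if nonmissing.any() and bool(matches_sig[nonmissing].all()):
        return RelativeVerdict(
            individual_id="", rule=rule, passed=False,
            first_fail_marker=str(marker_ids[idx[nonmissing][0]]),
            reason="homozygous for the shared signature across the segment",
        )
    if rule == "carrier":
        viol = np.flatnonzero(lacks_allele)
        if viol.size > tolerance:
            fail_at = idx[viol[tolerance]]
            return RelativeVerdict(
                individual_id="", rule=rule, passed=False,
                first_fail_marker=str(marker_ids[fail_at]),
                reason=f"lacks the shared allele at {viol.size} marker(s), tolerance {tolerance}",
            )
    return RelativeVerdict(individual_id="", rule=rule, passed=True)


def apply_consistency_filter(
    segments: list[SharedSegment],
    genotypes: GenotypeMatrix,
    rules: ConsistencyRuleSet,
) -> list[CandidateRegion]:
    """Partition segments into consistent and excluded under relative rules."""
    if not rules.all_ids():
        logger.warning("empty consistency rule set: all segments pass unfiltered")
    marker_ids = genotypes.marker_map.table["id"].to_numpy()
    regions: list[CandidateRegion] = []
    rule_rows = [(iid, "carrier") for iid in rules.obligate_carrier_ids + rules.declared_carrier_ids]
    rule_rows += [(iid, "unaffected") for iid in rules.unaffected_ids]
    calls = {iid: genotypes.row(iid) for iid, _ in rule_rows}
    for seg in segments:
        verdicts = []
        for iid, rule in rule_rows:
            v = _check_relative(calls[iid], seg, rule, rules.tolerance, marker_ids)
            verdicts.append(
                RelativeVerdict(iid, v.rule, v.passed, v.first_fail_marker, v.reason)
            )
        status = "consistent" if all(v.passed for v in verdicts) else "excluded"
        regions.append(CandidateRegion(seg, tuple(verdicts), status))
    return regions


def region_report(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Tabular report: one row per region with span arithmetic and verdicts.

    ``span_bp = end - start`` (boundary-marker difference) and ``span_mb``
    is that value over 1e6 rounded half-up to one decimal.
    """
    rows = []
    for region in regions:
        seg = region.segment
        failing = [v.individual_id for v in region.verdicts if not v.passed]
        rows.append(
            {
                "chrom": seg.chrom,
                "start_bp": seg.start_bp,
                "end_bp": seg.end_bp,
                "span_bp": seg.span_bp,
                "span_mb": round_half_up(seg.span_bp / 1e6, 1),
                "n_markers": seg.n_markers,
                "status": region.status,
                "failing_relatives": ",".join(failing),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_bp", "end_bp", "span_bp", "span_mb",
                 "n_markers", "status", "failing_relatives"],
    )


def gene_overlap(
    regions: list[CandidateRegion],
    gene_table: pd.DataFrame,
    slop_bp: int = 0,
) -> pd.DataFrame:
    """Genes overlapping or within ``slop_bp`` of each region.

    ``gene_table`` columns: gene, chrom, start, end (1-based inclusive, same
    assembly as the marker map). Distance is 0 for overlap, otherwise the
    bp gap between the closest interval ends.
    """
    required = {"gene", "chrom", "start", "end"}
    if not required <= set(gene_table.columns):
        raise PedmapError(f"gene table requires columns {sorted(required)}")
    rows = []
    for ridx, region in enumerate(regions):
        seg = region.segment
        for rec in gene_table.itertuples(index=False):
            if rec.chrom != seg.chrom:
                continue
            distance = max(int(rec.start) - seg.end_bp, seg.start_bp - int(rec.end), 0)
            if distance <= slop_bp:
                rows.append(
                    {
                        "gene": rec.gene,
                        "chrom": seg.chrom,
                        "region_index": ridx,
                        "region_start_bp": seg.start_bp,
                        "region_end_bp": seg.end_bp,
                        "region_status": region.status,
                        "distance_bp": distance,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "region_index", "region_start_bp",
                 "region_end_bp", "region_status", "distance_bp"],
    ).sort_values(["region_index", "distance_bp"], kind="stable").reset_index(drop=True)


def evidence_matrix(
    genotypes: GenotypeMatrix, affected_ids: list[str], max_missing_run: int = 5
) -> pd.DataFrame:
    """Per-marker machine-readable sharing evidence (the colour-grid view)."""
    state, signature = classify_markers(genotypes, affected_ids, max_missing_run)
    tab = genotypes.marker_map.table
    label = np.select(
        [state == SHARED, state == BREAK], ["shared_hom", "break"], default="neutral"
    )
    return pd.DataFrame(
        {
            "chrom": tab["chrom"],
            "pos": tab["pos"],
            "marker": tab["id"],
            "state": label,
            "signature_allele": [
                (tab["a1"].iloc[j] if signature[j] == HOM1
                 else tab["a2"].iloc[j] if signature[j] == HOM2 else ".")
                for j in range(len(tab))
            ],
        }
    )
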