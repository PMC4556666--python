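"""Variant consequence mapping and cross-species conservation profiling.

Maps a coding-DNA substitution onto its codon and amino-acid change with
the standard genetic code, computes pairwise percent identity between
protein sequences (native global alignment or a precomputed alignment),
and scans a multiple alignment for columns conserved for a residue class
(e.g. the invariant cysteines of a cysteine-rich domain), reporting them
in reference-sequence residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .model import PedmapError


@dataclass(frozen=True)
class CodonMapping:
    """Consequence of a single-base CDS substitution."""

    cds_position: int              # 1-based within the CDS
    codon_index: int               # 1-based residue number
    codon_offset: int              # position within codon, 1..3
    ref_codon: str
    alt_codon: str
    ref_residue: str
    alt_residue: str
    hgvs_c: str
    hgvs_p: str

    @property
    def synonymous(self) -> bool:
        return self.ref_residue == self.alt_residue


def map_cdna_variant(
    cds_position: int, ref_base: str, alt_base: str, cds_sequence: str
) -> CodonMapping:
    """Map c.<pos><ref>><alt> to its protein consequence.

    The CDS must be a whole number of codons; the base at ``cds_position``
    must equal ``ref_base`` (mismatches are reported with the observed
    base). Translation uses the standard genetic code.
    """
    cds = cds_sequence.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise PedmapError(f"CDS length {len(cds)} is not a multiple of 3")
    if not 1 <= cds_position <= len(cds):
        raise PedmapError(f"position {cds_position} beyond CDS of length {len(cds)}")
    observed = cds[cds_position - 1]
    if observed != ref_base.upper():
        raise PedmapError(
            f"reference base mismatch at c.{cds_position}: expected "
            f"{ref_base.upper()!r}, observed {observed!r}"
        )
    codon_index = (cds_position + 2) // 3
    codon_offset = (cds_position - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds[start:start + 3]
    alt_codon = (
        ref_codon[: codon_offset - 1] + alt_base.upper() + ref_codon[codon_offset:]
    )
    ref_residue = str(Seq(ref_codon).translate())
    alt_residue = str(Seq(alt_codon).translate())
    hgvs_p = (
        f"p.{ref_residue}{codon_index}=" if ref_residue == alt_residue
        else f"p.{ref_residue}{codon_index}{alt_residue}"
    )
    return CodonMapping(
        cds_position=cds_position,
        codon_index=codon_index,
        codon_offset=codon_offset,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_residue=ref_residue,
        alt_residue=alt_residue,
        hgvs_c=f"c.{cds_position}{ref_base.upper()}>{alt_base.upper()}",
        hgvs_p=hgvs_p,
    )


#: identity scoring used for native global alignment
ALIGNER_PARAMS = {
    "match_score": 1.0,
    "mismatch_score": 0.0,
    "open_gap_score": -2.0,
    "extend_gap_score": -0.5,
}


def _global_align(seq_a: str, seq_b: str) -> tuple[str, str]:
    aligner = PairwiseAligner(mode="global", **ALIGNER_PARAMS)
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    mode: str = "global-alignment",
    denominator: str = "alignment",
) -> dict:
    """Percent identity between two protein sequences.

    mode='global-alignment' aligns natively (match 1 / mismatch 0, affine
    gaps); mode='precomputed-alignment' takes already-aligned sequences of
    equal length with '-' gaps. The default denominator is the full
    alignment length, gap columns included; 'shorter' (shorter raw
    sequence) and 'ungapped' (columns with residues in both sequences) are
    selectable. The integer percentage and the method metadata are
    both returned.
    """
    if not seq_a or not seq_b:
        raise PedmapError("empty sequence")
    if mode == "global-alignment":
        a, b = _global_align(seq_a.upper(), seq_b.upper())
    elif mode == "precomputed-alignment":
        a, b = seq_a.upper(), seq_b.upper()
        if len(a) != len(b):
            raise PedmapError("precomputed alignment rows differ in length")
    else:
        raise PedmapError(f"unknown mode {mode!r}")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    denominators = {
        "alignment": len(a),
        "shorter": min(len(a.replace("-", "")), len(b.replace("-", ""))),
        "ungapped": sum(1 for x, y in zip(a, b) if x != "-" and y != "-"),
    }
    if denominator not in denominators:
        raise PedmapError(f"unknown denominator {denominator!r}")
    denom = denominators[denominator]
    pct = 100.0 * matches / denom if denom else 0.0
    return {
        "percent_identity": int(round(pct)),
        "percent_identity_raw": pct,
        "matches": matches,
        "denominator": denominator,
        "denominator_value": denom,
        "alignment_length": len(a),
        "mode": mode,
        "aligner_params": dict(ALIGNER_PARAMS) if mode == "global-alignment" else None,
    }


def _reference_column_map(ref_aligned: str) -> dict[int, int]:
    """1-based reference residue number -> 0-based alignment column."""
    mapping: dict[int, int] = {}
    residue = 0
    for col, ch in enumerate(ref_aligned):
        if ch != "-":
            residue += 1
            mapping[residue] = col
    return mapping


@dataclass
class ConservationProfile:
    """Per-reference-residue conservation flags over an alignment window."""

    reference_id: str
    window: tuple[int, int]        # inclusive reference residue range
    table: pd.DataFrame            # residue, column, ref_residue, fully_conserved,
    #                                predicate_conserved, residues (per-species string)

    def residue(self, number: int) -> pd.Series:
        sub = self.table[self.table["residue"] == number]
        if sub.empty:
            raise PedmapError(f"residue {number} outside profile window {self.window}")
        return sub.iloc[0]


def conserved_column_scan(
    alignment: dict[str, str],
    reference_id: str,
    window: tuple[int, int] | None = None,
    residue_predicate: str | None = None,
) -> tuple[ConservationProfile, list[int]]:
    """Find alignment columns conserved across all sequences.

    A column is *fully conserved* when every sequence holds the same
    residue and none has a gap; it is *predicate conserved* when every
    sequence holds a residue in ``residue_predicate`` (a string of allowed
    letters, e.g. "C") and none has a gap. Columns are reported by
    reference residue number over the requested window (default: the whole
    reference). Returns the profile and the residue numbers matching the
    predicate (the full-conservation flag when no predicate is given).
    """
    if reference_id not in alignment:
        raise PedmapError(f"reference {reference_id!r} not in alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise PedmapError("alignment rows differ in length")
    ref = alignment[reference_id].upper()
    col_of = _reference_column_map(ref)
    n_res = len(col_of)
    lo, hi = window or (1, n_res)
    if not 1 <= lo <= hi <= n_res:
        raise PedmapError(f"window {lo}:{hi} outside reference length {n_res}")
    others = {k: v.upper() for k, v in alignment.items()}
    rows = []
    matching: list[int] = []
    predicate = set(residue_predicate.upper()) if residue_predicate else None
    for residue_number in range(lo, hi + 1):
        col = col_of[residue_number]
        column = [others[k][col] for k in others]
        gap_free = "-" not in column
        fully = gap_free and len(set(column)) == 1
        pred_ok = gap_free and predicate is not None and all(c in predicate for c in column)
        rows.append(
            {
                "residue": residue_number,
                "column": col,
                "ref_residue": ref[col],
                "fully_conserved": fully,
                "predicate_conserved": bool(pred_ok),
                "residues": "".join(column),
            }
        )
        if (pred_ok if predicate is not None else fully):
            matching.append(residue_number)
    profile = ConservationProfile(
        reference_id=reference_id,
        window=(lo, hi),
        table=pd.DataFrame(rows),
    )
    return profile, matching


def substitution_report(
    mapping: CodonMapping,
    profile: ConservationProfile,
    domain_window: tuple[int, int] = (375, 451),
    known_mutations: pd.DataFrame | None = None,
) -> dict:
    """Combine a substitution with its conservation and domain context.

    ``known_mutations`` (optional) has columns residue, change, phenotype —
    orthologous disease mutations to cross-reference by residue number.
    No deleteriousness score is computed; external predictor scores are
    metadata, not outputs, of this package.
    """
    residue = mapping.codon_index
    lo, hi = profile.window
    in_profile = lo <= residue <= hi
    fully = bool(profile.residue(residue)["fully_conserved"]) if in_profile else None
    in_domain = domain_window[0] <= residue <= domain_window[1]
    cross_refs = []
    if known_mutations is not None and len(known_mutations):
        hits = known_mutations[known_mutations["residue"].astype(int) == residue]
        cross_refs = hits.to_dict("records")
    if in_domain and fully:
        category = "conserved-domain substitution"
    elif in_domain:
        category = "domain substitution, not fully conserved"
    else:
        category = "outside domain"
    return {
        "substitution": mapping.hgvs_p,
        "hgvs_c": mapping.hgvs_c,
        "residue": residue,
        "ref_residue": mapping.ref_residue,
        "alt_residue": mapping.alt_residue,
        "fully_conserved": fully,
        "in_domain": in_domain,
        "domain_window": domain_window,
        "category": category,
        "known_orthologous_mutations": cross_refs,
    }
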