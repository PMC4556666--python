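"""Readers and writers for every on-disk format the pipeline touches.

Formats: PLINK text .ped/.map (white-space delimited), a FAM-style carrier
side-car TSV, single-variant genotype tables (TSV or minimal single-site
VCF), and FASTA / aligned FASTA. All readers validate into the internal
model and reject structural errors rather than repairing them; all writers
emit files their reader accepts.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    HET,
    HOM1,
    HOM2,
    MISSING,
    GenotypeMatrix,
    Individual,
    MarkerMap,
    ParseError,
    Pedigree,
    VariantGenotypeTable,
    normalise_genotype_string,
)

logger = logging.getLogger(__name__)

_SEX_CODE = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {v: k for k, v in _SEX_CODE.items()}
_PHENO_CODE = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
_PHENO_TO_CODE = {"affected": "2", "unaffected": "1", "unknown": "0"}


def read_map(map_path: str | os.PathLike) -> MarkerMap:
    """PLINK .map: chrom, marker id, genetic position (ignored), bp."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, mid, _cm, bp = parts[:4]
            a1, a2 = (parts[4], parts[5]) if len(parts) >= 6 else ("1", "2")
            try:
                rows.append((chrom, mid, int(bp), a1, a2))
            except ValueError:
                raise ParseError(f"{map_path}:{lineno}: non-integer bp {bp!r}") from None
    return MarkerMap(pd.DataFrame(rows, columns=["chrom", "id", "pos", "a1", "a2"]))


def read_plink(
    ped_path: str | os.PathLike, map_path: str | os.PathLike
) -> tuple[Pedigree, GenotypeMatrix]:
    """Read a PLINK text fileset into a validated pedigree + call matrix.

    PHENO coding 2=affected, 1=unaffected, 0/-9=unknown; missing alleles
    are "0". Allele symbols observed in the .ped refine the .map allele
    columns when the .map carries placeholder alleles.
    """
    marker_map = read_map(map_path)
    n_markers = len(marker_map)
    individuals: list[Individual] = []
    raw_alleles: list[list[str]] = []
    ids_seen: set[str] = set()
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} columns "
                    f"for {n_markers} markers, got {len(parts)}"
                )
            _fid, iid, pat, mat, sex, pheno = parts[:6]
            if iid in ids_seen:
                raise ParseError(f"{ped_path}:{lineno}: duplicate individual id {iid!r}")
            ids_seen.add(iid)
            if sex not in _SEX_CODE:
                raise ParseError(f"{ped_path}:{lineno}: invalid sex code {sex!r}")
            if pheno not in _PHENO_CODE:
                raise ParseError(f"{ped_path}:{lineno}: invalid phenotype code {pheno!r}")
            individuals.append(
                Individual(
                    iid,
                    sire=None if pat == "0" else pat,
                    dam=None if mat == "0" else mat,
                    sex=_SEX_CODE[sex],
                    phenotype=_PHENO_CODE[pheno],
                )
            )
            raw_alleles.append(parts[6:])

    if n_markers == 0 and individuals:
        raise ParseError(f"{map_path}: empty marker map with non-empty {ped_path}")

    # resolve allele symbols per marker; observed symbols must not exceed two
    calls = np.full((len(individuals), n_markers), MISSING, dtype=np.int8)
    map_tab = marker_map.table
    placeholder = (map_tab["a1"] == "1").to_numpy() & (map_tab["a2"] == "2").to_numpy()
    a1 = map_tab["a1"].to_numpy().astype(object)
    a2 = map_tab["a2"].to_numpy().astype(object)
    for m in range(n_markers):
        observed = []
        for row in raw_alleles:
            for al in (row[2 * m], row[2 * m + 1]):
                if al != "0" and al not in observed:
                    observed.append(al)
        if placeholder[m] and observed:
            a1[m] = observed[0]
            a2[m] = observed[1] if len(observed) > 1 else ("2" if observed[0] != "2" else "1")
        allowed = {a1[m], a2[m]}
        for i, row in enumerate(raw_alleles):
            x, y = row[2 * m], row[2 * m + 1]
            if (x == "0") != (y == "0"):
                raise ParseError(
                    f"{ped_path}: individual {individuals[i].id!r} marker "
                    f"{map_tab['id'].iloc[m]!r}: half-missing genotype"
                )
            if x == "0":
                continue
            if x not in allowed or y not in allowed:
                raise ParseError(
                    f"{ped_path}: individual {individuals[i].id!r} marker "
                    f"{map_tab['id'].iloc[m]!r}: allele {x!r}/{y!r} not in map alleles {sorted(allowed)}"
                )
            if x == y:
                calls[i, m] = HOM1 if x == a1[m] else HOM2
            else:
                calls[i, m] = HET
    refined = MarkerMap(map_tab.assign(a1=a1, a2=a2))
    pedigree = Pedigree(individuals)
    matrix = GenotypeMatrix([i.id for i in individuals], refined, calls)
    rates = matrix.call_rates()
    logger.info("read %d individuals x %d markers; call rates %.3f-%.3f",
                len(individuals), n_markers, rates.min() if len(rates) else 1.0,
                rates.max() if len(rates) else 1.0)
    return pedigree, matrix


def write_plink(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    out_prefix: str | os.PathLike,
) -> tuple[Path, Path]:
    """Write .ped/.map re-readable by :func:`read_plink`.

    Carrier declarations are not representable in PLINK; persist them with
    :func:`write_declared_status` if needed.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    tab = genotypes.marker_map.table
    with open(map_path, "w") as fh:
        for rec in tab.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.id}\t0\t{rec.pos}\t{rec.a1}\t{rec.a2}\n")
    a1 = tab["a1"].to_numpy()
    a2 = tab["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for iid in genotypes.individual_ids:
            ind = pedigree[iid]
            row = genotypes.row(iid)
            fields = [
                "FAM1", iid, ind.sire or "0", ind.dam or "0",
                _SEX_TO_CODE[ind.sex], _PHENO_TO_CODE[ind.phenotype],
            ]
            pairs = np.empty((len(row), 2), dtype=object)
            pairs[row == HOM1] = np.stack([a1[row == HOM1]] * 2, axis=1)
            pairs[row == HOM2] = np.stack([a2[row == HOM2]] * 2, axis=1)
            pairs[row == HET, 0] = a1[row == HET]
            pairs[row == HET, 1] = a2[row == HET]
            pairs[row == MISSING] = ("0", "0")
            fields.extend(pairs.ravel())
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_pedigree_table(path: str | os.PathLike) -> Pedigree:
    """FAM-style TSV: individual, sire, dam, sex, phenotype, declared_status
    ('0' or empty for unknown parents)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    cols = {c.lower(): c for c in df.columns}
    for req in ("individual", "sire", "dam", "sex", "phenotype"):
        if req not in cols:
            raise ParseError(f"{path}: missing column {req!r}")
    inds = []
    for rec in df.itertuples(index=False):
        row = {k.lower(): v for k, v in zip(df.columns, rec)}
        inds.append(
            Individual(
                row["individual"],
                sire=row["sire"] or None if row["sire"] != "0" else None,
                dam=row["dam"] or None if row["dam"] != "0" else None,
                sex=row["sex"] or "unknown",
                phenotype=row["phenotype"] or "unknown",
                declared_status=row.get("declared_status") or "none",
            )
        )
    return Pedigree(inds)


def write_pedigree_table(pedigree: Pedigree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tsire\tdam\tsex\tphenotype\tdeclared_status\n")
        for ind in pedigree:
            fh.write(
                f"{ind.id}\t{ind.sire or '0'}\t{ind.dam or '0'}\t{ind.sex}\t"
                f"{ind.phenotype}\t{ind.declared_status}\n"
            )


def read_declared_status(path: str | os.PathLike) -> dict[str, str]:
    """Side-car TSV (individual, status) with carrier declarations."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "individual" not in cols or "status" not in cols:
        raise ParseError(f"{path}: expected columns 'individual' and 'status'")
    return dict(zip(df[cols["individual"]], df[cols["status"]]))


def write_declared_status(statuses: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tstatus\n")
        for iid, status in statuses.items():
            fh.write(f"{iid}\t{status}\n")


def read_variant_table(
    path: str | os.PathLike,
    variant_id: str | None = None,
    ref: str = "G",
    alt: str = "A",
) -> VariantGenotypeTable:
    """Read a single-variant genotype table from TSV or minimal VCF.

    TSV columns: individual, genotype, optional breed; genotype strings are
    unordered allele pairs ("G/A" == "A/G"). Unrecognisable genotype strings
    become missing with a logged warning. A ``.vcf`` path is parsed as a
    single-site VCF with GT fields.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_single_site_vcf(path, variant_id)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "individual" not in cols or "genotype" not in cols:
        raise ParseError(f"{path}: no recognizable individual/genotype columns")
    out = pd.DataFrame(
        {
            "individual": df[cols["individual"]].astype(str),
            "breed": df[cols["breed"]].fillna("") if "breed" in cols else "",
        }
    )
    classes = []
    for iid, raw in zip(out["individual"], df[cols["genotype"]].fillna("")):
        cls = normalise_genotype_string(str(raw), ref, alt)
        if cls is None:
            logger.warning("%s: unrecognised genotype %r for %s -> missing", path, raw, iid)
            cls = "missing"
        classes.append(cls)
    out["genotype"] = classes
    return VariantGenotypeTable(variant_id or path.stem, ref, alt, out)


def _read_single_site_vcf(path: Path, variant_id: str | None) -> VariantGenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = list(vcf)
    if len(records) != 1:
        raise ParseError(f"{path}: expected exactly one VCF site, found {len(records)}")
    rec = records[0]
    if len(rec.ALT) != 1:
        raise ParseError(f"{path}: expected a biallelic site")
    classes = []
    for gt in rec.genotypes:  # [allele0, allele1, phased]
        pair = [a for a in gt[:-1]]
        if any(a < 0 for a in pair):
            classes.append("missing")
        else:
            classes.append({0: "hom_ref", 1: "het", 2: "hom_alt"}[sum(pair)])
    df = pd.DataFrame({"individual": samples, "genotype": classes, "breed": ""})
    vid = variant_id or (rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    return VariantGenotypeTable(vid, rec.REF, rec.ALT[0], df)


def write_variant_table(table: VariantGenotypeTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# variant: {table.variant_id} ref={table.ref} alt={table.alt}\n")
        fh.write("individual\tbreed\tgenotype\n")
        for rec in table.table.itertuples(index=False):
            fh.write(f"{rec.individual}\t{rec.breed}\t{table.genotype_label(rec.genotype)}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA to an ordered {id: residues} mapping."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ParseError(f"{path}: no FASTA records")
    return seqs


def read_aligned_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Aligned FASTA; enforces equal record lengths ('-' as gap)."""
    seqs = read_fasta(path)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ParseError(f"{path}: aligned records have unequal lengths {sorted(lengths)}")
    return seqs


def gap_only_columns(alignment: dict[str, str]) -> list[int]:
    """0-based indices of columns that are gaps in every sequence."""
    arr = np.array([list(s) for s in alignment.values()])
    return [int(i) for i in np.flatnonzero((arr == "-").all(axis=0))]


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
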