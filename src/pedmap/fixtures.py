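"""Reference fixtures: the published genotype tables and synthetic bundles.

`table1_*` encode the study's family validation cohort (27 typed cats at
the candidate variant); `table2_*` encode the 14-breed control panels
(306 cats, including the 81-cat Sphynx control subpanel). Both are small
printed tables, reconstructed here programmatically. The demo family,
ortholog set and CDS are synthetic, generated by :mod:`pedmap.sim`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as pio
from .model import Individual, Pedigree, VariantGenotypeTable
from .sim import SimulationConfig, generate_ortholog_set, simulate_study_family

VARIANT_ID = "COLQ c.1190G>A"
REF, ALT = "G", "A"


def table1_pedigree() -> Pedigree:
    """The validation-cohort pedigree: affected Sphynx sib-pair, parents,
    paternal grandparents, four healthy siblings, three sisters of the
    sire, 13 paternal half-siblings (dams untyped) and one unrelated
    affected Devon Rex."""
    inds = [
        Individual("PGF", sex="male", phenotype="unaffected"),
        Individual("PGM", sex="female", phenotype="unaffected",
                   declared_status="declared_carrier"),
        Individual("SIRE", sire="PGF", dam="PGM", sex="male", phenotype="unaffected"),
        Individual("DAM", sex="female", phenotype="unaffected"),
        Individual("PROBAND", sire="SIRE", dam="DAM", sex="male", phenotype="affected"),
        Individual("AFF2", sire="SIRE", dam="DAM", sex="female", phenotype="affected"),
        Individual("DR_AFF", sex="female", phenotype="affected"),
    ]
    inds += [
        Individual(f"SIB{i}", sire="SIRE", dam="DAM", sex="female", phenotype="unaffected")
        for i in range(1, 5)
    ]
    inds += [
        Individual(f"AUNT{i}", sire="PGF", dam="PGM", sex="female", phenotype="unaffected")
        for i in range(1, 4)
    ]
    # half-siblings of the proband: sire x four untyped dams
    dams = [f"HDAM{i}" for i in range(1, 5)]
    inds += [Individual(d, sex="female", phenotype="unknown") for d in dams]
    inds += [
        Individual(f"HS{i:02d}", sire="SIRE", dam=dams[(i - 1) % 4],
                   sex="unknown", phenotype="unaffected")
        for i in range(1, 14)
    ]
    return Pedigree(inds)


def table1_variant_table() -> VariantGenotypeTable:
    """Genotypes of the 27 typed cats: 9 G/G, 15 G/A, 3 A/A."""
    rows: list[tuple[str, str]] = [
        ("PROBAND", "hom_alt"), ("AFF2", "hom_alt"), ("DR_AFF", "hom_alt"),
        ("SIRE", "het"), ("DAM", "het"),
        ("PGM", "het"), ("PGF", "hom_ref"),
        ("SIB1", "het"), ("SIB2", "het"), ("SIB3", "het"), ("SIB4", "het"),
        ("AUNT1", "hom_ref"), ("AUNT2", "hom_ref"), ("AUNT3", "het"),
    ]
    half_sib_genos = ["hom_ref"] * 6 + ["het"] * 7
    rows += [(f"HS{i:02d}", g) for i, g in enumerate(half_sib_genos, start=1)]
    df = pd.DataFrame(rows, columns=["individual", "genotype"])
    df["breed"] = "Sphynx"
    df.loc[df["individual"] == "DR_AFF", "breed"] = "Devon Rex"
    return VariantGenotypeTable(VARIANT_ID, REF, ALT, df)


#: control panels: breed -> (n hom-ref, n het, n hom-alt)
TABLE2_PANEL_COUNTS: dict[str, tuple[int, int, int]] = {
    "Control Sphynx cats": (78, 3, 0),
    "Control Devon Rex cats": (14, 0, 0),
    "Siamese & Oriental SH and LH": (22, 0, 0),
    "Persian": (20, 0, 0),
    "British SH and LH": (20, 0, 0),
    "Birman": (27, 0, 0),
    "Ragdoll": (10, 0, 0),
    "Norwegian Forest": (22, 0, 0),
    "Maine Coon": (21, 0, 0),
    "Chartreux": (16, 0, 0),
    "Bengal": (15, 0, 0),
    "Abyssinian": (7, 0, 0),
    "Russian Blue": (4, 0, 0),
    "Outbred domestic shorthair cats": (27, 0, 0),
}


def table2_variant_table() -> VariantGenotypeTable:
    """Per-individual expansion of the 14 control panels (306 cats)."""
    rows = []
    for bi, (breed, (n_rr, n_ra, n_aa)) in enumerate(TABLE2_PANEL_COUNTS.items(), 1):
        tag = f"BR{bi:02d}_"
        k = 0
        for geno, count in (("hom_ref", n_rr), ("het", n_ra), ("hom_alt", n_aa)):
            for _ in range(count):
                k += 1
                rows.append((f"{tag}{k:03d}", geno, breed))
    df = pd.DataFrame(rows, columns=["individual", "genotype", "breed"])
    return VariantGenotypeTable(VARIANT_ID, REF, ALT, df)


def sphynx_control_subpanel() -> VariantGenotypeTable:
    """The 81-cat control Sphynx subpanel (78 G/G, 3 G/A)."""
    full = table2_variant_table()
    sub = full.table[full.table["breed"] == "Control Sphynx cats"]
    return VariantGenotypeTable(VARIANT_ID, REF, ALT, sub)


def synthetic_cds(n_codons: int = 397, variant_codon: int = 397) -> str:
    """Deterministic CDS whose codon ``variant_codon`` is TGC (cysteine),
    so that the G at the codon's second base sits at CDS position
    3*variant_codon - 1. Synthetic stand-in for the unavailable feline
    transcript sequence."""
    codons = ["ATG"] + ["GCT"] * (n_codons - 1)
    codons[variant_codon - 1] = "TGC"
    return "".join(codons)


#: ten invariant cysteines within the human 375-451 C-terminal window
DEFAULT_CONSERVED_CYSTEINES = (375, 381, 397, 400, 405, 412, 420, 430, 440, 451)

ORTHOLOG_SPECIES = ("Homo", "Felis", "Mus", "Bos", "Gallus", "Xenopus", "Danio", "Takifugu")


def synthetic_ortholog_bundle(
    seed: int = 0,
    reference_length: int = 455,
    divergence: float = 0.13,
    conserved_positions: tuple[int, ...] = DEFAULT_CONSERVED_CYSTEINES,
) -> dict[str, str]:
    """Gapless synthetic ortholog set mirroring the eight-species COLQ
    comparison: pinned cysteines in the C-terminal window, ~13% per-site
    divergence from the reference elsewhere."""
    return generate_ortholog_set(
        reference_length=reference_length,
        n_species=len(ORTHOLOG_SPECIES),
        conserved_positions=list(conserved_positions),
        divergence=divergence,
        seed=seed,
        conserved_residue="C",
        species_names=list(ORTHOLOG_SPECIES),
    )


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the full fixture bundle; byte-identical under a fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ped = table1_pedigree()
    paths["table1_pedigree"] = out / "table1_pedigree.tsv"
    pio.write_pedigree_table(ped, paths["table1_pedigree"])
    paths["table1_variants"] = out / "table1_variants.tsv"
    pio.write_variant_table(table1_variant_table(), paths["table1_variants"])
    paths["table2_panel"] = out / "table2_panel.tsv"
    pio.write_variant_table(table2_variant_table(), paths["table2_panel"])
    paths["sphynx_subpanel"] = out / "sphynx_subpanel.tsv"
    pio.write_variant_table(sphynx_control_subpanel(), paths["sphynx_subpanel"])

    config = SimulationConfig(n_markers=8_000, seed=seed)
    fam = simulate_study_family(config)
    paths["family_ped"], paths["family_map"] = pio.write_plink(
        fam.pedigree, fam.genotypes, out / "family"
    )
    paths["family_pedigree"] = out / "family_pedigree.tsv"
    pio.write_pedigree_table(fam.pedigree, paths["family_pedigree"])
    truth = pd.DataFrame(
        {
            "individual": list(fam.truth),
            "carrier_status": [fam.truth[i].carrier_status for i in fam.truth],
        }
    )
    paths["family_truth"] = out / "family_truth.tsv"
    truth.to_csv(paths["family_truth"], sep="\t", index=False)
    mm = fam.genotypes.marker_map.table
    causal = mm.iloc[fam.causal_marker_index]
    genes = pd.DataFrame(
        [
            {"gene": "COLQ", "chrom": causal.chrom,
             "start": int(causal.pos) - 40_000, "end": int(causal.pos) + 40_000},
            {"gene": "DECOY1", "chrom": "A1", "start": 1_000_000, "end": 1_100_000},
        ]
    )
    paths["genes"] = out / "genes.tsv"
    genes.to_csv(paths["genes"], sep="\t", index=False)

    orthologs = synthetic_ortholog_bundle(seed=seed)
    paths["orthologs"] = out / "orthologs.fasta"
    pio.write_fasta(orthologs, paths["orthologs"])
    paths["orthologs_aln"] = out / "orthologs_aln.fasta"
    pio.write_fasta(orthologs, paths["orthologs_aln"])  # gapless -> already aligned
    paths["cds"] = out / "cds.fasta"
    pio.write_fasta({"COLQ_CDS_synthetic": synthetic_cds()}, paths["cds"])
    return paths
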