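"""Synthetic pedigree genotypes, breed panels and ortholog protein sets.

The generator emulates the data regime of a small-pedigree recessive-disease
mapping study: a dense biallelic SNP array (~61,705 usable markers on an
18-autosome cat-like karyotype), a three-generation family segregating a
founder-introduced recessive mutation with an affected sib-pair, per-call
missingness keeping call rates above 95%, and healthy breed panels with a
configurable carrier frequency.

Gene dropping is a forward simulation: founder haplotypes are drawn
marker-independently from stated allele frequencies, then transmitted with
recombination under the Haldane map function at a uniform cM/Mb rate.
Haplotype origins are tracked exactly, so ground truth (identity by descent,
carrier status at the causal locus) is available for every simulated
individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    CAT_AUTOSOMES,
    MISSING,
    GenotypeMatrix,
    Individual,
    MarkerMap,
    Pedigree,
    PedmapError,
    VariantGenotypeTable,
)

DEFAULT_N_MARKERS = 61_705


@dataclass
class SimulationConfig:
    """Stated world for the family simulation.

    Parameters
    ----------
    n_markers
        Total marker count, distributed over chromosomes proportionally to
        their physical length (the array's per-chromosome density is not
        published; proportional allocation is the package default).
    chromosome_lengths_mb
        Autosome labels with lengths in Mb; default is the 18 cat autosomes.
    recomb_rate_cm_per_mb
        Uniform genetic-map rate; 1 cM/Mb is the standard mammalian default.
    missing_rate
        Independent per-call missing probability. Default 0.04 keeps
        per-individual call rates above the study's 95% threshold.
    causal_chrom, causal_bp
        Location of the implanted recessive locus.
    carrier_founders
        Founder ids whose haplotype 0 carries the mutation.
    ancestral_segment_mb
        Length of the identical-by-descent segment shared by all mutant
        founder haplotypes around the causal locus, emulating a recent
        founder mutation (without it the affecteds would not be
        shared-homozygous at the locus).
    freq_low, freq_high
        Per-marker founder allele-1 frequency is Uniform(freq_low, freq_high),
        mimicking array ascertainment toward common variants.
    """

    n_markers: int = DEFAULT_N_MARKERS
    chromosome_lengths_mb: dict[str, float] = field(
        default_factory=lambda: dict(CAT_AUTOSOMES)
    )
    recomb_rate_cm_per_mb: float = 1.0
    missing_rate: float = 0.04
    genotype_error_rate: float = 0.0
    causal_chrom: str = "C2"
    causal_bp: int = 139_000_000
    carrier_founders: tuple[str, ...] = ("PGM", "DAM")
    ancestral_segment_mb: float = 20.0
    freq_low: float = 0.2
    freq_high: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise PedmapError("missing_rate must be in [0, 1)")
        if self.missing_rate >= 0.05:
            raise PedmapError(
                "missing_rate >= 0.05 contradicts the >95% call-rate regime"
            )
        if self.causal_chrom not in self.chromosome_lengths_mb:
            raise PedmapError(f"causal chromosome {self.causal_chrom!r} not in karyotype")
        span = self.chromosome_lengths_mb[self.causal_chrom] * 1e6
        if not 1 <= self.causal_bp <= span:
            raise PedmapError("causal locus outside its chromosome span")


def _distinct_positions(rng: np.random.Generator, span: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions in [1, span] without permuting
    the whole range (spans are hundreds of Mb)."""
    if n > span:
        raise PedmapError("more markers requested than positions available")
    pos = np.unique(rng.integers(1, span + 1, size=int(n * 1.05) + 16))
    while pos.size < n:
        extra = rng.integers(1, span + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False)) if pos.size > n else pos


def simulate_marker_map(config: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    """Random marker map: counts proportional to chromosome length,
    positions sorted uniform draws, allele symbols two distinct bases."""
    lengths = config.chromosome_lengths_mb
    total = sum(lengths.values())
    rows = []
    bases = np.array(list("ACGT"))
    remaining = config.n_markers
    chroms = list(lengths)
    for i, chrom in enumerate(chroms):
        n = remaining if i == len(chroms) - 1 else int(round(config.n_markers * lengths[chrom] / total))
        n = min(n, remaining)
        remaining -= n
        span = int(lengths[chrom] * 1e6)
        pos = _distinct_positions(rng, span, n)
        allele_idx = rng.integers(0, 4, size=(n, 2))
        allele_idx[:, 1] = (allele_idx[:, 0] + 1 + (allele_idx[:, 1] % 3)) % 4
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "id": [f"{chrom}_{p}" for p in pos],
            "pos": pos,
            "a1": bases[allele_idx[:, 0]],
            "a2": bases[allele_idx[:, 1]],
        }))
    return MarkerMap(pd.concat(rows, ignore_index=True))


def simulate_founder_haplotypes(
    marker_map: MarkerMap,
    freqs: np.ndarray | float,
    n_founders: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw founder haplotypes marker-independently.

    Returns an ``(n_founders, 2, n_markers)`` uint8 array of allele indices
    (0 = allele1, 1 = allele2); allele1 is drawn with its stated frequency.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(marker_map)
    freqs = np.broadcast_to(np.asarray(freqs, dtype=float), (n,))
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise PedmapError("founder allele frequencies must lie strictly in (0, 1)")
    if n_founders < 2:
        raise PedmapError("need at least 2 founders")
    draws = rng.random((n_founders, 2, n))
    return (draws >= freqs).astype(np.uint8)  # allele1 with prob freq


def uniform_founder_freqs(
    marker_map: MarkerMap, rng: np.random.Generator, low: float = 0.2, high: float = 0.8
) -> np.ndarray:
    return rng.uniform(low, high, size=len(marker_map))


def _crossover_probs(marker_map: MarkerMap, rate_cm_per_mb: float) -> np.ndarray:
    """Haldane inter-marker crossover probabilities, 0.5 across chromosome
    boundaries (independent assortment)."""
    tab = marker_map.table
    pos = tab["pos"].to_numpy(dtype=float)
    chrom = tab["chrom"].to_numpy()
    d_morgan = np.diff(pos) / 1e6 * rate_cm_per_mb / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    r[chrom[1:] != chrom[:-1]] = 0.5
    return r


def _meiosis(origins: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a (2, n_markers) origin-label pair."""
    n = origins.shape[1]
    cross = rng.random(n - 1) < r
    phase = np.empty(n, dtype=np.int8)
    phase[0] = rng.integers(0, 2)
    np.bitwise_xor.accumulate(np.concatenate(([phase[0]], cross.astype(np.int8))), out=phase)
    return origins[phase, np.arange(n)]


@dataclass
class TruthRecord:
    """Ground-truth haplotype origins for one simulated individual.

    ``origins`` holds global founder-haplotype labels (index into
    ``GeneDropResult.hap_labels``) for the paternal and maternal strand.
    """

    individual_id: str
    origins: np.ndarray  # (2, n_markers) int32
    carrier_status: str = "unknown"  # hom_mut | carrier | noncarrier | unknown


@dataclass
class GeneDropResult:
    genotypes: GenotypeMatrix
    truth: dict[str, TruthRecord]
    hap_labels: list[str]          # e.g. "PGM.0"
    hap_alleles: np.ndarray        # (n_founder_haps, n_markers) allele indices


def _origins_to_calls(origins: np.ndarray, hap_alleles: np.ndarray) -> np.ndarray:
    cols = np.arange(origins.shape[1])
    alt_count = hap_alleles[origins[0], cols] + hap_alleles[origins[1], cols]
    return alt_count.astype(np.int8)  # 0->HOM1, 1->HET, 2->HOM2 by encoding


def drop_genes(
    pedigree: Pedigree,
    founder_haplotypes: dict[str, np.ndarray],
    marker_map: MarkerMap,
    recomb_rate_cm_per_mb: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> GeneDropResult:
    """Transmit founder haplotypes through the pedigree with recombination.

    Every transmitted gamete is a recombinant of the parent's two strands
    with inter-marker crossover probabilities from the Haldane map function;
    the returned truth records store exact haplotype origins, so Mendelian
    consistency holds at every marker by construction.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    founder_ids = [f.id for f in pedigree.founders()]
    for fid in founder_ids:
        if fid not in founder_haplotypes:
            raise PedmapError(f"founder {fid!r} has no assigned haplotypes")
    n = len(marker_map)
    hap_labels = [f"{fid}.{h}" for fid in founder_ids for h in (0, 1)]
    hap_alleles = np.vstack(
        [np.asarray(founder_haplotypes[fid], dtype=np.uint8).reshape(2, n) for fid in founder_ids]
    )
    r = _crossover_probs(marker_map, recomb_rate_cm_per_mb)

    origins: dict[str, np.ndarray] = {}
    for ind in pedigree.topological_order():
        if ind.is_founder:
            base = 2 * founder_ids.index(ind.id)
            origins[ind.id] = np.stack(
                [np.full(n, base, dtype=np.int32), np.full(n, base + 1, dtype=np.int32)]
            )
        else:
            pat = _meiosis(origins[ind.sire], r, rng)
            mat = _meiosis(origins[ind.dam], r, rng)
            origins[ind.id] = np.stack([pat, mat])

    ids = [ind.id for ind in pedigree.topological_order()]
    calls = np.vstack([_origins_to_calls(origins[i], hap_alleles) for i in ids])
    truth = {i: TruthRecord(i, origins[i]) for i in ids}
    return GeneDropResult(
        genotypes=GenotypeMatrix(ids, marker_map, calls),
        truth=truth,
        hap_labels=hap_labels,
        hap_alleles=hap_alleles,
    )


def implant_recessive_disease(
    result: GeneDropResult,
    causal_chrom: str,
    causal_bp: int,
    carrier_founders: list[str] | tuple[str, ...],
    mutant_hap: int = 0,
) -> dict[str, str]:
    """Assign phenotypes from descent at the causal locus.

    An individual is affected iff both strands at the marker nearest the
    causal position descend from mutation-bearing founder haplotypes
    (haplotype ``mutant_hap`` of each carrier founder). Truth records are
    updated with carrier status; the phenotype map is returned.
    """
    mm = result.genotypes.marker_map
    causal_idx = mm.nearest_marker(causal_chrom, causal_bp)
    mutant = {
        result.hap_labels.index(f"{fid}.{mutant_hap}") for fid in carrier_founders
        if f"{fid}.{mutant_hap}" in result.hap_labels
    }
    if len(mutant) != len(carrier_founders):
        missing = [f for f in carrier_founders if f"{f}.{mutant_hap}" not in result.hap_labels]
        raise PedmapError(f"carrier founders not in pedigree founders: {missing}")
    phenotypes: dict[str, str] = {}
    for iid, rec in result.truth.items():
        hits = sum(int(rec.origins[s, causal_idx]) in mutant for s in (0, 1))
        rec.carrier_status = {0: "noncarrier", 1: "carrier", 2: "hom_mut"}[hits]
        phenotypes[iid] = "affected" if hits == 2 else "unaffected"
    return phenotypes


def apply_missingness(
    genotypes: GenotypeMatrix, rate: float, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Set each call independently to missing with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise PedmapError("missing rate must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    calls = genotypes.calls.copy()
    if rate > 0.0:
        calls[rng.random(calls.shape) < rate] = MISSING
    return GenotypeMatrix(list(genotypes.individual_ids), genotypes.marker_map, calls)


def simulate_panel(
    n_individuals: int,
    carrier_fraction: float,
    seed: int | np.random.Generator,
    variant_id: str = "COLQ c.1190G>A",
    ref: str = "G",
    alt: str = "A",
    breed: str = "",
    id_prefix: str = "P",
) -> VariantGenotypeTable:
    """Healthy control panel at one variant: each individual is heterozygous
    with probability ``carrier_fraction``, otherwise homozygous reference.
    Homozygous-alternate genotypes are never emitted (affected animals do
    not enter control panels)."""
    if not 0.0 <= carrier_fraction <= 1.0:
        raise PedmapError("carrier_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    het = rng.random(n_individuals) < carrier_fraction
    df = pd.DataFrame(
        {
            "individual": [f"{id_prefix}{i + 1:04d}" for i in range(n_individuals)],
            "genotype": np.where(het, "het", "hom_ref"),
            "breed": breed,
        }
    )
    return VariantGenotypeTable(variant_id, ref, alt, df)


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def generate_ortholog_set(
    reference_length: int,
    n_species: int,
    conserved_positions: list[int] | tuple[int, ...],
    divergence: float,
    seed: int | np.random.Generator,
    conserved_residue: str = "C",
    species_names: list[str] | None = None,
    exclusive: bool = True,
) -> dict[str, str]:
    """Reference protein plus diverged orthologs with pinned conserved sites.

    ``conserved_positions`` (1-based) always hold ``conserved_residue`` in
    every sequence; all other positions substitute independently with
    probability ``divergence``. With ``exclusive=True`` (default) the
    conserved residue never appears outside the pinned positions in any
    sequence, so a conserved-column scan for that residue recovers exactly
    the constructed set.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if any(not 1 <= p <= reference_length for p in conserved_positions):
        raise PedmapError("conserved positions outside reference length")
    alphabet = AMINO_ACIDS.replace(conserved_residue, "") if exclusive else AMINO_ACIDS
    letters = np.array(list(alphabet))
    cons = np.zeros(reference_length, dtype=bool)
    cons[np.asarray(conserved_positions, dtype=int) - 1] = True

    ref = letters[rng.integers(0, len(letters), size=reference_length)]
    ref[cons] = conserved_residue
    names = species_names or ["reference"] + [f"species{i}" for i in range(1, n_species)]
    if len(names) != n_species:
        raise PedmapError("species_names length must equal n_species")
    out = {names[0]: "".join(ref)}
    for name in names[1:]:
        seq = ref.copy()
        mutate = (rng.random(reference_length) < divergence) & ~cons
        for i in np.flatnonzero(mutate):
            choices = letters[letters != seq[i]]
            seq[i] = choices[rng.integers(0, len(choices))]
        out[name] = "".join(seq)
    return out


# ---------------------------------------------------------------------------
# The study-family simulator: three generations, affected sib-pair.
# ---------------------------------------------------------------------------

STUDY_FAMILY_IDS = ("PGF", "PGM", "DAM", "SIRE", "KID1", "KID2", "KID3")


def study_family_pedigree(phenotypes: dict[str, str] | None = None) -> Pedigree:
    """Seven-member nuclear family: paternal grandparents, sire, dam
    (founder), an affected sib-pair and their healthy littermate."""
    ph = phenotypes or {}

    def p(iid: str, default: str = "unaffected") -> str:
        return ph.get(iid, default)

    return Pedigree(
        [
            Individual("PGF", sex="male", phenotype=p("PGF")),
            Individual("PGM", sex="female", phenotype=p("PGM"),
                       declared_status="declared_carrier"),
            Individual("DAM", sex="female", phenotype=p("DAM")),
            Individual("SIRE", sire="PGF", dam="PGM", sex="male", phenotype=p("SIRE")),
            Individual("KID1", sire="SIRE", dam="DAM", sex="male", phenotype=p("KID1", "affected")),
            Individual("KID2", sire="SIRE", dam="DAM", sex="female", phenotype=p("KID2", "affected")),
            Individual("KID3", sire="SIRE", dam="DAM", sex="male", phenotype=p("KID3")),
        ]
    )


@dataclass
class FamilySimulation:
    pedigree: Pedigree
    genotypes: GenotypeMatrix          # after missingness
    complete_genotypes: GenotypeMatrix  # before missingness
    truth: dict[str, TruthRecord]
    hap_labels: list[str]
    causal_marker_index: int
    config: SimulationConfig


def _conditioned_meiosis(
    origins: np.ndarray,
    r: np.ndarray,
    rng: np.random.Generator,
    causal_idx: int,
    require_mutant: bool | None,
    mutant: set[int],
) -> np.ndarray:
    """Rejection-sample a gamete whose causal-locus origin is (not) mutant.

    Conditioning by per-gamete rejection yields the exact conditional
    recombination process given the observed phenotype pattern.
    """
    for _ in range(10_000):
        g = _meiosis(origins, r, rng)
        carries = int(g[causal_idx]) in mutant
        if require_mutant is None or carries == require_mutant:
            return g
    raise PedmapError("conditioned meiosis failed to satisfy constraint")


def simulate_study_family(
    config: SimulationConfig | None = None,
    seed: int | np.random.Generator | None = None,
    marker_map: MarkerMap | None = None,
) -> FamilySimulation:
    """Simulate the mapping family conditioned on its phenotype pattern.

    KID1 and KID2 are affected (homozygous by descent for the founder
    mutation carried by PGM and DAM), KID3 is an unaffected littermate,
    SIRE is an obligate carrier. The mutant haplotypes of PGM and DAM share
    an identical-by-descent ancestral segment around the causal locus.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed) \
        if not isinstance(seed, np.random.Generator) else seed
    mm = marker_map or simulate_marker_map(config, rng)
    freqs = uniform_founder_freqs(mm, rng, config.freq_low, config.freq_high)
    haps = simulate_founder_haplotypes(mm, freqs, 3, rng)
    founder_haps = {"PGF": haps[0], "PGM": haps[1], "DAM": haps[2]}

    causal_idx = mm.nearest_marker(config.causal_chrom, config.causal_bp)
    # founder-effect IBD: mutant haplotypes identical around the causal locus
    half = config.ancestral_segment_mb * 1e6 / 2.0
    tab = mm.table
    seg = (
        (tab["chrom"] == config.causal_chrom)
        & (tab["pos"] >= config.causal_bp - half)
        & (tab["pos"] <= config.causal_bp + half)
    ).to_numpy()
    founder_haps["DAM"][0, seg] = founder_haps["PGM"][0, seg]

    founder_ids = ["PGF", "PGM", "DAM"]
    hap_labels = [f"{fid}.{h}" for fid in founder_ids for h in (0, 1)]
    hap_alleles = np.vstack([founder_haps[f].reshape(2, len(mm)) for f in founder_ids])
    mutant = {hap_labels.index(f"{fid}.0") for fid in config.carrier_founders}
    r = _crossover_probs(mm, config.recomb_rate_cm_per_mb)
    n = len(mm)

    def founder_origins(fid: str) -> np.ndarray:
        base = 2 * founder_ids.index(fid)
        return np.stack([np.full(n, base, dtype=np.int32), np.full(n, base + 1, dtype=np.int32)])

    origins = {f: founder_origins(f) for f in founder_ids}
    # SIRE: obligate carrier -> maternal gamete carries PGM's mutant strand
    sire_pat = _meiosis(origins["PGF"], r, rng)
    sire_mat = _conditioned_meiosis(origins["PGM"], r, rng, causal_idx, True, mutant)
    origins["SIRE"] = np.stack([sire_pat, sire_mat])
    # affected kids: mutant from both parents; littermate: not both
    for kid, affected in (("KID1", True), ("KID2", True), ("KID3", False)):
        if affected:
            pat = _conditioned_meiosis(origins["SIRE"], r, rng, causal_idx, True, mutant)
            mat = _conditioned_meiosis(origins["DAM"], r, rng, causal_idx, True, mutant)
        else:
            while True:
                pat = _meiosis(origins["SIRE"], r, rng)
                mat = _meiosis(origins["DAM"], r, rng)
                both = int(pat[causal_idx]) in mutant and int(mat[causal_idx]) in mutant
                if not both:
                    break
        origins[kid] = np.stack([pat, mat])

    ids = list(STUDY_FAMILY_IDS)
    calls = np.vstack([_origins_to_calls(origins[i], hap_alleles) for i in ids])
    complete = GenotypeMatrix(ids, mm, calls)
    observed = apply_missingness(complete, config.missing_rate, rng)
    truth = {i: TruthRecord(i, origins[i]) for i in ids}
    for iid, rec in truth.items():
        hits = sum(int(rec.origins[s, causal_idx]) in mutant for s in (0, 1))
        rec.carrier_status = {0: "noncarrier", 1: "carrier", 2: "hom_mut"}[hits]
    phenotypes = {i: ("affected" if truth[i].carrier_status == "hom_mut" else "unaffected")
                  for i in ids}
    return FamilySimulation(
        pedigree=study_family_pedigree(phenotypes),
        genotypes=observed,
        complete_genotypes=complete,
        truth=truth,
        hap_labels=hap_labels,
        causal_marker_index=causal_idx,
        config=config,
    )
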