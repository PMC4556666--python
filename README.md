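# pedmap

Disease-gene mapping for very small pedigrees: SNP-based shared-homozygosity
mapping with relative-consistency filtering, autosomal-recessive (AR)
segregation checking, carrier-frequency estimation with exact confidence
intervals, and protein-level variant-consequence / conservation analysis.

The package is aimed at the study design where a genome-wide association
study is impossible because only one or two affected animals exist — the
classic situation in companion-animal genetics (an affected sib-pair of
Sphynx cats with a congenital myasthenic syndrome is the motivating case,
where the causal gene is *COLQ*, the collagen-like tail subunit that anchors
acetylcholinesterase at the neuromuscular junction). Every analysis stage is
paired with a forward gene-dropping simulator, so the whole pipeline is
testable end to end without any external data.

## What it computes

**Shared-homozygosity scan.** A marker is *shared-homozygous* when every
affected individual is homozygous for the same allele. Maximal runs of such
markers (missing calls are neutral, but a run cannot begin or end on one,
and a missing stretch longer than `max_missing_run` breaks it) with at least
`min_markers` shared markers become candidate segments.

**Relative-consistency filter.** Under AR inheritance, an obligate or
declared carrier must carry the shared allele across a true disease segment
without being homozygous for the whole signature, and an unaffected relative
must not be homozygous for the signature (either would make them affected).
Segments violating any rule are excluded; the survivors are the candidate
regions. Region spans are reported as `end − start` bp and Mb.

**Segregation concordance.** Each genotyped individual gets an expectation
class — affected → hom-alt, obligate/declared carrier → het, other
unaffected → not hom-alt (parents of affecteds are auto-promoted to obligate
carriers) — and concordance is the percentage of typed individuals whose
genotype matches.

**Carrier frequency.** Heterozygote percentage in a healthy panel with a
Clopper–Pearson exact 95% CI, per breed and in total.

**Conservation.** `c.`→`p.` mapping of a CDS substitution via the standard
genetic code, pairwise percent identity (native global alignment, match 1 /
mismatch 0, affine gaps, full-alignment-length denominator by default), and
a conserved-column scan that reports, in reference residue numbering, the
alignment columns where all species hold a residue class such as cysteine.

**Simulator.** Founder haplotypes drawn from per-marker allele frequencies
(Uniform(0.2, 0.8) by default, mimicking array ascertainment) are dropped
through the pedigree with Haldane-model recombination at 1 cM/Mb on an
18-autosome cat-like karyotype (~61,705 markers by default). A recessive
mutation is implanted on chosen founder haplotypes, which share an
identical-by-descent ancestral segment around the locus (founder effect);
phenotypes follow descent exactly and ground truth is recorded per
individual.

## Worked example

```
$ pedmap make-fixtures --out-dir fx --seed 1
$ pedmap carriers --variants fx/sphynx_subpanel.tsv
          panel  n_hom_ref  n_het  n_hom_alt  n_total  carrier_pct  ci95_low_pct  ci95_high_pct
sphynx_subpanel         78      3          0       81          3.7      0.770404      10.444371
```

3 of 81 healthy control Sphynx are heterozygous carriers: 3.7%, exact 95%
CI 0.77–10.44%. Mapping the variant onto the coding sequence:

```
$ pedmap map-variant --cds fx/cds.fasta --pos 1190 --ref G --alt A
{ "hgvs_c": "c.1190G>A", "hgvs_p": "p.C397Y", "codon_index": 397,
  "codon_offset": 2, "ref_codon": "TGC", "alt_codon": "TAC", "synonymous": false }
```

The G>A change hits the second base of codon 397 (TGC→TAC), replacing a
cysteine with tyrosine. An end-to-end run (simulate a 61,705-marker family,
scan, filter, plus the segregation and carrier stages on the bundled tables):

```
$ printf 'seed=1\nout_dir=run\nstages=simulate,map,segregate,carriers\nsim_n_markers=61705\npedigree_table=fx/table1_pedigree.tsv\nvariants=fx/table1_variants.tsv\npanel=fx/sphynx_subpanel.tsv\n' > demo.cfg
$ pedmap run --config demo.cfg
...
$ grep consistent run/regions.tsv
C2	138197703	140062646	1864943	1.9	44	consistent
```

The scan recovers a single consistent region on chromosome C2 (1.9 Mb,
44 markers) containing the implanted causal locus; the segregation stage
reports 100.0% concordance over the 27 typed individuals of the bundled
family table.

## Acceptance script

`scripts/acceptance.py` recomputes the two headline quantities from scratch
by running the package on its bundled input tables: the AR segregation
concordance over the 27-cat validation cohort, and the protein residue
index (with the amino-acid change) of the c.1190G>A substitution.

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `pedmap.model` — pedigree, marker map, genotype matrix, variant tables
- `pedmap.sim` — gene-dropping simulator, panels, ortholog sets
- `pedmap.io` — PLINK text, FAM-style TSV, variant TSV / minimal VCF, FASTA
- `pedmap.homozygosity` — scan, consistency filter, region/gene reports
- `pedmap.segregation` — AR compatibility, concordance, carrier statistics
- `pedmap.conservation` — codon mapping, percent identity, conserved columns
- `pedmap.pipeline` / `pedmap.cli` — orchestration, config, `pedmap` CLI
- `docs/methods.md` — model assumptions, parameter defaults, limitations
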