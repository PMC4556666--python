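# Methods

## The mapping model

With a single affected sib-pair, association testing is underpowered, but a
recessive mutation recently introduced by a founder makes both affecteds
homozygous for the *same haplotype* around the locus. The mapper therefore
looks for runs where all affecteds are homozygous for the same allele at
every informative marker, then removes runs contradicted by relatives:

- **Carrier rule** (obligate carriers — unaffected parents of affecteds —
  and declared carriers such as an inferred-heterozygous grandparent): the
  individual must carry the shared allele at every non-missing signature
  marker (a configurable `tolerance`, default 0, forgives isolated
  violations from genotyping error), and must not be homozygous for the
  signature at every non-missing marker of the segment — that genotype would
  make them affected.
- **Unaffected-relative rule**: only the whole-segment signature
  homozygosity check applies. Lacking the allele locally is fine — an
  unaffected sib may carry zero, one, or (outside the disease segment) two
  signature alleles.

Carrier status is deliberately formalised through these two checks rather
than strict per-marker heterozygosity: array markers are not all
informative, so a carrier parent is routinely homozygous at individual
markers inside a true disease segment.

### Numerical and boundary choices

- Missing calls are neutral: they neither extend nor break a run, but a run
  cannot begin or end on one. A stretch of more than `max_missing_run`
  (default 5) consecutive missing calls in any affected breaks the run,
  since an arbitrarily long gap could hide a heterozygous block.
- `min_markers` (default 20) counts *shared* markers in a run, not its bp
  extent. Runs that individually pass the size filter and sit closer than
  `merge_gap_bp` (default 1 Mb) on one chromosome are merged when the
  homozygous allele class at the facing run ends agrees (the run signature
  is per-marker, so "identical flanking signatures" is interpreted at the
  two facing boundary markers).
- Region span is `end − start` (difference of boundary marker positions,
  not marker count intervals); Mb values are rounded half-up to one
  decimal. Sorting is by (chromosome label, start bp); chromosomes never
  merge.
- The scan is linear-time per chromosome and is verified in the test suite
  against an exhaustive window-enumeration oracle on matrices up to
  30 × 1,000.

## Segregation and carrier statistics

Expectation classes are a pure function of phenotype and carrier
annotation; unaffected parents of an affected are auto-promoted to obligate
carriers, which is the informative part of the check — a hom-ref parent of
an affected falsifies the candidate variant. Individuals with missing
genotypes are "untyped" and excluded from the concordance denominator.
Percentages are rounded half-up to one decimal.

Carrier confidence intervals are Clopper–Pearson (beta-quantile) exact 95%
intervals, chosen for the very small heterozygote counts involved (3/81,
0/14). Note the exact interval is *conservative*: its true coverage at
n = 81, p = 0.037 is P(K ≤ 7) ≈ 98.97%, not 95%. A coverage simulation at
these parameters therefore lands near 99%, above any symmetric ~95% band;
this is a property of the interval, not an implementation artefact.
Mid-p or Wilson intervals would centre coverage near the nominal level but
sacrifice the guaranteed-coverage property; the exact interval is kept.
"First-degree relative" exclusions for subpanel construction are
caller-supplied id lists; the package never infers relatedness.

## Conservation analysis

`map_cdna_variant` uses the standard genetic code only and requires an
in-frame CDS whose base at the stated position matches the stated reference
base; codon index is `(pos + 2) div 3`. Percent identity defaults to the
full alignment length as denominator (terminal and internal gaps included);
because published identity figures rarely state their denominator, the
alternative denominators (`shorter`, `ungapped`) are selectable and the
method metadata (mode, scoring, denominator) is always attached to the
result rather than asserting comparability with any published figure.
Native alignment is global with match 1 / mismatch 0, gap open −2, gap
extend −0.5; multiple alignments must be supplied pre-aligned (progressive
MSA is out of scope). Conserved-column scans report reference-sequence
residue numbering (human numbering for the COLQ use case) and require
gap-free columns.

## The simulator: what it emulates, and what it does not

The generator reproduces the statistical regime the mapper assumes:

- ~61,705 biallelic markers allocated to the 18 cat autosome labels
  proportionally to physical length (per-chromosome array densities are
  not published); positions are uniform within chromosomes.
- Founder allele-1 frequencies per marker ~ Uniform(0.2, 0.8), mimicking
  array ascertainment toward common SNPs.
- Recombination under the Haldane map function at a uniform 1 cM/Mb
  (no published feline genetic map is bundled); independent assortment
  across chromosome boundaries.
- Per-call independent missingness at 4%, keeping per-individual call
  rates above the 95% threshold used for sample inclusion; genotyping
  error is available as a knob but off by default.
- The study family: paternal grandparents, a founder dam, the sire, an
  affected sib-pair and a healthy littermate. The mutation sits on one
  haplotype each of the paternal grandmother and the dam, and those two
  haplotypes share an identical-by-descent ancestral segment (default
  20 Mb) around the locus — without this founder-effect identity the
  affecteds would not be shared-homozygous at the causal locus at all.
  Phenotypes are conditioned on the observed pattern (two affected, one
  unaffected littermate) by per-gamete rejection sampling at the causal
  marker, which yields the exact conditional transmission process.
- Healthy panels: each individual heterozygous with the stated carrier
  fraction, never homozygous-alternate (affected animals do not enter
  control panels).
- Ortholog sets: a reference protein plus diverged copies with pinned
  conserved residues; in exclusive mode (default) the conserved residue
  letter never occurs outside the pinned positions, so a conserved-column
  scan recovers the construction exactly.

Not emulated: linkage disequilibrium among founder haplotypes, coalescent
founder ancestry, marker-level assay failure, X-linked inheritance, and
assembly-version coordinate discrepancies. A green recovery test therefore
establishes that the scan/filter machinery finds a founder-IBD recessive
locus under clean array-like data — not that it is robust to LD-induced
chance homozygosity runs, which real arrays exhibit and which the
`min_markers` threshold exists to suppress.

## Parameter-recovery behaviour

At the default settings (200 simulated families, full marker density,
4% missingness, `min_markers=20`), the implanted locus falls inside a
consistent region in ~100% of replicates and the median number of
consistent regions is 1. The simulated count of shared segments is lower
than a manual-inspection analysis of real array data would produce,
because simulated founder haplotypes carry no LD; the relative-consistency
filter behaves identically either way (it only removes segments).

## Pipeline plumbing

One global seed fans out to per-stage seeds by SHA-256 of
`"{seed}:{stage}"` (kept below 2³¹), so stages rerun in isolation
reproducibly. Config files are flat `key=value` text with unknown keys
rejected; every TSV output names the config hash in its header, and the
manifest records input checksums, making identical reruns byte-comparable.
Logs go to stderr; machine outputs never mix with logs.
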