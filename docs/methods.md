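# Methods

guenonflow implements the statistical chain used in comparative
genomic studies of closely related primate lineages: genotype-level
filtering, genome-wide and windowed introgression statistics, runs of
homozygosity (ROH), derived-allele mutation load, convergent
amino-acid detection, and gene-set overlap tests — together with
coalescent generators that produce every input with known truth. This
note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Data model and filters

Genotypes are biallelic diploid dosages (0/1/2, or missing) in a
samples × sites matrix; indels and multiallelic records are excluded
at parse time because none of the downstream statistics is defined on
them. VCF positions stay 1-based; all interval work (genes, windows,
ROH segments) is 0-based half-open, with conversions confined to the
readers.

Two masks run before any statistic:

* **Depth mask.** A genotype is set to missing when its site depth is
  below half or above twice the sample's mean autosomal depth (an
  optional X-specific mean applies on X-named chromosomes). Bounds are
  exclusive: depth exactly at 0.5× or 2× is retained. Site depths are
  taken from FORMAT/DP as given, not recomputed from alignments.
* **Allele-balance mask.** A heterozygous call is set to missing when
  min(ref, alt)/(ref+alt) < 0.25; homozygous calls are never touched,
  and a het with zero informative reads is masked and tallied.

Both masks are idempotent and only ever remove genotypes — properties
the suite tests directly.

## Four-taxon introgression statistics

For populations P1, P2 (sister lineages), P3 (candidate donor) and an
outgroup, a site is usable when every role has at least one called
genotype and the outgroup is monomorphic; the outgroup allele is taken
as ancestral. With derived-allele frequencies p1..p4 the
frequency-weighted pattern sums are

    ABBA = Σ (1−p1)·p2·p3·(1−p4),   BABA = Σ p1·(1−p2)·p3·(1−p4)

and D = (ABBA−BABA)/(ABBA+BABA). Sites with a polymorphic outgroup
are skipped rather than polarized by majority — a deliberate,
conservative choice that loses a small fraction of sites but never
mispolarizes. With a single diploid sample per role, frequencies are
dosage/2 (no pseudohaploid draws).

**Uncertainty** comes from a weighted delete-one-block jackknife
(Busing-style delete-m_j), with contiguous genomic blocks weighted by
their usable-site counts and Z = D/SE. The library default block size
is 1 Mb; the replicate studies on 5-Mb simulated chromosomes use
250-kb blocks so that ~20 blocks support the SE — with 5 blocks the
variance of the variance estimate itself makes Z unstable. Blocks
remain two orders of magnitude larger than the simulated LD scale.

**f_dM** is computed in non-overlapping tiled windows (default 10 kb).
The numerator is the windowed ABBA−BABA sum; the denominator is the
same sum with the *dynamic donor* substitution: at sites with p2 ≥ p1,
P2 and P3 are both replaced by PD = max(p2, p3); at sites with
p1 > p2, P1 and P3 are replaced by PD = max(p1, p3) and the term
enters negatively. This symmetric form is bounded in [−1, 1], matches
the D statistic's sign on single-site windows, and treats excess
sharing with P1 and P2 even-handedly. Windows with fewer than
`min_snps` usable sites (default 100) or a zero denominator are
dropped. Outlier windows are those at or above the linear-interpolation
empirical percentile (default 99th), ties included.

`min_snps = 100` per 10-kb window reflects deep multi-species panels;
simulated panels at μ = 1e-8 carry ~10–25 usable SNPs per 10-kb
window, so the simulation analyses use `min_snps = 10` (or raise μ,
below) — matched to SNP density, not to outcomes.

## Runs of homozygosity

The caller reproduces the classic scanning-window parameterization:
windows of 50 consecutive SNPs (after removing missing genotypes, so
missing calls cannot break a run) are homozygous-compatible when they
contain ≤ 1 het; a SNP is a *hit* when ≥ 5% of its overlapping windows
are compatible. Maximal hit runs are split at inter-SNP gaps > 1 Mb
and emitted when they simultaneously satisfy: length ≥ 100 kb,
≥ 100 SNPs, and ≤ 50 kb per SNP. Segment endpoints are the first and
last SNP of the run (SNP-delimited); published scanning-window
implementations under-document their edge trimming, so this
SNP-delimited variant is declared the reference behaviour here and
pinned by fixtures.

The **accessible genome** per sample is the total ROH length callable
after converting every het to a homozygote — the denominator for ROH
fractions, which makes a fully homozygous genome exactly fraction 1.
Fractions are reported separately for short (100 kb–1 Mb, both bounds
inclusive) and long (> 1 Mb) ROH, old versus recent inbreeding
respectively.

## Heterozygosity and load

Heterozygosity is n_het/n_called per sample over the supplied site
list; absolute values therefore depend on whether invariant sites are
present, and only relative/structural behaviour is claimed. Load is
counted in alleles (a hom-derived genotype contributes 2): for each
impact category, the derived-allele total divided by the synonymous
derived-allele total. The ratio form cancels per-sample callability
when callability is category-independent; whether that held upstream
of a real impact table cannot be checked here. Sites whose derived
allele is not the allele the impact table categorizes contribute
nothing.

## Convergent amino-acid detection

Per-gene codon alignments are translated codon-wise ('---' → gap, any
N/partial gap → X, terminal stop tolerated). A sequence is excluded
for an internal stop or > 50% missing residues; a gene is dropped when
more than half the samples of either focal group were excluded. A
column is convergent when all non-missing residues of both focal
groups equal one amino acid that appears in no non-missing background
residue. Fixation is evaluated over non-missing residues only:
requiring complete data would discard columns the missingness filters
deliberately kept. The background is required only to *lack* the
focal state, not to be monomorphic ("private", not "background-fixed")
— the stricter reading would only shrink the call set.

## Synthetic data: what it emulates, what it does not

* `simulate_snp_data` — msprime coalescent-with-recombination under
  ((P1,P2),P3),OUT with one optional pulse. Defaults (2 diploids per
  population, Ne = 10,000 per branch, splits at 10/40/100 kgen,
  μ = r = 1e-8, pulse 5 kgen ago) are desk-scale fixture choices: a
  5-Mb replicate simulates in ~1 s while giving ~20 jackknife blocks
  and clear D behaviour at f = 0.1. The reference allele is the
  ancestral state, so alt dosage equals derived dosage by construction.
* The **landscape scenario** (five populations, two sister recipients)
  places the shared pulse 30 kgen ago against a recipient split 5 kgen
  ago — 2.5 Ne generations of shared sorting, so introgressed tracts
  fix or are lost in the common ancestor and both recipients inherit
  the same mosaic, which is what makes real recipient lineages of one
  ancient pulse show near-identical landscapes. μ is raised to 5e-8 so
  10-kb windows reach the ≥ 100-SNP retained regime. The contrast
  scenario delivers the same fraction independently into each
  recipient 2.5 kgen ago.
* `simulate_roh_genome` plants autozygous tracts directly (homozygous
  SNPs inside, het probability 0.3 outside at 1 SNP/500 bp) rather
  than simulating inbreeding loops; it controls tract boundaries
  exactly, which the recovery scoring needs.
* `simulate_impact_table` assigns categories independently per site at
  fixed rates; real impact classes cluster in genes and covary with
  conservation, so tests show bookkeeping correctness, not robustness
  to annotation structure.
* `simulate_codon_alignments` plants convergent columns and optional
  filter-triggering defects on an otherwise identical background; it
  contains no phylogenetic substitution process, so detection tests
  exercise the predicate and filters, not homoplasy rates under real
  divergence.

None of the generators models selection, recombination-rate
variation, genotyping error (beyond the optional ROH error-het rate),
or reference bias; passing tests show the estimators are correct on
their defined inputs, not that real-data complications are handled.

## Numerical and degenerate-case choices

* D with ABBA+BABA = 0 is NaN (signalled, not raised); jackknife SE of
  0 with D ≠ 0 yields ±inf Z.
* Blocks/windows with no usable sites are dropped before
  jackknifing/correlation; landscape correlation uses only windows
  retained in both landscapes and requires ≥ 3.
* Fisher's exact test is two-sided by minimum-likelihood summation
  (the classical convention; doubling the one-sided p would change
  results), delegated to scipy and cross-checked against full
  hypergeometric enumeration in the suite. Odds-ratio zero cells give
  inf/NaN and are flagged.
* The outlier threshold uses numpy's linear-interpolation quantile
  with a ≥ comparison, so ties at the threshold are all included.
* Gene records sharing an id in GFF3 collapse to their union span;
  strand '.' records are rejected (strand is needed for upstream
  arithmetic). Upstream regions are exactly `upstream_bp` long,
  clipped at 0, half-open.

## Replicate-study problem sizes

The packaged studies run 20 replicates of 5-Mb chromosomes for D
calibration/power, one 10-Mb chromosome per landscape scenario, and a
12-Mb chromosome with three planted tracts (0.3/1/3 Mb) for ROH
recovery. These sizes give stable pass/fail behaviour across seeds
while the whole battery completes in a few minutes on one CPU.

## Known limitations

* The ROH scanner is a reimplementation of the scanning-window idea
  with declared semantics, not a bit-compatible clone of any released
  tool.
* Outgroup polarization ignores recurrent/back mutation at deep
  timescales; a small fraction of sites is mispolarized in principle,
  identically for all statistics sharing the convention.
* The pipeline's `filters` stage applies masks only when DP/AD are
  present in the input VCF; it does not impute or recalibrate.
* Window tiling starts at coordinate 0 per chromosome; there is no
  reference-guided tiling or masking of assembly gaps.
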