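# Methods

`igklocus` genotypes a two-segmental-duplication immunoglobulin locus
from phased haplotype assemblies and reproduces the population-level
analyses such data support: germline allele inference, diploid SNV
genotyping with windowed density statistics, structural-variant and
gene-conversion genotyping, and inter-population allele-frequency
tests. This note records the models, the defaults and why, and what
the synthetic data do and do not establish.

## The locus model

The immunoglobulin kappa (IGK) locus consists of two large inverted
segmental duplications — a proximal and a distal region — whose V
genes pair as paralogs; distal gene names carry a `D` infix
(`IGKV1-13` / `IGKV1D-13`). The model is data-driven: a BED-like TSV
declares region bounds, per-gene features (L-Part1 leader, intron,
coding exon, recombination signal sequence), strand, functional class,
structural-variant definitions and the gene-conversion acceptor
window. Paralog pairs may be declared explicitly; otherwise the `D`
infix naming rule is applied, restricted to genes actually present.
Coordinates are 0-based half-open everywhere; the single conversion to
1-based happens at VCF emission. Features of minus-strand genes are
reverse-complemented before any exon or codon logic.

Analyses run against a *custom reference*: the base assembly with the
locus's common insertion SV spliced in and the unassembled inter-region
gap N-masked. `build_custom_reference` applies edits in descending
coordinate order (so the result is independent of listing order) and
returns an edit ledger supporting exact liftover in both directions;
positions inside replaced spans or spliced-in payload map to
`deleted`. Working on an SV-inclusive reference turns presence/absence
of the insertion into a coverage question rather than a breakpoint
question.

## The synthetic cohort generator

The generator emulates the study design this kind of pipeline is built
for: an ancestrally diverse cohort of 36 diploid samples (AFR 8, EAS
7, SAS 10, EUR 10, AMR 1), each contributing two phased haplotypes of
the full locus. Per haplotype, in order:

1. **Germline alleles.** One allele per gene is drawn from
   population-specific frequency vectors (explicit in the
   configuration, or Dirichlet(1) draws from a dedicated seed
   substream) and written into the sequence as exon substitutions.
   The synthetic germline database assigns `*01` to the reference
   exon of every gene; other alleles differ by 1–8 substitutions,
   matching the nearest-match distance range reported for novel
   alleles in capture-based surveys of this locus.
2. **Gene conversion.** With a per-population probability, the distal
   acceptor window (~3 Kbp in the desk-scale fixture, standing in for
   the ~16 Kbp tract observed at IGKV1D-12/13) is overwritten with the
   proximal donor sequence. Paralog-divergent positions inside the
   window then surface as apparent SNVs against the distal reference —
   exactly the elevated-density signature that marks conversion
   haplotypes in real data. Genes whose exon lies inside the window
   are "conversion-coupled": their allele is determined by the
   conversion state (`*02` = the donor exon on converted haplotypes),
   mirroring the perfect association observed between the conversion
   and the alleles of the genes it covers.
3. **Insertion SV.** With a per-population *deletion* frequency
   (defaults: AFR 0.50, EAS 0.786, SAS 0.90, EUR 0.85 — the published
   per-population frequencies of the deletion allele), the payload and
   its carried gene are removed; the truth ledger marks the gene
   `deleted`.
4. **Inversion.** With low probability (default 0.014 ≈ one haplotype
   in 72), the span between the midpoints of the two paralog anchor
   genes is reverse-complemented. Anchors are gene midpoints because
   real breakpoints are localized only to genes by breakpoint-spanning
   reads.
5. **Scattered SNVs.** Substitutions are placed as a Poisson process
   with per-region densities (defaults 5×10⁻⁴/bp proximal,
   1×10⁻³/bp distal per haplotype — reproducing the distal > proximal
   contrast) and per-feature multipliers (V-exon 2.0, L-Part1 2.0,
   intron 1.5, RSS 1.0; enrichment is reported qualitatively in the
   source data without printed values, so these are configuration, not
   claims). Positions already edited, deleted or N-masked are skipped.
   Only substitutions are planted — the variant analyses downstream
   are SNV-only.

The truth ledger records, per haplotype, the *effective* allele per
gene (a scattered SNV hitting an exon legitimately turns the drawn
allele into a novel one; the ledger stores the resulting sequence),
every position at which the haplotype differs from the reference, and
the SV/conversion/inversion states. Truth alignments are emitted as
PAF records with `=`/`X`/`D` CIGARs, split into orientation-flipped
records around a planted inversion.

Determinism: one global seed; each haplotype's random stream is
derived from (seed, haplotype counter), so a cohort is byte-identical
across runs and stable under resizing. The desk-scale reference itself
is generated from a fixed internal seed and is the same object in
every installation.

Long reads are simulated per haplotype with normal fragment lengths
(default mean 10 Kbp, HiFi-like), uniform starts, i.i.d. substitution
errors (default 10⁻³/base) and configurable fold coverage (default
30×), with truth alignments to the haplotype.

**What the generator does not model:** linkage between scattered SNVs
(each haplotype's background is private, so frequency filters strip
them — see below), capture-probe bias, chimeric reads, read indels,
assembly errors, and the lymphoblastoid V(D)J-rearrangement artifact
(modelled only as an optional mask that yields `unresolved` calls).
Passing recovery tests therefore demonstrates correctness of the
genotyping logic on clean phased assemblies, not robustness to
assembly error.

## SNV genotyping

Variants are read directly off assembly-to-reference alignments: every
mismatch column inside the analysis regions is a call (assemblies are
consensus sequences; there is no base-quality model). Indel columns
yield no SNV. Region positions covered by no aligned base — including
spans deleted in the haplotype — form an explicit per-haplotype
missing set, so a haplotype lacking the SV payload contributes
*missing*, not reference, at payload sites. Overlapping records of one
haplotype that disagree on a base mark the position
assembly-inconsistent and excluded from allele counts (a deterministic
stand-in for manual curation of unsupported variants).

Per-haplotype calls merge into a biallelic site × haplotype matrix
(multiallelic positions become multiple rows); AC and AN are derived
from the matrix, never stored. The frequency filter retains sites with
AC > 1 and reports the implied MAF floor, (AC_min+1)/AN_max × 100 —
2.86% for 35 fully-called diploid samples (70 haplotypes). Whether the
denominator counts 35 or 36 samples is the caller's choice of cohort;
the function takes the haplotype complement as given. VCF 4.2 output
is biallelic, 1-based, phased (`0|1`; `.` for a missing haplotype),
with INFO keys AC, AN and FEAT, and round-trips losslessly.

## Allele calling

The coding exon of each gene is lifted out of the alignment (indels
preserved, strand-normalized), then matched against the germline
database: an exact match takes the database label; otherwise the call
is novel, labelled `GENE_N<k>` with k ordered by cohort observation
count then sequence (deterministic), and reported with the nearest
known allele by edit distance (substitutions and indels each weigh 1;
an indel-bearing novel is flagged). Equidistant nearest matches break
to the lexicographically first label with a tie flag. Coding
consequence vs the nearest allele: net length change not divisible by
3 → frameshift; otherwise codon-wise translation comparison →
nonsynonymous or synonymous_only; codons containing N are skipped and
flagged. The reading frame is frame-0 from the exon start after strand
normalization (configurable offset).

A gene whose exon footprint has no aligned bases is `deleted`; a
footprint truncated at a contig end or overlapping a declared mask is
`unresolved`. Heterozygosity per gene counts a sample heterozygous iff
its two haplotype labels/states differ, with `deleted` as a distinct
allele state; samples with an unresolved haplotype leave that gene's
denominator (counting them either way would bias the estimate).

Read support for an allele counts reads fully spanning the exon
footprint on the *haplotype* (personalized reference), and the subset
spanning with zero mismatches/indels inside the footprint. Assembly
accuracy is (diploid length − positions where > 25% of covering reads
mismatch) / diploid length × 100; zero-coverage positions are not
flaggable but stay in the denominator and are reported.

## Structural genotyping

* **Insertion SV**: present iff ≥ 0.9 of the payload footprint is
  covered by aligned bases; deleted iff ≤ 0.1 is covered *and* both
  500 bp flanks are aligned (absence must be observed, not missing);
  otherwise no-call.
* **Gene conversion**: the haplotype's acceptor-window sequence is
  compared to the proximal donor (identity I_p) and the distal
  reference (I_d); converted iff I_p − I_d > 0.002, reference iff
  I_d − I_p > 0.002, else no-call. Identity comparison was chosen over
  the SNV-density signature because it is symmetric in the reference
  used; the density route remains available downstream as a
  cross-check. The 0.002 margin sits well below the ~1% donor–acceptor
  divergence and above the default scattered-SNV density, giving exact
  genotypes whenever within-window SNV density stays below half the
  paralog divergence.
* **Inversions**: a contig aligning in ≥ 2 records of opposite
  orientation yields a call at the facing ends of the minority-
  orientation segment; calls within 100 bp pool, and evidence counts
  supporting contigs. Single-orientation alignments yield an empty
  list, not an error.

## Population statistics

SNV density over an interval is Σ(alternate-allele dosage) /
(2 × length) per sample; tracks tile a region half-open in 10 Kbp
windows (final partial window normalized by true length). The
proximal-vs-distal contrast is the per-sample difference of window
means (distal − proximal, so positive = distal denser) with a
two-sided paired Wilcoxon signed-rank p (exact for n ≤ 25 without
ties, normal approximation with tie correction otherwise; all-zero
differences return p = 1 with a degenerate flag). In the end-to-end
summary, density uses the *unfiltered* matrix: the generator's
scattered SNVs are private to haplotypes, so an AC > 1 filter removes
exactly the variation the statistic measures — a deliberate divergence
from a real-data workflow, where ancestry makes variants shared.

Allele-frequency skew is tested per gene on the population × allele
haplotype-count table (deleted is an allele category; unresolved
haplotypes are dropped) with a chi-square without continuity
correction or expected-count guards — the tables are small by design,
so the minimum expected count is reported for the user to judge —
followed by Benjamini–Hochberg adjustment across all testable genes in
the run (single-allele genes are untestable and excluded from the
family). Two-group contrasts (AFR vs pooled non-AFR; whether the
single AMR sample joins the pool is the caller's grouping choice) use
the two-sided Fisher's exact test; zero margins return p = 1 flagged.

PCA uses allele-frequency-scaled dosages ((d − 2p)/√(p(1−p)),
missing imputed at the site mean, monomorphic sites dropped),
eigendecomposition of the sample covariance, and a sign convention
making each eigenvector's largest-magnitude loading positive. IBS
dissimilarity is 1 − mean per-site (2 − |dᵢ − dⱼ|)/2 over jointly
called sites, clustered with average linkage; samples are processed in
sorted label order so ties resolve deterministically.

## Numerical and design choices

* Edit distances via edlib; translations via Biopython; chi-square,
  Fisher, Wilcoxon and hierarchical clustering via scipy; BH via
  statsmodels. Each of these is verified in the test suite against an
  independent hand-rolled oracle (textbook chi-square formula, step-up
  BH, hypergeometric enumeration, sign-flip enumeration, brute-force
  IBS).
* Desk-scale fixture: two 50 Kbp regions, six genes each, 2 Kbp
  N-masked gap, 3 Kbp conversion window, 2 Kbp SV payload, ~1%
  paralog divergence, with a miniature 8 Kbp-region variant for
  replicate-heavy statistical tests. These sizes keep a full cohort
  simulation plus genotyping pass under a few seconds while preserving
  every structural feature the pipeline must handle; full-length
  realism adds nothing to correctness testing.
* All thresholds (MAC bound, SV coverage fractions, conversion margin,
  mismatch fraction, window size) are run configuration, logged with
  every CLI invocation.

## Known limitations

Conversion genotyping assumes the two regions are coordinate-aligned
copies over the acceptor window (true of the fixture; real loci would
need a donor alignment step). Inversion detection only finds
orientation flips within a contig — inversions at contig boundaries
are invisible. The novel-allele labelling is cohort-relative: the same
sequence can receive different `_N<k>` labels in different cohorts.
Distances to nearest alleles are computed on the exon only; leader and
RSS variation does not enter allele identity.
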