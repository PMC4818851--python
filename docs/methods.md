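# Methods

## The triangulation model

Evolutionary Triangulation treats differences in phenotype prevalence among
three populations as prior information about where risk alleles sit. A
design names an outlier population A (phenotype common) and a similar pair
B, C (phenotype comparably rare). An allele is *appropriately distributed*
for that design when its frequency is unusual in A relative to both B and C
while B and C agree with each other. Operationally the filter intersects
three empirical F_ST tails: high θ̂(A,B), high θ̂(A,C), low θ̂(B,C).

The filter is a heuristic, not a test: it assumes (i) phenotype prevalence
differences are partly driven by frequency differences at causal loci,
(ii) drift and selection have not produced the same high/high/low pattern
at too many unrelated loci, and (iii) allele frequencies are estimated from
samples large enough that ranking tails is meaningful. Violations (recent
admixture, strongly environmental phenotypes, small samples) degrade it
gracefully into noise — the enrichment test below quantifies whether
anything was gained.

## F_ST estimation

Per SNP and population pair we use the Weir–Cockerham (1984) ANOVA estimator
θ̂ = a/(a+b) in its allele-count (haploid-draw) formulation, since the input
is population allele frequencies with sample sizes in allele copies —
genotype/heterozygote counts, which the diploid variant needs, are not part
of the data model. Properties relied on downstream, all under test:

* allele-label invariance — ref/alt polarity never matters;
* θ̂ = 1 exactly iff a fixed difference; θ̂ = −1/(n−1) at equal sample
  frequencies with equal n (negative estimates are sampling noise around 0);
* undefined (NaN) exactly when the pooled sample is monomorphic; such SNPs
  are excluded from percentile ranking and from ET eligibility.

Negative estimates are **retained** for percentile ranking: the low-tail
criterion for the similar pair lives exactly where clamping would pile mass.
(`percentile_cutoff` callers can clamp upstream if they want the other
convention; nothing in the package does.) Percentiles are nearest-rank
(k = ⌈q/100·N⌉-th smallest defined value) with inclusive comparisons on both
sides, so ties at a cutoff are selected. Cutoffs are computed per pair over
the common universe of SNPs with all three θ̂ defined; SNPs outside that
universe are dropped and counted in the run summary.

## Gene mapping and the region contrast

"Within W of a gene" means the gene interval (1-based inclusive) expanded by
W bases on both sides contains the SNP position, boundaries inclusive;
W defaults to 100 kb with 250 kb as the documented alternate. A gene enters
the ET gene set once regardless of how many ET SNPs support it; per-SNP
distances (0 inside the gene body, else gap to the nearer edge) are kept in
the support table. The two-way-versus-three-way contrast compares the
fraction of selected SNPs falling within a window-widened target region for
the three-way filter against plain upper-tail scans of each single pair at
the same stringency.

## Enrichment by genome resampling

A (gene, phenotype) association qualifies with ≥5 supporting publications or
a GWAS p < 5×10⁻⁸ (strict inequality), and only phenotypes flagged
appropriately distributed — an input judgment, never inferred — count.
Each permutation draws |ET genes| genes uniformly without replacement from
the full annotation universe and counts qualifying genes; the empirical
p-value is the fraction of permutations meeting or exceeding the observed
count. Genes are counted once however many qualifying phenotypes they carry,
so pleiotropy cannot inflate the statistic. p is reported as count/n_perm
(matching the granularity of a 10,000-draw design); a (count+1)/(n_perm+1)
variant sits behind `plus_one=True`. The permutation count distribution is
checked in tests against the exact hypergeometric tail.

One ambiguity in the resampling design is worth recording: "sample the same
number of genes" could mean the ET gene-set size or the size of its
associated subset. The former is implemented — it is the reading under
which the test has a well-defined null and non-trivial p-values.

## Population Branch Statistic

PBS_A = (T_AB + T_AC − T_BC)/2 with T = −log(1−θ̂), computed per SNP.
θ̂ is clamped to [0, 1−10⁻¹²] before the log: branch lengths are lengths,
and the upper clamp keeps fixed differences finite. Top-K selection breaks
ties by (chromosome, position) for reproducibility and logs that a tie
occurred. PBS is the natural baseline: it also uses three populations but
places no prevalence constraint on the third.

## The synthetic testbed

`evotri.simulate` draws, per SNP, an ancestral frequency p uniform on
(0.05, 0.95) and per-population latent frequencies from the Balding–Nichols
Beta(mean p, variance F·p(1−p)) model — F = 0.1 for the outlier, F = 0.01
shared by the similar pair (F = 0 short-circuits to p exactly). Observed
frequencies are binomial draws over n_chrom = 200 allele copies. Signal SNPs
(50 of 20,000 by default) shift the outlier's latent frequency by
delta = 0.4 and force the similar pair to share one latent draw. The shift
is directed away from the nearer frequency boundary: θ̂ is allele-label
invariant, so the sign is immaterial downstream, whereas a fixed upward
shift saturates at the clip for high ancestral frequencies and silently
erases the planted differentiation.

Annotation geometry is chosen for two designed properties. First, the
coordinate axis is genome-scale (3 Gb) with genes tiled every 300 kb
(~10,000 genes), so the ~50 labeled genes are a sub-1% base rate — the
regime the resampling test actually faces on real annotations. Second,
300 kb exceeds gene_length + 2·window (220 kb), so distinct genes' widened
windows are disjoint, every SNP maps to at most one gene, and the gene-level
permutation null is *exact* for generated data. On real annotations genes
cluster within a window and labels arrive in correlated bursts, which makes
gene-level genome resampling mildly anticonservative — a genuine limitation
of the resampling design itself that this testbed deliberately factors out
(and that users of real data should keep in mind).

What the generator does not emulate: linkage disequilibrium (every SNP is
independent), ascertainment, selection dynamics, admixture, or realistic
gene-length/spacing variation. Passing tests therefore demonstrate the
statistical machinery — estimator fidelity, threshold logic, calibration,
recovery of frequency-level signal — not robustness to LD-induced SNP
clustering or annotation structure.

## Test and acceptance problem sizes

The study conditions for end-to-end checks are the generator defaults
(20,000 SNPs, 50 signal SNPs, F = 0.1/0.01, delta = 0.4, n_chrom = 200,
95th/5th thresholds, ±100 kb window). Under these conditions the similar
pair's low-tail filter discriminates equal-latent SNPs from background only
modestly — latent drift spread over binomial noise is
√(F·n_chrom) = √2 ≈ 1.4, so a signal SNP passes the 5th-percentile cut
~9% of the time versus 5% for background — and the expected number of
captured signal SNPs per dataset is ~3. Single-dataset outcomes are
therefore bimodal, and the recovery and contrast checks pool a fixed
ensemble of replicate datasets (seeds 0..R−1; R = 10–12), asserting the
pooled recovery fold (≥5× background), a pooled stratified permutation p
(≤0.01), and the pooled region-proportion contrast. The delta = 0 null is
run as 50 replicates, requiring p ≥ 0.05 in ≥90% of them.

Null calibration of the permutation p is asserted one-sidedly: an empirical
p from a discrete count statistic is super-uniform by construction, so the
check is that the empirical CDF of 200 null p-values never exceeds the
uniform CDF by more than the KS bound (no anti-conservatism), plus a band
on the mean; a two-sided uniformity test would reject for the harmless
discrete direction.

## Numerical and degenerate-input choices

* Sample sizes below 2 allele copies per pair leave θ̂ undefined (no
  within-population information).
* Frequency-table rows with frequencies outside [0,1] or non-positive
  sample sizes are dropped at read time and counted, never repaired.
* BED input is converted to 1-based inclusive coordinates at the boundary;
  zero-length BED intervals are rejected with a diagnostic.
* HapMap-dialect merging keeps only SNPs present in every population,
  harmonizes swapped ref/alt labels by flipping frequencies, discards
  irreconcilable allele pairs, and exposes `drop_monomorphic` as a switch
  (upstream QC conventions vary, so the adapter does not guess).
* All randomness flows from a single top-level seed through named
  `SeedSequence` substreams (CRC32 of the stage name as the spawn key), so
  every stage is independently reproducible and run summaries are
  byte-identical given a seed.
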