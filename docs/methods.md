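# Methods

This note documents the statistical procedures, the synthetic-data model, the
conventions adopted where the problem is genuinely open, and the limitations
of what the validation experiments can show.

## Window statistics

**Fst.** The two-population Weir–Cockerham (1984) estimator with variance
components a (among populations), b (among individuals within populations)
and c (within individuals), computed from per-site sample sizes, allele
frequencies and observed heterozygosity. Individuals with any missing allele
at a site are excluded from that site's sample sizes; a site is defined when
each group retains at least one called diploid and the mean sample size
exceeds 1. Windowed Fst is the ratio of sums Σa / Σ(a+b+c) over the window's
defined sites (the "weighted" windowed convention of vcftools). Monomorphic
sites contribute zero components and are harmless; a window whose denominator
is zero is undefined and excluded from the Z-transform. Negative window
values are retained — clamping at zero would distort the genome-wide null
that the Z-transform estimates.

**Windows.** 20-kb windows sliding in 10-kb steps (defaults; configurable).
Coordinates are 0-based half-open internally; a variant with VCF position
`pos` belongs to window [start, end) iff `pos−1 ∈ [start, end)`. Trailing
partial windows are emitted. Windows with fewer than `min_snps` SNPs
(default 10) are flagged `low_snp` and excluded from the Z-transform but kept
in the output; without this exclusion, near-empty windows produce
noise-driven ZFst outliers.

**ZFst.** (x − mean)/sd with the sample sd (ddof = 1), computed per contrast
over all retained windows genome-wide, not per contig. A degenerate scan
(zero variance) is an error, not a silent zero.

**Tajima's D.** Standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) from the
1989 definitions, with S counted over sites restricted to their called
chromosomes and π as the sum of per-site unbiased heterozygosity
2x(k−x)/(k(k−1)). With missing data the constants need a single n; we use the
floor of the mean per-site called chromosome count. (An alternative — the
minimum per-site count — is more conservative but discards information when a
single badly-covered site is present; with complete data the two coincide,
which is the regime the oracle tests exercise.) D is undefined for S = 0 or
n < 4.

## Region calling and classification

Candidate windows (ZFst strictly > 2 against the local wild group) are merged
when overlapping or book-ended; regions of the two domestic contrasts are
intersected (≥ 1 bp) into common regions whose extent is the intersection.

**Permutation test.** Within each domestic/wild contrast the pooled sample
labels are permuted with group sizes fixed and the region Fst (ratio of sums
over the region's SNPs) recomputed; p = (n+1)/(N+1) with N = 1000 by default.
The region-level rule is `max`: each contrast gets its own empirical p and
the region p is the larger one, so a region passes p < 0.01 only if both
contrasts are individually significant. A `joint` rule (a permutation counts
only when it exceeds the observed value in *both* contrasts simultaneously)
is available but not the default: the count then estimates the product of two
survival probabilities, so under the null p ≈ U₁·U₂ and
P(p < α) = α(1 − ln α) ≈ 5.6% at α = 1% — anti-conservative, and it fails
the calibration experiment below by construction.

**Region summaries.** The spec of a region is its intersection extent; the
ZFst(CHD vs EUD) summary and the region identity scores are computed over the
member windows *fully contained* in that extent (falling back to
overlap-length weighting over all member windows, then to all overlapping
windows). Windows poking outside the extent average flanking background into
the summary and systematically pull unidirectional regions' ZFst toward zero.
The summary statistic is the overlap-weighted mean (configurable to max).

**Classification.** Unidirectional: region ZFst(CHD vs EUD) < −1 and
H12_CHD > H12_CHW and H12_EUD > H12_EUW (all strict). Bidirectional: same H12
filter with ZFst(CHD vs EUD) > 2. Everything else stays common. The H12
region summary is the maximum over scan windows whose center SNP lies in the
region — a sweep produces a peak, and averaging over an arbitrary overlap
would dilute it.

## H12

H12 = (p₁+p₂)² + Σ_{i>2} p_i² over exact-match haplotype classes in 50-SNP
windows advancing by 10 SNPs (window centers at SNP index start+25).
Haplotypes with any missing call in a window are dropped rather than imputed
— imputing the major allele would fabricate haplotype identity exactly where
sweeps make the major haplotype common. Input must be phased; unphased data
raise an error rather than silently degrade. Domestic groups larger than
their wild comparator are subsampled to the wild size 10 times (over
individuals, not haplotypes) and the per-window H12 averaged, removing the
sample-size bias of haplotype-homozygosity statistics.

## Identity scores and the ancient-genome test

Per site and group, the reference-allele frequency is computed over called
alleles, assessed only when the number of fully-called individuals is at
least ⌈group size / 2⌉ — for the single ancient sample this means the site
must be called in it. IS = 1 − |F₁ − F₂| per assessed site, averaged per
window; region IS is the unweighted mean over member windows. For a
unidirectional region, IS(AP,CHD) < IS(AP,EUW) + 0.1 calls
introgression-then-selection, the reverse strict inequality calls
pre-introgression selection, equality exactly at the margin is ambiguous, and
an undefined score (ancient coverage gap) is no_data.

## IBD proxy and nIBD

nIBD = cIBD/tIBD per 20-kb bin, where tIBD = (2n₁)(2n₂) cross-group haplotype
pairs and cIBD counts pairs whose IBD segments span the bin entirely. The
built-in segment caller is a deliberately simple binned identity criterion
(fraction of jointly-called sites identical ≥ 0.99, ≥ 5 shared sites per
bin, adjacent IBD bins concatenated); it is not an HMM and is not equivalent
to Beagle's fastIBD — externally produced segment files can be supplied
instead and are the recommended input for real data.

## Synthetic cohorts

The generator is a founder-haplotype pool model, not a coalescent. Each 20-kb
block carries K = 8 founder haplotypes with i.i.d. Bernoulli(½) alleles;
ancestral founder frequencies are Dirichlet(3) (an even-but-not-uniform wild
spectrum, so implanted sweeps have consistent effect sizes); frequencies
drift along the tree ancestor → {CHW, EUW} → {CHD, EUD} via the Dirichlet
analogue of Balding–Nichols: child ~ Dirichlet(parent·(1−θ)/θ). Defaults
θ_wild = 0.2 per wild branch (giving CHW-vs-EUW Fst ≈ 0.3–0.4, the observed
divergence between Chinese and European wild boar) and θ_dom = 0.05 per
domestication branch (domestic-vs-local-wild Fst ≈ 0.1). Haplotypes are drawn
i.i.d. from the group's frequency vector and paired at random (monoecious
random mating); every haplotype allele is flipped with probability 0.005
(private singleton variation — real resequencing cohorts are never exactly
monomorphic, and without this the CHD∪EUD union in a unidirectional region
collapses to literal monomorphism, leaving its Fst undefined). All randomness
derives from one seed, with per-block substreams keyed by (seed, block), so
identical configurations are byte-identical regardless of evaluation order.

Scenarios: *neutral* (drift only); *uni_introgression* (a founder drawn from
the CHW pool is raised to sweep frequency — default 0.98 — in both CHD and
EUD; the ancient sample draws from the EUW pool); *uni_preintrogression*
(same sweep, ancient sample drawn from the swept EUD pool); *bidirectional*
(distinct founders swept in CHD and EUD). The ancient sample is a single
individual masked at 30% of sites by default.

What the generator does **not** emulate: recombination and LD decay within
blocks, mutation-rate and SFS realism, demographic size changes, linked
background selection, sequencing error beyond the flat singleton rate, and X
chromosome dosage. Passing recovery tests therefore demonstrate that the
statistics and decision rules respond to frequency and haplotype structure as
designed — not that real-data power equals the synthetic power.

## Validation experiments and their outcomes

Problem sizes were chosen to keep the full suite and the acceptance script
in the minutes range on one CPU: recovery cohorts are 2 contigs × 2 Mb with
30 samples per group and 1 SNP per 200 bp; calibration uses 200 neutral
20-kb regions with 1000 permutations each.

- **Oracle equivalence.** Windowed Fst, H12 and Tajima's D are each checked
  against independently transcribed brute-force oracles (per-site variance
  components, literal haplotype-string counting, pairwise-difference
  enumeration) to 1e-10/1e-12 on hundreds of random fixtures.
- **Calibration.** With zero domestic-branch drift the domestic/wild labels
  are exchangeable; the fraction of neutral regions with permutation
  p < 0.01 under the max rule is ≈ 0 (well inside the 99% binomial envelope
  of the nominal 1%).
- **Recovery.** Across five cohorts, essentially no neutral region is called
  (false-call rate 0 of 250) and ancient calls on correctly-identified
  unidirectional regions are ≈ 95% correct at 30% ancient missingness. The
  recovery of implanted sweeps as classified regions is ≈ 0.5 (uni) and
  ≈ 0.3 (bi): with 30 sweeps on a 4-Mb genome, ~22% of sliding windows carry
  sweep signal, and because ZFst is standardised by the genome-wide mean and
  sd, this self-contamination caps an aligned sweep window's attainable ZFst
  near 2.1–2.8; with realistic wild-pool drift the weaker half of the sweeps
  falls under the fixed ZFst > 2 cut in at least one contrast, and the
  common-region intersection multiplies the two sensitivities. At real-data
  scale (sweeps a few percent of a gigabase genome) this ceiling is far
  higher; the desk-scale density is the price of a fast test genome.
- **Determinism.** Rerunning the pipeline with the same seed reproduces every
  artifact byte for byte.
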