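# Methods

## Scope and data model

`parallelscan` starts at the genotype matrix: a dense samples × sites
array of diploid alt-allele dosages {0, 1, 2, missing} over biallelic
SNPs. Upstream read mapping, variant calling and depth/quality filtering
are out of scope; only minor-allele-frequency and missingness filters are
applied here, with vcftools-style inclusive semantics (a site is kept iff
MAF ≥ `min_maf` over non-missing genotypes and missing fraction ≤
`max_missing`). Two filter profiles are carried through the pipeline: a
genome-scan profile (MAF 0.02, missingness 0.5) and a stricter profile
for the D statistics (MAF 0.05, missingness 0.2), mirroring common
practice for Dsuite-style analyses. Coordinates are 0-based half-open
internally and in BED; 1-based only at VCF boundaries.

## Window statistics

All scans use non-overlapping windows (default 5 kb). Per site with alt
count c of n called alleles, within-population diversity is the unbiased
estimator π = 2(c/n)(1−c/n)·n/(n−1); between-population divergence is
d_xy = p̂₁(1−p̂₂) + p̂₂(1−p̂₁). Window values divide per-site sums by an
effective length; the default denominator is the window length, which is
the right convention when the input VCF carries variant sites only and
monomorphic sites are implicitly zero. A `genotyped_sites` mode divides
by the number of analyzed sites instead, for use with accessibility
masks. F_ST is Hudson-type, computed as one minus the ratio of *window
sums* (not a mean of per-site ratios), which is stable in low-diversity
windows; it is undefined when the d_xy sum is zero.

A consequence of the unbiased π worth knowing: if two "populations" carry
literally identical genotypes, F_ST is not exactly 0 but −1/(n−1) (n =
called alleles per population), because π carries the n/(n−1) correction
while d_xy does not. The estimator is unbiased around 0 for true random
samples of one population; the small negative value for duplicated
samples is expected behavior, and the tests pin it exactly.

## HDRs and sharing

Per species pair and per statistic (F_ST or D_xy), window values are
standardized as Z = (value − mean)/sd over all defined windows, with the
sample (n−1) standard deviation. Windows with Z ≥ 2 (inclusive) are
highly diverged regions. "Shared" HDRs are identical grid windows called
in both pairs — grid identity, not partial bp overlap, since both pairs
are scanned on one reference grid. Sharing enrichment uses a plain 2×2
Pearson chi-square (no Yates correction), with a warning recommending
Fisher's exact test when an expected count is below 5. Group comparisons
(HDR vs non-HDR window values) use Welch's two-sided t-test. No
multiple-testing correction is applied to these scan-level tests; they
are descriptive, matching how such scans are usually reported.

Selection-score overlap treats per-window XP-CLR/XP-EHH-style scores as
an external track: HDR windows whose score ranks in the top 5% (ceiling
of `top_frac` × defined windows; ties broken by genomic order) are
candidate selection regions.

## Introgression statistics

Site patterns are frequency-based. The derived allele at each site is
the allele at minority frequency in the outgroup; sites with outgroup
frequency exactly 0.5, an entirely missing outgroup, or any trio
population uncalled are skipped. With derived frequencies p̂₁…p̂₃, p̂_O:
ABBA = (1−p̂₁)p̂₂p̂₃(1−p̂_O) and BABA = p̂₁(1−p̂₂)p̂₃(1−p̂_O);
D = Σ(ABBA−BABA)/Σ(ABBA+BABA). The standard error is a delete-one block
jackknife over 20 contiguous equal-span blocks of the concatenated
genome (blocks with no informative sites are merged leftwards), Z = D/SE
and p is two-sided normal. |Z| ≥ 3 is used as the conventional critical
value throughout.

The f4-ratio uses the split-half estimator: P3's samples are split at
random (seeded) into halves P3a/P3b, f̂ = S(P1,P2,P3a,O)/S(P1,P3b,P3a,O)
with S = Σ(p̂_B−p̂_A)p̂_C(1−p̂_O); the split is resampled 10× and
averaged. **Known estimator property**: f̂ estimates the admixture
fraction α only up to the drift the donor branch accrues *after* the
pulse — approximately a factor (T_root − t_pulse)/T_root under constant
population size. For recent gene flow the factor is ≈ 1 and f̂ is a
consistent estimate of α; for ancient pulses it is attenuated (we
measure f̂ ≈ 0.14 for α = 0.54 when the pulse sits at 75% of the root
time). This is a property of all f4-ratio-style estimators, not of this
implementation; the admixture-recovery check therefore uses the
`pulse_recovery` scenario, which keeps the hybrid-origin topology and
α = 0.54 but places the pulse recently (expected attenuation ≈ 0.96).

f_d replaces both P2 and P3 in the denominator by a dynamic donor proxy
P_D = argmax(p̂₂, p̂₃) per site. Windows with window-level ABBA−BABA ≤ 0
are clamped to f_d = 0, windows with fewer than 10 informative sites
(sites with ABBA+BABA > 0) are undefined, and reported values are
clamped into [0, 1]. Introgression windows are the top-f_d windows whose
*count* reaches the target fraction of defined windows (the f4-ratio of
the focal trio in the pipeline); count-based rather than bp-based
because partial terminal windows would otherwise distort the proportion.

The empirical null re-places an observed region set 1000× uniformly at
random, keeping each interval on its source chromosome, forbidding
overlap within a replicate, and preserving the interval-size multiset.
Placements are aligned to the window grid — observed region sets are
unions of grid windows, so grid alignment makes replicate means exact
(a deliberate difference from `bedtools shuffle`, which does not snap).
The empirical p is (1 + #{replicate mean ≥ observed mean})/(n + 1);
note that ties count, so a replicate that happens to re-cover the
observed windows contributes to p.

## Isolation by distance and haplotypes

IBS distance between two diploids is mean(|a−b|)/2 over co-genotyped
sites (equivalently 1 − shared-alleles/2, the PLINK convention);
population distance averages over cross-population individual pairs.
Individual-pair averaging was chosen over frequency-based population
distance because the convention is explicit and testable by hand.
Geographic distances are haversine great circles with Earth radius
6,371 km. The Mantel test is one-sided for positive association (the
direction isolation-by-distance predicts) with 9,999 permutations by
default; p = (1 + #{r_perm ≥ r})/(n_perm + 1). With k populations only
k! distinct permutations exist, so for small k the permutation draw can
include the identity and the p-value floor is attained only
approximately.

Haplotype collapse works on IUPAC-coded per-sample sequences (hets as
M/R/W/S/Y/K, missing as N, invariant columns removed at export). Columns
containing any ambiguity code are dropped before collapsing — a
deterministic, phase-free convention; a `fifth_state` mode keeps
ambiguity codes as distinct states instead. The network is an epsilon-0
minimum spanning network over Hamming distances: edges added in
increasing weight, keeping every equal-weight alternative connection
between the components existing at the previous level. Median vectors
are not inferred (no median-joining); for star-like data the two
coincide.

## Simulated scenarios

Scenarios are declarative (splits, pulses, migration epochs in
forward-time terms, times in generations) and compiled to msprime.
Mutations use the default nucleotide model; sites with more than one
mutation are dropped so every retained site is strictly biallelic with
known ancestral/derived states, matching the D/f_d frequency algebra.
Defaults: μ = 7e-9 /bp/generation, generation time 2 y, recombination
1e-8 /bp/generation (for quasi-independent windows and jackknife
blocks), Ne = 10,000 for every population (effective sizes are exposed
as parameters), 20 diploids per population, outgroup divergence 10× the
oldest ingroup split so ancestral alleles are near-fixed for
polarization.

The library includes: four two-population gene-flow modes (none,
secondary contact, early flow, constant flow); six origin topologies
(two single-origin orders, single origin with independent colonization,
strict parallel origin, and hybrid parallel origin with the admixed
ancestor in the West or the East, each receiving a 54% donor pulse);
`bestfit_hybrid_origin`, the hybrid-parallel-origin model with literal event
times (oldest split 1,087,000 generations = 2,174 kya at g = 2; pulse at
814,500 generations ≈ 1,629 kya, the midpoint of the reported interval;
final split 703,000 generations = 1,406 kya); `null_no_flow` and
`power_recent_migration` (the null plus 1e-3/generation migration from
the Western into the Eastern spurless population over the last 1,000
generations); `pulse_recovery` (above); and a single-population
Watterson calibration scenario.

Desk-scale times for the null/power/topology scenarios (pair splits at
4,000 generations, root at 12,000, outgroup at 120,000) were chosen so
that, at Ne = 10,000, incomplete lineage sorting is abundant — the
regime the D and f_d statistics are designed for. At the literal
million-generation event times with desk-scale Ne, lineage sorting is
complete and D saturates at ±1, which is faithful to the model but
uninformative for calibrating the statistics; `bestfit_hybrid_origin` keeps the
literal times for truth bookkeeping and kya conversion.

What the simulations do **not** emulate about real resequencing data:
genotyping error and depth-dependent missingness (simulated genotypes
are exact), reference bias, linked selection and recombination-rate
variation, population structure within labels, and real sample sizes
(the study system had 158 individuals; we simulate 20 diploids per
population). Passing calibration tests therefore demonstrates
correctness of the statistics under neutral coalescent conditions, not
robustness to those artifacts.

## Numerical and design choices

- Missing dosage is −1 internally; frequencies are computed over called
  alleles only. Sites where a needed population is entirely missing are
  skipped per statistic and logged.
- Jackknife blocks: 20 equal-span blocks by default; doubling the count
  changes Z by well under 20% on the desk-scale genomes (tested).
- `call_introgressed` tie-break: fd descending, then genomic order, so
  calls are deterministic and monotone in the target proportion.
- Z-score tracks preserve NaN (undefined windows) and error on constant
  input rather than emitting infinities.
- Empirical p-values are never 0 by construction ((1 + k)/(n + 1)).
- The pipeline derives per-stage sub-seeds from one master seed via
  `numpy.random.SeedSequence` and records them in the report; the same
  configuration reproduces byte-identical outputs.

## Problem sizes

The bundled calibration checks run ten seeds of the null and
migration-power scenarios (5 populations × 20 diploids, 10 × 1 Mb) and
ten seeds of the recovery scenario (20 × 1 Mb), plus twenty seeds of the
single-population Watterson scenario (1 Mb): about two minutes in total
on one CPU. These sizes give jackknife Z-scores stable to ~±1 under the
null and seed-to-seed f4-ratio scatter of ~0.02, which is what the
acceptance tolerances assume.

## Known limitations

- The f4-ratio attenuation for ancient pulses (above) means the 54%
  donor contribution of the literal best-fit history is not recoverable
  by f4-style estimators from present-day samples alone; SFS-based
  demographic fitting (out of scope) is the appropriate tool there.
- Hudson F_ST can be slightly negative; it is reported as computed, not
  clamped.
- The minimum spanning network omits median (unsampled ancestral)
  haplotypes and may under-represent reticulation relative to
  median-joining networks.
- `random_region_null` requires windowed region sets; arbitrary
  intervals are first snapped to the grid by construction of the inputs.
- Chi-square tests are asymptotic; for the small tables that arise in
  tiny simulations the emitted warning should be heeded.
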