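# Methods

This note documents the models and numerical choices behind ldnekit in
enough detail to reproduce or audit any number the package prints.

## Genotype representation and I/O

Genotypes are alt-allele dosages (0/1/2 copies of `allele_b`, −1 missing)
bound to a marker map sorted by (chromosome, 1-based bp position). PLINK
text PED/MAP is the interchange dialect: whitespace-delimited, six leading
PED columns, `0` as the missing-allele code. `allele_b` defaults to the
lexicographically later observed allele; since r², |D′| and homozygosity
are invariant under allele relabelling, orientation only affects reporting.
One consequence: a marker whose file shows a single allele is coded as 0
copies of an unobserved alternative, so a write→read round-trip is
bit-exact only for markers with both alleles observed, or when the caller
passes the allele orientation back to `read_ped_map(..., alleles=...)`.
Only configured autosomes (default labels "1"–"29", the cattle autosomes)
enter analysis.

## QC cascade

Order matters and is fixed: sample call rate → marker call rate (recomputed
on surviving samples) → Hardy–Weinberg exact test → MAF threshold →
optional random thinning. Both call-rate filters use a strict `<` at the
0.9 default. The HWE test is the standard two-sided conditional exact test
with probability ordering (no mid-p): given the allele counts, all
heterozygote counts of the right parity are enumerated and the
probabilities of configurations no more likely than the observed one are
summed (log-gamma arithmetic, normalised per marker; equality tolerance
1 + 1e−12 on the probability comparison). Markers with p ≥ 0.01 are
retained. MAF filtering keeps markers with minor-allele frequency ≥ the
threshold, computed on non-missing calls. Thinning is a uniform random
subset under a recorded seed, preserving map order; it exists so datasets
filtered at different MAF thresholds can be compared at equal marker
counts.

## Two-locus EM and LD statistics

For a marker pair the 3×3 genotype-dosage table over individuals
non-missing at both loci is the sufficient statistic. Haplotype frequencies
(f_AB, f_Ab, f_aB, f_ab) are fitted by EM: every genotype class determines
its two haplotypes except double heterozygotes, which split between the
coupling (AB/ab) and repulsion (Ab/aB) phases with posterior weight
f_AB·f_ab / (f_AB·f_ab + f_Ab·f_aB).

Numerical choices:

- **Initialisation.** Linkage-equilibrium start (products of allele
  frequencies) plus a 1e−6 coupling perturbation. The unperturbed start is
  an exact EM fixed point — a saddle — for tables consisting only of double
  heterozygotes; the perturbation lets EM descend to a maximum (either
  phase assignment maximises the likelihood equally there).
- **Restarts.** When double heterozygotes are present, two additional
  corner-leaning starts (coupling- and repulsion-weighted) run and the best
  converged log-likelihood wins. The two-locus likelihood is unimodal for
  almost all tables, but the restarts cost little and the test suite's
  grid-search oracle holds EM to the global maximum.
- **Convergence.** Maximum absolute frequency change < 1e−10, cap 1000
  iterations; unconverged pairs are emitted with a flag, not dropped.
- Pairs with < 2 informative individuals or a monomorphic locus are
  skipped and counted.

From fitted frequencies with p_A, p_B the marginals: D = f_AB − p_A·p_B;
D′ = |D|/D_max with D_max = min(p_A q_B, q_A p_B) if D > 0 else
min(p_A p_B, q_A q_B); r² = D²/(p_A q_A p_B q_B). D_max² never exceeds the
r² denominator, so r² ≤ D′² holds identically (asserted to 1e−9 in tests).

The sample-size correction (r² − 1/n)/(1 − 1/n) is affine and
order-preserving, maps 1 → 1 and 1/n → 0, and may go negative below the
sampling floor (reported as computed). `n` defaults to twice the pair's
informative individuals; a `global` mode (2 × cohort size, one n for every
pair) reproduces chip-wide summary tables and is what the pipeline uses.

Decay tables use half-open distance classes in kb — the default 16 classes
partition [0, 50 Mb) — with unweighted means over pairs and ddof-1
standard deviations. Adjacent-pair tables summarise consecutive markers per
chromosome, plus an unweighted cross-chromosome mean row. The non-syntenic
background takes a seeded random SNP subset and evaluates every
inter-chromosomal pair; under independent chromosomes its mean r² sits near
1/n (EM phase uncertainty adds slightly to the counting floor at small n).

## ROH detection

The windowed algorithm follows the PLINK `--homozyg` design. Per individual
and chromosome, windows of 20 consecutive SNPs pass with ≤ 5 missing and
≤ 1 heterozygous call; each SNP's hit rate is passing windows containing it
over windows containing it (edge SNPs sit in fewer windows), and SNPs with
hit rate ≥ 0.05 are candidates. Maximal candidate stretches are split at
inter-marker gaps > 1000 kb, trimmed so both endpoints are homozygous
non-missing calls (window leakage otherwise admits one flanking
heterozygote), and kept if ≥ 1 Mb, ≥ 20 SNPs, and length/SNP-count
≤ 200 kb (density over the whole segment, PLINK semantics). Segment
coordinates are the first/last member SNP positions, 1-based inclusive;
length = end − start + 1. All parameters live in `ROHParams` with the
published medium-density settings as defaults; the hit proportion is the
PLINK default, exposed as a parameter rather than asserted as anything
else. Chromosomes shorter than one window are skipped with a warning.
Detection inspects only heterozygosity and missingness, so it is invariant
under 0↔2 relabelling.

Length classes are half-open at the printed .999 boundaries (1–4.999,
5–9.999, …, > 50 Mb); a `<1 Mb` class exists only for callers who relax
the minimum-length rule. Summaries report per-individual counts and
genome fraction (total ROH length over total autosome length, the latter
defaulting to the maximum mapped position per chromosome), per-chromosome
counts/sums, and Pearson correlations against chromosome length and
against per-chromosome adjacent-pair r² (undefined — reported as None —
below three chromosomes or at zero variance).

## LD-based Ne

Physical distance maps to recombination fraction via Sved's function
f(c) = d(1 − d/2) with d = distance_bp × 10⁻⁸ Morgans (a uniform 1 cM/Mb
map — the only dimensionally coherent reading of the bp↔Morgan convention
used in this literature). Each distance bin contributes one estimate

    Ne(t) = 1/(4 f(c̄)) · (1/mean(r²_adj) − a),   t = 1/(2 f(c̄)),

with r²_adj = r² − 1/(2N) for N diploid individuals (the uncorrected EM
r², not the (1 − 1/n)-rescaled one — the adjustment already removes the
sampling term), a = 1 (mutation constant), and c̄ from the arithmetic mean
of member-pair distances (not the bin midpoint). t = 1/(2f) is the
standard LD-Ne generation assignment. Pairs whose adjusted r² is negative
fall below the sampling floor and are excluded from bin means; bins that
are empty or whose mean cannot be inverted (mean r²_adj ≥ 1/a) are
reported as undefined rather than dropped. Default binning is geometric
over 0.02–50 Mb with 14 bins (configurable); rows sort by increasing t,
which is strictly decreasing in distance.

Known properties, deliberately not "corrected": in the Wright–Fisher model
E[r² | both markers segregating] exceeds Sved's 1/(1 + 4Nc) by roughly
10–25% at intermediate distances, so bin estimates sit somewhat below the
true Ne on average, most visibly at the recent (long-distance) end — the
same direction of bias this estimator family is known for on real data.
Conversely, when the simulated epoch is short relative to 1/(2c) for a
bin's distance, that bin's LD has not fully built up and its (ancient) Ne
is overestimated.

## Wright–Fisher generator

Forward-in-time diploid simulation, chosen over a coalescent because
piecewise Ne, recombination and genotype-level missingness are exact and
transparent forward in time at desk scale. Haplotypes start at linkage
equilibrium with founding allele frequencies Uniform(maf_floor, 1 −
maf_floor), maf_floor = 0.05. Each generation N(t) diploids form by random
mating (selfing allowed); each gamete recombines with Poisson(L Morgans)
crossovers at uniform positions, and chromosomes assort independently.
There is no mutation: the panel is standing variation, as a SNP array
ascertains it, and markers that fix are retained for the MAF filter to
remove downstream. Identical seed and config give bit-identical output;
the truth record carries the schedule, seed, positions and founding
frequencies so drift laws (heterozygosity decay at rate 1 − 1/(2Ne) per
generation, allele-frequency variance p₀q₀(1 − (1 − 1/(2Ne))^t)) are
directly testable.

Defaults — the package's reference study condition — are 10 chromosomes of
10 Mb with 100 markers each (1,000 markers), a cohort of 50 diploids from
constant Ne = 100, 2% missing calls, and a 200-generation epoch: 2·Ne
generations, the timescale on which LD reaches quasi-equilibrium from the
LE start. Longer epochs without mutation drift the frequency spectrum so
far that conditioning on segregating markers visibly inflates r²; shorter
ones leave short-distance LD under-built. What the generator does *not*
emulate: mutation, selection, migration, admixture, non-random mating,
variable recombination maps, array genotyping error. Passing tests on this
generator therefore demonstrate estimator correctness under drift +
recombination, not robustness to those real-data complications.

The ROH fixture builder realises tract layouts (`hom`/`het`/`miss` runs at
fixed spacing, explicit gaps) exactly and returns the constructed
homozygous runs as truth, split at gaps above the detection limit. The LD
fixture draws 2n haplotypes multinomially from specified two-locus
frequencies and pairs them at random.

## Pipeline and reports

`run_all` executes: autosome filter → call-rate filters → HWE → per-MAF
(0.01/0.05/0.1) MAF filter with thinning to the smallest dataset →
syntenic scan (global-n correction) → decay and adjacent tables → ROH on
the pre-MAF dataset → per-MAF Ne trajectories and their unweighted mean
column (defined only where every dataset is defined; datasets must share
bin grids). Report rounding is 3 decimals for LD means and integers for
Ne. Every table is recomputed from stage outputs recorded in the manifest,
nothing is cached, and reruns are byte-identical (asserted in tests).

## Problem sizes used in the test suite

The suites run on reduced panels chosen to exercise every code path with
stable statistics: the shared fixture is 3 × 5 Mb chromosomes × 80 markers
(40 samples); the parameter-recovery study uses the generator defaults
(1,000 markers, 50 diploids) with 20 replicates for the constant-Ne median
and 2 replicates of the crash scenario (Ne 1000 → 50 at generation 8); the
EM grid oracle evaluates a 0.02-step simplex grid against all small count
tables plus 250 random tables with totals ≤ 12; the HWE oracle enumerates
every table with ≤ 8 individuals exactly (rational arithmetic).
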