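"""Runs of homozygosity in an inbred cohort.

A tiny population (Ne = 15) accumulates long autozygous tracts quickly;
the sliding-window scan recovers them and the summaries report how much of
the genome each individual carries inside ROH.
"""

from ldnekit.roh import classify_roh, detect_roh, roh_summaries
from ldnekit.simulate import DemographyConfig, simulate_wright_fisher

cfg = DemographyConfig(
    ne_schedule=((0, 15),), n_generations=60, n_chromosomes=4,
    chromosome_length_bp=8_000_000, n_markers_per_chromosome=150,
    n_samples=15, missing_rate=0.02, seed=23,
)
g, _ = simulate_wright_fisher(cfg)
segments = detect_roh(g)
print(f"{len(segments)} ROH segments in {g.n_samples} individuals")

for label, count in classify_roh(segments).items():
    if count:
        print(f"  {label:<15} {count}")

summary = roh_summaries(segments, g)
per_ind = summary.per_individual
print(f"mean segments per individual: {per_ind['n_segments'].mean():.1f}")
print(f"mean genome fraction inside ROH: {summary.mean_genome_fraction:.1%}")
corr = summary.correlations["count_vs_chrom_length"]
if corr:
    r, n, p = corr
    print(f"ROH count vs chromosome length: r = {r:.2f} (n = {n}, p = {p:.2g})")
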