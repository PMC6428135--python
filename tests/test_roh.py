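"""ROH detection against hand-traced fixtures, invariants and summaries."""

import numpy as np
import pytest

from ldnekit.genotype_io import MISSING, GenotypeMatrix
from ldnekit.roh import (
    ROHParams,
    ROHSegment,
    classify_length,
    classify_roh,
    detect_roh,
    roh_summaries,
)
from ldnekit.simulate import DemographyConfig, make_roh_fixture, simulate_wright_fisher


def test_fully_heterozygous_individual_yields_nothing():
    g, truth = make_roh_fixture([[("het", 120)]])
    assert truth == []
    assert detect_roh(g) == []


def test_three_mb_homozygous_tract_detected_exactly():
    # 60 hom SNPs at 50 kb spacing span 2.95 Mb: one class-1 segment whose
    # endpoints are the first and last homozygous SNP (het flanks trimmed)
    g, truth = make_roh_fixture([[("het", 30), ("hom", 60), ("het", 30)]])
    segs = detect_roh(g)
    assert len(segs) == 1
    seg = segs[0]
    assert (seg.start_bp, seg.end_bp, seg.n_snps) == (
        truth[0]["start_bp"], truth[0]["end_bp"], truth[0]["n_snps"]
    )
    assert seg.length_class == "1 to 4.999 Mb"


def test_internal_gap_splits_the_run():
    # two 30-SNP tracts (1.45 Mb each) separated by a 1.2 Mb gap: the gap
    # exceeds the 1 Mb limit, so two segments, each passing every rule
    g, truth = make_roh_fixture(
        [[("het", 25), ("hom", 30), ("gap", 1_200_000), ("hom", 30), ("het", 25)]]
    )
    segs = detect_roh(g)
    assert len(segs) == len(truth) == 2
    for seg, t in zip(segs, truth):
        assert (seg.start_bp, seg.end_bp, seg.n_snps) == (
            t["start_bp"], t["end_bp"], t["n_snps"]
        )


def test_short_tract_fails_minimum_rules():
    # 15 hom SNPs span 0.7 Mb: below both the 1 Mb and 20-SNP floors
    g, _ = make_roh_fixture([[("het", 30), ("hom", 15), ("het", 30)]])
    assert detect_roh(g) == []


def test_whole_chromosome_homozygote_gives_single_spanning_segment():
    g, truth = make_roh_fixture([[("hom", 100)]])
    segs = detect_roh(g)
    assert len(segs) == 1
    assert segs[0].start_bp == truth[0]["start_bp"]
    assert segs[0].end_bp == truth[0]["end_bp"]
    assert segs[0].n_snps == 100


def test_detection_invariant_under_allele_orientation_swap(small_sim):
    g, _ = small_sim
    params = ROHParams(min_length_bp=200_000, min_snps=5, window_snps=10)
    swapped_calls = g.calls.copy()
    hom0 = swapped_calls == 0
    hom2 = swapped_calls == 2
    swapped_calls[hom0] = 2
    swapped_calls[hom2] = 0
    swapped = GenotypeMatrix(g.samples, g.markers, swapped_calls)
    assert detect_roh(g, params) == detect_roh(swapped, params)


def test_detection_invariant_to_distant_het_padding():
    layout = [[("het", 30), ("hom", 60), ("het", 30)]]
    g, _ = make_roh_fixture(layout)
    padded, _ = make_roh_fixture(
        [[("het", 20), ("gap", 5_000_000)] + layout[0] + [("gap", 5_000_000), ("het", 20)]]
    )
    segs = detect_roh(g)
    padded_segs = detect_roh(padded)
    # the padding shifts the tract by 20 x 50 kb + 5 Mb = 6 Mb but must not
    # change what is detected
    assert [(s.start_bp, s.end_bp, s.n_snps) for s in segs] == [
        (s.start_bp - 6_000_000, s.end_bp - 6_000_000, s.n_snps) for s in padded_segs
    ]


def test_emitted_segments_satisfy_all_invariants(small_sim):
    # a drifted small population carries plenty of real homozygous runs
    cfg = DemographyConfig(
        ne_schedule=((0, 15),), n_generations=60, n_chromosomes=4,
        chromosome_length_bp=8_000_000, n_markers_per_chromosome=150,
        n_samples=15, missing_rate=0.02, seed=23,
    )
    g, _ = simulate_wright_fisher(cfg)
    params = ROHParams()
    segs = detect_roh(g, params)
    assert segs, "inbred cohort should yield at least one ROH"
    pos = g.positions
    for s in segs:
        assert s.length_bp >= params.min_length_bp
        assert s.n_snps >= params.min_snps
        assert s.length_bp / s.n_snps <= params.min_density_bp_per_snp
        idx = g.marker_indices(s.chromosome)
        member = idx[(pos[idx] >= s.start_bp) & (pos[idx] <= s.end_bp)]
        gaps = np.diff(pos[member].astype(np.int64))
        assert gaps.max(initial=0) <= params.max_gap_bp
        # endpoints are homozygous non-missing calls
        row = g.samples.index(s.sample_id)
        first = g.calls[row, member[0]]
        last = g.calls[row, member[-1]]
        assert first in (0, 2) and last in (0, 2)


def test_window_shorter_chromosomes_skipped_with_warning():
    g, _ = make_roh_fixture([[("hom", 10)]])
    with pytest.warns(UserWarning, match="skipped"):
        assert detect_roh(g) == []


# ---------------------------------------------------------------------------
# length classes
# ---------------------------------------------------------------------------

def test_class_boundaries():
    assert classify_length(3_000_000) == "1 to 4.999 Mb"
    assert classify_length(5_000_000) == "5 to 9.999 Mb"
    assert classify_length(60_000_000) == ">50 Mb"


def test_class_histogram_matches_brute_force():
    rng = np.random.default_rng(6)
    lengths = rng.integers(1_000_000, 80_000_000, size=300)
    segs = [
        ROHSegment("s", "1", 1, int(l), 50, classify_length(int(l)))
        for l in lengths
    ]
    counts = classify_roh(segs)
    edges_mb = [1, 5, 10, 15, 20, 25, 50, np.inf]
    hist, _ = np.histogram(lengths / 1e6, bins=edges_mb)
    assert list(counts.values()) == hist.tolist()


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_single_roh_coverage_fraction():
    seg = ROHSegment("s1", "1", 1_000_001, 2_000_000, 30, "1 to 4.999 Mb")
    summary = roh_summaries([seg], chromosome_lengths={"1": 100_000_000})
    assert summary.per_individual["genome_fraction"].iloc[0] == pytest.approx(0.01)
    assert summary.mean_genome_fraction == pytest.approx(0.01)


def test_zero_segments_reported_as_undefined(small_sim):
    g, _ = small_sim
    summary = roh_summaries([], g)
    assert summary.per_individual["n_segments"].sum() == 0
    assert summary.correlations["count_vs_chrom_length"] is None


def test_missing_chromosome_lengths_instructs_caller():
    with pytest.raises(ValueError, match="chromosome_lengths"):
        roh_summaries([])


def test_summaries_match_independent_aggregation(small_sim):
    cfg = DemographyConfig(
        ne_schedule=((0, 15),), n_generations=60, n_chromosomes=4,
        chromosome_length_bp=8_000_000, n_markers_per_chromosome=150,
        n_samples=15, missing_rate=0.02, seed=23,
    )
    g, _ = simulate_wright_fisher(cfg)
    segs = detect_roh(g)
    summary = roh_summaries(segs, g)
    for _, row in summary.per_individual.iterrows():
        mine = [s for s in segs if s.sample_id == row["sample_id"]]
        assert row["n_segments"] == len(mine)
        assert row["total_bp"] == sum(s.length_bp for s in mine)
    for _, row in summary.per_chromosome.iterrows():
        mine = [s for s in segs if s.chromosome == row["chromosome"]]
        assert row["n_segments"] == len(mine)
        assert row["total_bp"] == sum(s.length_bp for s in mine)
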