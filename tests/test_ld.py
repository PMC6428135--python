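"""EM haplotype estimation, LD statistics, decay binning and summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ldnekit.errors import ConfigError, InsufficientDataError, MonomorphicMarkerError
from ldnekit.ld import (
    DEFAULT_BINS_KB,
    HaploFreqs,
    PairLD,
    adjacent_summary,
    bin_decay_table,
    correct_r2,
    cross_chromosome_mean,
    em_from_counts,
    ld_from_haplofreqs,
    nonsyntenic_background,
    pair_ld,
    scan_syntenic_pairs,
)
from ldnekit.simulate import make_ld_fixture


def _freqs(h: HaploFreqs) -> np.ndarray:
    return np.array([h.f_AB, h.f_Ab, h.f_aB, h.f_ab])


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------

def test_perfect_coupling_recovers_half_half():
    # 5 individuals hom-ref/hom-ref and 5 hom-alt/hom-alt: no ambiguity
    counts = [[5, 0, 0], [0, 0, 0], [0, 0, 5]]
    h = em_from_counts(counts)
    np.testing.assert_allclose(_freqs(h), [0.5, 0.0, 0.0, 0.5], atol=1e-12)


def test_equilibrium_table_is_a_fixed_point():
    counts = [[1, 2, 1], [2, 4, 2], [1, 2, 1]]
    h = em_from_counts(counts)
    np.testing.assert_allclose(_freqs(h), [0.25] * 4, atol=1e-8)
    assert abs(sum(_freqs(h)) - 1.0) < 1e-9


def test_em_equals_direct_counting_without_double_heterozygotes():
    rng = np.random.default_rng(3)
    for _ in range(25):
        counts = rng.integers(0, 5, size=(3, 3))
        counts[1, 1] = 0
        n = counts.sum()
        hap = np.zeros(4)  # AB, Ab, aB, ab direct haplotype tally
        weights = {
            (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
            (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
            (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
        }
        for (gi, gj), w in weights.items():
            hap += counts[gi, gj] * np.array(w)
        expected = hap / (2 * n)
        p1 = expected[0] + expected[1]
        p2 = expected[0] + expected[2]
        if n < 2 or min(p1, 1 - p1, p2, 1 - p2) <= 0:
            continue
        h = em_from_counts(counts)
        np.testing.assert_allclose(_freqs(h), expected, atol=1e-9)


def test_em_log_likelihood_beats_simplex_grid():
    """EM attains at least the best likelihood on a grid over the simplex."""
    step = 0.02
    ticks = int(round(1 / step))
    pts = []
    for i in range(ticks + 1):
        for j in range(ticks + 1 - i):
            for k in range(ticks + 1 - i - j):
                pts.append((i * step, j * step, k * step, 1 - (i + j + k) * step))
    grid = np.array(pts)  # (G, 4) in order (f_ab, f_aB, f_Ab, f_AB)
    f_ab, f_aB, f_Ab, f_AB = grid.T
    cell_probs = np.stack(
        [
            f_ab * f_ab, 2 * f_ab * f_aB, f_aB * f_aB,
            2 * f_ab * f_Ab, 2 * f_AB * f_ab + 2 * f_Ab * f_aB, 2 * f_aB * f_AB,
            f_Ab * f_Ab, 2 * f_Ab * f_AB, f_AB * f_AB,
        ],
        axis=1,
    )
    with np.errstate(divide="ignore"):
        log_cell = np.log(cell_probs)

    def grid_best(counts: np.ndarray) -> float:
        flat = counts.reshape(-1).astype(float)
        nz = flat > 0
        ll = log_cell[:, nz] @ flat[nz]
        return float(np.max(ll))

    tables = [
        np.array(t).reshape(3, 3)
        for t in itertools.product(range(4), repeat=9)
        if 2 <= sum(t) <= 4
    ]
    rng = np.random.default_rng(7)
    for _ in range(150):  # larger tables with totals up to 12
        t = rng.multinomial(int(rng.integers(5, 13)), np.full(9, 1 / 9))
        tables.append(t.reshape(3, 3))

    checked = 0
    for counts in tables:
        try:
            h = em_from_counts(counts)
        except (InsufficientDataError, MonomorphicMarkerError):
            continue
        assert h.log_likelihood >= grid_best(counts) - 1e-6, counts
        checked += 1
    assert checked > 500


def test_double_het_only_table_escapes_the_symmetric_saddle():
    # two double heterozygotes: the MLE is a fully coupled (or fully
    # repulsed) pair of haplotypes, not the equilibrium saddle
    h = em_from_counts([[0, 0, 0], [0, 2, 0], [0, 0, 0]])
    assert h.log_likelihood == pytest.approx(2 * np.log(0.5), abs=1e-6)


def test_monomorphic_and_tiny_tables_raise():
    with pytest.raises(MonomorphicMarkerError):
        em_from_counts([[4, 0, 0], [0, 0, 0], [0, 0, 0]])
    with pytest.raises(InsufficientDataError):
        em_from_counts([[1, 0, 0], [0, 0, 0], [0, 0, 0]])


# ---------------------------------------------------------------------------
# LD statistics from haplotype frequencies
# ---------------------------------------------------------------------------

def _hf(f_AB, f_Ab, f_aB, f_ab):
    return HaploFreqs(f_AB, f_Ab, f_aB, f_ab, 0.0, 0, 0)


def test_complete_coupling_gives_unit_ld():
    d, dp, r2 = ld_from_haplofreqs(_hf(0.5, 0.0, 0.0, 0.5))
    assert (d, dp, r2) == (pytest.approx(0.25), pytest.approx(1.0), pytest.approx(1.0))


def test_equilibrium_gives_zero_ld():
    d, dp, r2 = ld_from_haplofreqs(_hf(0.25, 0.25, 0.25, 0.25))
    assert (d, dp, r2) == (0.0, 0.0, 0.0)


def test_hand_worked_repulsion_example():
    # worked by hand from the definitions: p_A = p_B = 0.75,
    # D = 0.5 - 0.5625 = -0.0625, D_max = min(0.5625, 0.0625) -> D' = 1,
    # r2 = 0.0625^2 / 0.75^2 0.25^2 = 1/9
    d, dp, r2 = ld_from_haplofreqs(_hf(0.5, 0.25, 0.25, 0.0))
    assert d == pytest.approx(-0.0625)
    assert dp == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0 / 9.0)


def test_monomorphic_marginal_rejected():
    with pytest.raises(MonomorphicMarkerError):
        ld_from_haplofreqs(_hf(0.5, 0.5, 0.0, 0.0))


@given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
def test_r2_bounded_by_dprime_squared(raw):
    f = np.array(raw) / sum(raw)
    h = _hf(*f)
    p_a, p_b = h.f_AB + h.f_Ab, h.f_AB + h.f_aB
    if min(p_a, 1 - p_a, p_b, 1 - p_b) <= 1e-9:
        return
    _, dp, r2 = ld_from_haplofreqs(h)
    assert 0.0 <= r2 <= 1.0 + 1e-12
    assert 0.0 <= dp <= 1.0 + 1e-12
    assert r2 <= dp * dp + 1e-9


# ---------------------------------------------------------------------------
# sample-size correction
# ---------------------------------------------------------------------------

def test_correction_reproduces_reported_rounding():
    assert round(correct_r2(0.227, 174), 3) == 0.223
    assert round(correct_r2(0.291, 174), 3) == 0.287
    assert correct_r2(1.0, 174) == pytest.approx(1.0)
    assert correct_r2(1.0 / 174, 174) == pytest.approx(0.0)


@given(
    st.floats(0, 1), st.floats(0, 1), st.integers(min_value=2, max_value=10_000)
)
def test_correction_is_affine_and_order_preserving(r2a, r2b, n):
    ca, cb = correct_r2(r2a, n), correct_r2(r2b, n)
    if r2a < r2b:
        assert ca < cb
    mid = correct_r2((r2a + r2b) / 2, n)
    assert mid == pytest.approx((ca + cb) / 2, abs=1e-12)


def test_correction_rejects_degenerate_n():
    with pytest.raises(ValueError):
        correct_r2(0.5, 1)


# ---------------------------------------------------------------------------
# pair scans
# ---------------------------------------------------------------------------

def test_three_close_markers_give_three_pairs():
    g, _ = make_ld_fixture([0.3, 0.2, 0.2, 0.3], 30, seed=1)
    # extend to 3 markers on one chromosome by duplicating a column
    import pandas as pd

    from ldnekit.genotype_io import GenotypeMatrix

    markers = pd.concat(
        [g.markers, g.markers.iloc[[1]].assign(marker_id="mC", position_bp=30_000)],
        ignore_index=True,
    ).sort_values("position_bp", ignore_index=True)
    calls = np.column_stack([g.calls, g.calls[:, 1]])[:, [0, 2, 1]]
    g3 = GenotypeMatrix(g.samples, markers, calls)
    pairs, stats = scan_syntenic_pairs(g3, 50_000_000)
    assert stats.n_pairs == 3


def test_distance_cutoff_excludes_far_pairs():
    g, _ = make_ld_fixture(
        [0.3, 0.2, 0.2, 0.3], 30, seed=1, positions=(1_000_000, 61_000_000)
    )
    pairs, stats = scan_syntenic_pairs(g, 50_000_000)
    assert stats.n_pairs == 0


def test_scan_matches_brute_force_enumeration(small_sim):
    g, _ = small_sim
    max_d = 2_000_000
    pairs, stats = scan_syntenic_pairs(g, max_d)
    got = {(p.marker_i, p.marker_j) for p in pairs}

    expected = set()
    n_skip = 0
    chroms = g.chromosomes
    pos = g.positions
    ids = g.markers["marker_id"].to_numpy()
    for i in range(g.n_markers):
        for j in range(i + 1, g.n_markers):
            if chroms[i] != chroms[j] or abs(int(pos[j]) - int(pos[i])) >= max_d:
                continue
            try:
                pair_ld(g, i, j)
            except (InsufficientDataError, MonomorphicMarkerError):
                n_skip += 1
                continue
            expected.add((ids[i], ids[j]))
    assert got == expected
    assert stats.n_skipped == n_skip


# ---------------------------------------------------------------------------
# decay binning
# ---------------------------------------------------------------------------

def _stub_pair(distance_bp, r2=0.1):
    return PairLD("a", "b", "1", "1", distance_bp, 0.01, 0.5, r2, r2 / 2, 80)


def test_single_pair_lands_in_first_bin():
    bins = bin_decay_table([_stub_pair(10_000)], DEFAULT_BINS_KB)
    assert bins[0].n_pairs == 1
    assert sum(b.n_pairs for b in bins[1:]) == 0


def test_boundary_pair_goes_to_upper_bin():
    bins = bin_decay_table([_stub_pair(20_000)], DEFAULT_BINS_KB)
    assert bins[0].n_pairs == 0
    assert bins[1].n_pairs == 1


def test_bin_counts_match_histogram_oracle():
    rng = np.random.default_rng(21)
    dists = rng.integers(0, 50_000_000, size=1000)
    bins = bin_decay_table([_stub_pair(int(d)) for d in dists], DEFAULT_BINS_KB)
    edges = [lo * 1000 for lo, _ in DEFAULT_BINS_KB] + [50_000_000]
    hist, _ = np.histogram(dists, bins=edges)
    assert [b.n_pairs for b in bins] == hist.tolist()


def test_overlapping_bins_rejected():
    with pytest.raises(ConfigError):
        bin_decay_table([], [(0, 30), (20, 40)])


# ---------------------------------------------------------------------------
# non-syntenic background
# ---------------------------------------------------------------------------

def test_single_chromosome_background_rejected():
    g, _ = make_ld_fixture([0.3, 0.2, 0.2, 0.3], 30, seed=1)
    with pytest.raises(ValueError):
        nonsyntenic_background(g, 2, seed=0)


def test_two_by_two_markers_give_four_pairs(small_sim):
    g, _ = small_sim
    # pick two polymorphic markers on each of two chromosomes
    maf = np.nan_to_num(g.minor_allele_freq())
    keep = []
    for chrom in g.chromosome_labels()[:2]:
        idx = sorted(g.marker_indices(chrom), key=lambda i: -maf[i])
        keep += sorted(int(i) for i in idx[:2])
    sub = g.take_markers(keep)
    summary = nonsyntenic_background(sub, 4, seed=0)
    assert summary.n_pairs == 4


def test_background_r2_near_sampling_floor(small_sim):
    g, _ = small_sim
    from ldnekit.qc import maf_filter

    d = maf_filter(g, 0.1)
    summary = nonsyntenic_background(d, min(60, d.n_markers), seed=2)
    n_hap = 2 * g.n_samples
    # independence: background r2 should sit near 1/n_haplotypes
    assert 0.5 / n_hap < summary.mean_r2 < 3.0 / n_hap


# ---------------------------------------------------------------------------
# adjacent-pair summaries
# ---------------------------------------------------------------------------

def test_two_marker_chromosome_summary():
    g, _ = make_ld_fixture([0.35, 0.15, 0.15, 0.35], 400, seed=4)
    table = adjacent_summary(g)
    row = table[table["chromosome"] == "1"].iloc[0]
    assert row["n_pairs"] == 1
    assert 0.0 <= row["mean_r2"] <= 1.0
    if row["mean_r2"] > 0.2:
        assert row["pct_r2_gt_0.2"] == 100.0


def test_summary_matches_brute_force_recomputation(small_sim):
    g, _ = small_sim
    from ldnekit.ld import adjacent_pairs

    pairs = adjacent_pairs(g)
    table = adjacent_summary(g, pairs)
    for chrom in g.chromosome_labels():
        plist = [p for p in pairs if p.chromosome_i == chrom]
        if not plist:
            continue
        row = table[table["chromosome"] == chrom].iloc[0]
        r2 = np.array([p.r2 for p in plist])
        assert row["mean_r2"] == pytest.approx(r2.mean())
        assert row["pct_r2_gt_0.2"] == pytest.approx((r2 > 0.2).mean() * 100)
    mean_row = table[table["chromosome"] == "Mean"].iloc[0]
    per_chrom = table[table["chromosome"] != "Mean"]["mean_r2"]
    assert mean_row["mean_r2"] == pytest.approx(per_chrom.mean())


def test_cross_chromosome_mean_is_unweighted():
    assert cross_chromosome_mean([0.1, 0.2, 0.3]) == pytest.approx(0.2)
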