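"""Synthetic genotype data with known demographic truth.

A forward-in-time diploid Wright-Fisher simulator provides the statistical
structure the LD/ROH/Ne estimators assume: neutral biallelic markers whose
LD is generated purely by drift and recombination under a piecewise-constant
Ne history.  There is no mutation during the simulated epoch - the panel is
standing variation, which matches the ascertainment regime of a SNP array -
so markers that fix along the way are retained in the output and are
expected to be removed by the MAF filter, exercising the real pipeline path.

Deterministic fixtures for ROH and two-locus LD truth are also built here.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import LayoutError
from .genotype_io import MISSING, GenotypeMatrix


@dataclasses.dataclass
class DemographyConfig:
    """Simulation parameters.

    ``ne_schedule`` is a piecewise-constant history: entries
    ``(generations_ago_start, Ne)`` where the entry with the largest start
    not exceeding a generation applies; an entry with start 0 is required so
    the schedule covers the present.  Defaults describe a small livestock
    panel: 10 chromosomes of 10 Mb carrying 100 markers each at a uniform
    1 cM/Mb map, a cohort of 50 diploids drawn from a constant Ne of 100,
    2% missing calls, and a 200-generation epoch (2 Ne, the timescale on
    which LD equilibrates from the linkage-equilibrium start).
    """

    ne_schedule: tuple[tuple[int, int], ...] = ((0, 100),)
    n_generations: int = 200
    n_chromosomes: int = 10
    chromosome_length_bp: int = 10_000_000
    n_markers_per_chromosome: int = 100
    morgans_per_bp: float = 1e-8
    missing_rate: float = 0.02
    maf_floor_init: float = 0.05
    n_samples: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        starts = [s for s, _ in self.ne_schedule]
        if any(n <= 0 for _, n in self.ne_schedule):
            raise ValueError("every Ne in the schedule must be positive")
        if 0 not in starts:
            raise ValueError("the schedule needs an entry starting at generation 0")
        if any(s < 0 or s > self.n_generations for s in starts):
            raise ValueError("schedule starts must lie in [0, n_generations]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0 < self.maf_floor_init < 0.5):
            raise ValueError("maf_floor_init must lie in (0, 0.5)")

    def ne_at(self, generations_ago: int) -> int:
        """Ne in force ``generations_ago`` (largest schedule start <= t)."""
        best_start, best_ne = -1, None
        for start, ne in self.ne_schedule:
            if start <= generations_ago and start > best_start:
                best_start, best_ne = start, ne
        assert best_ne is not None
        return best_ne


def _unique_sorted_positions(
    rng: np.random.Generator, n: int, length_bp: int
) -> np.ndarray:
    pos: np.ndarray = np.unique(rng.integers(1, length_bp + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length_bp + 1, size=n - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n]


def simulate_wright_fisher(
    cfg: DemographyConfig,
) -> tuple[GenotypeMatrix, dict]:
    """Forward Wright-Fisher simulation returning genotypes plus the truth.

    Haplotypes start at linkage equilibrium with allele frequencies drawn
    uniformly in [maf_floor_init, 1 - maf_floor_init].  Each generation N(t)
    diploids are formed by random mating (selfing possible); every gamete
    recombines with a Poisson number of crossovers (mean = chromosome length
    in Morgans, positions uniform).  After ``n_generations`` a cohort of
    ``n_samples`` diploids is drawn and per-call missingness applied.  The
    returned truth record holds the schedule, seed, marker positions and the
    founding allele frequencies.
    """
    if cfg.n_samples > cfg.ne_at(0):
        raise ValueError(
            f"cohort of {cfg.n_samples} exceeds the final population of {cfg.ne_at(0)}"
        )
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_markers_per_chromosome
    l_bp = cfg.chromosome_length_bp
    l_morgan = l_bp * cfg.morgans_per_bp

    positions = [
        _unique_sorted_positions(rng, m, l_bp) for _ in range(cfg.n_chromosomes)
    ]
    n_anc = cfg.ne_at(cfg.n_generations)
    init_freqs = [
        rng.uniform(cfg.maf_floor_init, 1.0 - cfg.maf_floor_init, size=m)
        for _ in range(cfg.n_chromosomes)
    ]
    haplos = [
        (rng.random((2 * n_anc, m)) < f).astype(np.int8) for f in init_freqs
    ]

    n_prev = n_anc
    for t in range(cfg.n_generations - 1, -1, -1):
        n_now = cfg.ne_at(t)
        parents = rng.integers(0, n_prev, size=(n_now, 2))
        for c in range(cfg.n_chromosomes):
            # chromosomes assort independently: fresh start haplotype per chrom
            start_hap = rng.integers(0, 2, size=(n_now, 2))
            hap_row = (2 * parents + start_hap).reshape(-1)
            n_cross = rng.poisson(l_morgan, size=(n_now, 2))
            new = haplos[c][hap_row].copy()
            for k, gam in zip(*np.nonzero(n_cross)):
                xs = np.sort(rng.uniform(0, l_bp, size=n_cross[k, gam]))
                parity = (start_hap[k, gam] + np.searchsorted(xs, positions[c])) % 2
                p = parents[k, gam]
                new[2 * k + gam] = np.where(
                    parity == 0, haplos[c][2 * p], haplos[c][2 * p + 1]
                )
            haplos[c] = new
        n_prev = n_now

    cohort = np.sort(rng.choice(n_prev, size=cfg.n_samples, replace=False))
    geno_blocks = [
        (haplos[c][2 * cohort] + haplos[c][2 * cohort + 1]).astype(np.int8)
        for c in range(cfg.n_chromosomes)
    ]
    calls = np.concatenate(geno_blocks, axis=1)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    marker_rows = []
    for c in range(cfg.n_chromosomes):
        for k, p in enumerate(positions[c]):
            marker_rows.append(
                {
                    "marker_id": f"chr{c + 1}_snp{k + 1:04d}",
                    "chromosome": str(c + 1),
                    "position_bp": int(p),
                    "allele_a": "A",
                    "allele_b": "B",
                }
            )
    g = GenotypeMatrix(
        samples=[f"ind_{i + 1:03d}" for i in range(cfg.n_samples)],
        markers=pd.DataFrame(marker_rows),
        calls=calls,
    )
    truth = {
        "config": cfg,
        "ne_schedule": tuple(cfg.ne_schedule),
        "seed": cfg.seed,
        "positions": positions,
        "init_freqs": init_freqs,
        "final_population": n_prev,
    }
    return g, truth


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------

_ROH_STATES = {"hom": 2, "het": 1, "miss": MISSING}


def make_roh_fixture(
    individual_layouts: Sequence[Sequence[tuple]],
    spacing_bp: int = 50_000,
    chromosome: str = "1",
    start_bp: int = 1_000_000,
    split_gap_bp: int = 1_000_000,
) -> tuple[GenotypeMatrix, list[dict]]:
    """Genotype matrix realising per-individual homozygosity tracts exactly.

    Each layout is a list of tracts: ``(state, n_snps)`` with state one of
    ``"hom"``, ``"het"``, ``"miss"`` (markers spaced ``spacing_bp`` apart),
    or ``("gap", gap_bp)`` advancing the coordinate without markers.  All
    layouts must realise the same marker grid.  The returned truth lists the
    constructed homozygous runs per individual, split wherever consecutive
    hom markers are farther apart than ``split_gap_bp``.
    """
    if not individual_layouts:
        raise LayoutError("at least one individual layout is required")

    grids: list[np.ndarray] = []
    state_rows: list[np.ndarray] = []
    for layout in individual_layouts:
        pos_list: list[int] = []
        states: list[int] = []
        cursor = start_bp
        for tract in layout:
            kind = tract[0]
            if kind == "gap":
                gap = int(tract[1])
                if gap <= 0:
                    raise LayoutError("gap length must be positive")
                cursor += gap
                continue
            if kind not in _ROH_STATES:
                raise LayoutError(f"unknown tract state {kind!r}")
            n = int(tract[1])
            if n <= 0:
                raise LayoutError("tract SNP count must be positive")
            for _ in range(n):
                pos_list.append(cursor)
                states.append(_ROH_STATES[kind])
                cursor += spacing_bp
        grids.append(np.array(pos_list))
        state_rows.append(np.array(states, dtype=np.int8))
    for other in grids[1:]:
        if other.shape != grids[0].shape or not np.array_equal(other, grids[0]):
            raise LayoutError("all individual layouts must realise the same marker grid")
    pos = grids[0]
    if np.any(np.diff(pos) <= 0):
        raise LayoutError("tracts overlap: positions are not strictly increasing")

    calls = np.vstack(state_rows)
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{k + 1:04d}" for k in range(pos.size)],
            "chromosome": chromosome,
            "position_bp": pos.astype(int),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = [f"ind_{i + 1:03d}" for i in range(len(individual_layouts))]
    g = GenotypeMatrix(samples=samples, markers=markers, calls=calls)

    truth: list[dict] = []
    for i, states in enumerate(state_rows):
        hom_idx = np.flatnonzero(states == 2)
        if hom_idx.size == 0:
            continue
        run_start = 0
        for k in range(hom_idx.size):
            last = k == hom_idx.size - 1
            broken = (not last) and (
                pos[hom_idx[k + 1]] - pos[hom_idx[k]] > split_gap_bp
                or hom_idx[k + 1] != hom_idx[k] + 1
            )
            if last or broken:
                lo, hi = hom_idx[run_start], hom_idx[k]
                truth.append(
                    {
                        "sample_id": samples[i],
                        "chromosome": chromosome,
                        "start_bp": int(pos[lo]),
                        "end_bp": int(pos[hi]),
                        "n_snps": int(hi - lo + 1),
                    }
                )
                run_start = k + 1
    return g, truth


def make_ld_fixture(
    haplotype_freqs: Sequence[float],
    n_individuals: int,
    seed: int,
    chromosome: str = "1",
    positions: tuple[int, int] = (1_000_000, 1_050_000),
) -> tuple[GenotypeMatrix, dict]:
    """Two-marker cohort drawn from known haplotype frequencies.

    ``haplotype_freqs`` is (f_AB, f_Ab, f_aB, f_ab) where A/B are the
    dosage-counted alleles at the two markers; 2n haplotypes are drawn
    multinomially and paired at random into diploids.  The truth records the
    requested frequencies and the realised haplotype counts.
    """
    f = np.asarray(haplotype_freqs, dtype=float)
    if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype_freqs must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(2 * n_individuals, f)
    # rows: (dose at locus 1, dose at locus 2) per haplotype category
    doses = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
    haps = np.repeat(doses, counts, axis=0)
    rng.shuffle(haps, axis=0)
    calls = haps[0::2] + haps[1::2]
    markers = pd.DataFrame(
        {
            "marker_id": ["mA", "mB"],
            "chromosome": chromosome,
            "position_bp": list(positions),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    g = GenotypeMatrix(
        samples=[f"ind_{i + 1:03d}" for i in range(n_individuals)],
        markers=markers,
        calls=calls,
    )
    truth = {"haplotype_freqs": f, "haplotype_counts": counts}
    return g, truth
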