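"""Pairwise linkage disequilibrium from unphased genotypes.

Two-locus haplotype frequencies are estimated by EM under the multinomial
model in which only double heterozygotes are phase-ambiguous (the classic
Hill 1974 / Excoffier-Slatkin formulation used by Haploview).  D, D' and r2
follow from the fitted frequencies; r2 can further be corrected for sample
size with the haplotype-count correction (r2 - 1/n) / (1 - 1/n).

Conventions
-----------
"A" and "B" denote the dosage-counted allele (``allele_b`` of the marker
map) at the first and second locus of a pair, so ``f_AB`` is the frequency
of the haplotype carrying both counted alleles and D = f_AB - p_A * p_B.
D' is reported as |D'| in [0, 1].
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError, MonomorphicMarkerError
from .genotype_io import MISSING, GenotypeMatrix

#: Distance-class edges in kb, half-open [lo, hi), partitioning [0, 50 Mb).
DEFAULT_BINS_KB: tuple[tuple[float, float], ...] = (
    (0, 20), (20, 40), (40, 60), (60, 100), (100, 200), (200, 500),
    (500, 1000), (1000, 2000), (2000, 5000), (5000, 10000), (10000, 12000),
    (12000, 15000), (15000, 17000), (17000, 20000), (20000, 30000),
    (30000, 50000),
)

EM_TOL = 1e-10
EM_MAX_ITER = 1000


@dataclasses.dataclass
class HaploFreqs:
    """Maximum-likelihood two-locus haplotype frequencies."""

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    log_likelihood: float
    n_iterations: int
    n_informative: int
    converged: bool = True


@dataclasses.dataclass
class PairLD:
    """LD summary for one marker pair (``distance_bp`` is None if non-syntenic)."""

    marker_i: str
    marker_j: str
    chromosome_i: str
    chromosome_j: str
    distance_bp: int | None
    D: float
    D_prime: float
    r2: float
    r2_corrected: float
    n_haplotypes: int
    converged: bool = True


@dataclasses.dataclass
class DecayBin:
    """Aggregated LD for one distance class (or the non-syntenic background)."""

    lo_kb: float | None
    hi_kb: float | None
    n_pairs: int
    mean_D_prime: float
    sd_D_prime: float
    mean_r2: float
    sd_r2: float
    mean_r2_corrected: float
    sd_r2_corrected: float


@dataclasses.dataclass
class ScanStats:
    """Bookkeeping for a pair scan: emitted, skipped, and unconverged pairs."""

    n_pairs: int = 0
    n_skipped: int = 0
    n_unconverged: int = 0


def _counts_3x3(ci: np.ndarray, cj: np.ndarray) -> tuple[np.ndarray, int]:
    informative = (ci != MISSING) & (cj != MISSING)
    n = int(informative.sum())
    idx = ci[informative].astype(np.intp) * 3 + cj[informative].astype(np.intp)
    counts = np.bincount(idx, minlength=9).reshape(3, 3)
    return counts, n


def em_from_counts(
    counts: np.ndarray | Sequence[Sequence[int]],
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HaploFreqs:
    """EM on a 3x3 genotype count table (rows: dosage at locus 1, cols: locus 2).

    Initialised at linkage equilibrium (products of allele frequencies) with a
    tiny coupling perturbation, plus two corner-leaning restarts; the start
    with the best converged log-likelihood wins.  The perturbation breaks the
    exact EM fixed point that the symmetric equilibrium start hits on
    double-heterozygote-only tables.

    Raises
    ------
    InsufficientDataError
        Fewer than two informative individuals.
    MonomorphicMarkerError
        Either locus is monomorphic among the informative individuals.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (3, 3) or (c < 0).any():
        raise ValueError("counts must be a non-negative 3x3 table")
    n = c.sum()
    if n < 2:
        raise InsufficientDataError(
            f"two-locus EM needs >= 2 informative individuals, got {int(n)}"
        )
    n_a1 = 2 * c[2, :].sum() + c[1, :].sum()  # counted-allele count, locus 1
    n_a2 = 2 * c[:, 2].sum() + c[:, 1].sum()
    if n_a1 == 0 or n_a1 == 2 * n or n_a2 == 0 or n_a2 == 2 * n:
        raise MonomorphicMarkerError("a locus is monomorphic among informative calls")

    p1 = n_a1 / (2 * n)
    p2 = n_a2 / (2 * n)
    eps = 1e-6
    le = _normalise(
        (1 - p1) * (1 - p2) + eps,
        (1 - p1) * p2 - eps,
        p1 * (1 - p2) - eps,
        p1 * p2 + eps,
    )
    starts = [le]
    if c[1, 1] > 0:  # phase ambiguity present: guard against the minor mode
        starts.append((0.4, 0.1, 0.1, 0.4))
        starts.append((0.1, 0.4, 0.4, 0.1))
    best: HaploFreqs | None = None
    for start in starts:
        fit = _em_single(c, start, tol, max_iter)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def _normalise(*vals: float) -> tuple[float, ...]:
    clipped = [max(v, 1e-12) for v in vals]
    total = sum(clipped)
    return tuple(v / total for v in clipped)


def _loglik_scalar(c: np.ndarray, f_ab, f_aB, f_Ab, f_AB) -> float:
    probs = (
        (f_ab * f_ab, 2 * f_ab * f_aB, f_aB * f_aB),
        (2 * f_ab * f_Ab, 2 * f_AB * f_ab + 2 * f_Ab * f_aB, 2 * f_aB * f_AB),
        (f_Ab * f_Ab, 2 * f_Ab * f_AB, f_AB * f_AB),
    )
    total = 0.0
    for gi in range(3):
        for gj in range(3):
            cnt = c[gi, gj]
            if cnt > 0:
                p = probs[gi][gj]
                if p <= 0.0:
                    return -math.inf
                total += cnt * math.log(p)
    return total


def _em_single(
    c: np.ndarray, f0: tuple[float, ...], tol: float, max_iter: int
) -> HaploFreqs:
    # unpack the count table once; the loop is pure scalar arithmetic
    c00, c01, c02 = float(c[0, 0]), float(c[0, 1]), float(c[0, 2])
    c10, c11, c12 = float(c[1, 0]), float(c[1, 1]), float(c[1, 2])
    c20, c21, c22 = float(c[2, 0]), float(c[2, 1]), float(c[2, 2])
    n2 = 2.0 * (c00 + c01 + c02 + c10 + c11 + c12 + c20 + c21 + c22)
    f_ab, f_aB, f_Ab, f_AB = f0
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        denom = f_AB * f_ab + f_Ab * f_aB
        w = 0.5 if denom == 0.0 else (f_AB * f_ab) / denom
        e_AB = 2 * c22 + c21 + c12 + w * c11
        e_Ab = 2 * c20 + c21 + c10 + (1 - w) * c11
        e_aB = 2 * c02 + c01 + c12 + (1 - w) * c11
        e_ab = 2 * c00 + c01 + c10 + w * c11
        n_ab, n_aB, n_Ab, n_AB = e_ab / n2, e_aB / n2, e_Ab / n2, e_AB / n2
        delta = max(
            abs(n_ab - f_ab), abs(n_aB - f_aB), abs(n_Ab - f_Ab), abs(n_AB - f_AB)
        )
        f_ab, f_aB, f_Ab, f_AB = n_ab, n_aB, n_Ab, n_AB
        if delta < tol:
            converged = True
            break
    return HaploFreqs(
        f_AB=f_AB,
        f_Ab=f_Ab,
        f_aB=f_aB,
        f_ab=f_ab,
        log_likelihood=_loglik_scalar(c, f_ab, f_aB, f_Ab, f_AB),
        n_iterations=n_iter,
        n_informative=int(round(n2 / 2)),
        converged=converged,
    )


def em_two_locus(
    g: GenotypeMatrix,
    i: int,
    j: int,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HaploFreqs:
    """EM haplotype-frequency estimate for markers at column indices i and j."""
    counts, n = _counts_3x3(g.calls[:, i], g.calls[:, j])
    if n < 2:
        raise InsufficientDataError(
            f"markers {i},{j}: only {n} individuals non-missing at both loci"
        )
    return em_from_counts(counts, tol=tol, max_iter=max_iter)


def ld_from_haplofreqs(h: HaploFreqs) -> tuple[float, float, float]:
    """(D, |D'|, r2) from fitted haplotype frequencies.

    D = f_AB - p_A p_B; D' normalises |D| by its maximum attainable value
    given the allele frequencies; r2 = D^2 / (p_A q_a p_B q_b).
    """
    p_a = h.f_AB + h.f_Ab
    p_b = h.f_AB + h.f_aB
    q_a = 1.0 - p_a
    q_b = 1.0 - p_b
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise MonomorphicMarkerError("marginal allele frequency not in (0, 1)")
    d = h.f_AB - p_a * p_b
    if d >= 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    d_prime = 0.0 if d == 0 else abs(d) / d_max
    r2 = d * d / (p_a * q_a * p_b * q_b)
    return d, min(d_prime, 1.0), min(r2, 1.0)


def correct_r2(r2: float, n_haplotypes: int) -> float:
    """Haplotype-count sample-size correction (r2 - 1/n) / (1 - 1/n).

    Affine and order-preserving; maps 1 -> 1 and 1/n -> 0.  The result may be
    negative for r2 below the 1/n sampling floor and is returned as computed.
    """
    if n_haplotypes < 2:
        raise ValueError("sample-size correction requires n_haplotypes >= 2")
    inv = 1.0 / n_haplotypes
    return (r2 - inv) / (1.0 - inv)


def pair_ld(
    g: GenotypeMatrix,
    i: int,
    j: int,
    n_haplotypes_mode: str = "per_pair",
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> PairLD:
    """Full LD record for one marker pair.

    ``n_haplotypes_mode`` chooses the n of the r2 correction: ``"per_pair"``
    uses 2 x (individuals informative at both loci), ``"global"`` uses
    2 x cohort size (a single n for every pair, as in chip-wide summaries).
    """
    ids = g.markers["marker_id"].to_numpy()
    chroms = g.chromosomes
    pos = g.positions
    return _pair_ld_fast(
        g, ids, chroms, pos, i, j, n_haplotypes_mode, tol, max_iter
    )


def _pair_ld_fast(
    g: GenotypeMatrix,
    ids: np.ndarray,
    chroms: np.ndarray,
    pos: np.ndarray,
    i: int,
    j: int,
    n_haplotypes_mode: str,
    tol: float,
    max_iter: int,
) -> PairLD:
    if n_haplotypes_mode not in ("per_pair", "global"):
        raise ValueError("n_haplotypes_mode must be 'per_pair' or 'global'")
    h = em_two_locus(g, i, j, tol=tol, max_iter=max_iter)
    d, d_prime, r2 = ld_from_haplofreqs(h)
    n_hap = 2 * (g.n_samples if n_haplotypes_mode == "global" else h.n_informative)
    same = chroms[i] == chroms[j]
    return PairLD(
        marker_i=ids[i],
        marker_j=ids[j],
        chromosome_i=chroms[i],
        chromosome_j=chroms[j],
        distance_bp=int(abs(int(pos[j]) - int(pos[i]))) if same else None,
        D=d,
        D_prime=d_prime,
        r2=r2,
        r2_corrected=correct_r2(r2, n_hap),
        n_haplotypes=n_hap,
        converged=h.converged,
    )


def iter_syntenic_pairs(
    g: GenotypeMatrix,
    max_distance_bp: int = 50_000_000,
    n_haplotypes_mode: str = "per_pair",
    stats: ScanStats | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> Iterator[PairLD]:
    """Yield LD for every same-chromosome pair closer than ``max_distance_bp``.

    Pairs failing the EM preconditions (monomorphic locus, < 2 informative
    individuals) are skipped and counted in ``stats``; unconverged EM fits are
    emitted with ``converged=False``.
    """
    stats = stats if stats is not None else ScanStats()
    pos = g.positions
    ids = g.markers["marker_id"].to_numpy()
    chroms = g.chromosomes
    for chrom in g.chromosome_labels():
        idx = g.marker_indices(chrom)
        for a in range(idx.size):
            i = int(idx[a])
            for b in range(a + 1, idx.size):
                j = int(idx[b])
                if abs(int(pos[j]) - int(pos[i])) >= max_distance_bp:
                    # markers sorted within chromosome: no later j is closer
                    break
                try:
                    pair = _pair_ld_fast(
                        g, ids, chroms, pos, i, j, n_haplotypes_mode, tol, max_iter
                    )
                except (InsufficientDataError, MonomorphicMarkerError):
                    stats.n_skipped += 1
                    continue
                stats.n_pairs += 1
                if not pair.converged:
                    stats.n_unconverged += 1
                yield pair


def scan_syntenic_pairs(
    g: GenotypeMatrix,
    max_distance_bp: int = 50_000_000,
    n_haplotypes_mode: str = "per_pair",
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> tuple[list[PairLD], ScanStats]:
    """Materialised version of :func:`iter_syntenic_pairs`."""
    stats = ScanStats()
    pairs = list(
        iter_syntenic_pairs(g, max_distance_bp, n_haplotypes_mode, stats, tol, max_iter)
    )
    return pairs, stats


def _summarise(pairs: Sequence[PairLD], lo_kb=None, hi_kb=None) -> DecayBin:
    def mean_sd(vals: np.ndarray) -> tuple[float, float]:
        if vals.size == 0:
            return math.nan, math.nan
        if vals.size == 1:
            return float(vals[0]), 0.0
        return float(vals.mean()), float(vals.std(ddof=1))

    dp = np.array([p.D_prime for p in pairs])
    r2 = np.array([p.r2 for p in pairs])
    r2c = np.array([p.r2_corrected for p in pairs])
    m_dp, s_dp = mean_sd(dp)
    m_r2, s_r2 = mean_sd(r2)
    m_r2c, s_r2c = mean_sd(r2c)
    return DecayBin(lo_kb, hi_kb, len(pairs), m_dp, s_dp, m_r2, s_r2, m_r2c, s_r2c)


def nonsyntenic_background(
    g: GenotypeMatrix,
    n_snps: int,
    seed: int,
    n_haplotypes_mode: str = "per_pair",
) -> DecayBin:
    """Background LD from a seeded random SNP subset: all inter-chromosome pairs.

    Under independent chromosomes the expected background r2 is roughly
    1/n_haplotypes, the sampling floor of the estimator.
    """
    if n_snps > g.n_markers:
        raise ValueError(f"cannot sample {n_snps} of {g.n_markers} markers")
    if len(g.chromosome_labels()) < 2:
        raise ValueError("non-syntenic background needs markers on >= 2 chromosomes")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(g.n_markers, size=n_snps, replace=False))
    chroms = g.chromosomes
    ids = g.markers["marker_id"].to_numpy()
    pos = g.positions
    pairs: list[PairLD] = []
    for a in range(chosen.size):
        for b in range(a + 1, chosen.size):
            i, j = int(chosen[a]), int(chosen[b])
            if chroms[i] == chroms[j]:
                continue
            try:
                pairs.append(
                    _pair_ld_fast(
                        g, ids, chroms, pos, i, j, n_haplotypes_mode, EM_TOL, EM_MAX_ITER
                    )
                )
            except (InsufficientDataError, MonomorphicMarkerError):
                continue
    return _summarise(pairs)


def bin_decay_table(
    pairs: Iterable[PairLD],
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS_KB,
) -> list[DecayBin]:
    """Aggregate syntenic pairs into half-open distance classes (kb).

    Each pair lands in the unique bin with lo_kb <= distance < hi_kb; bins
    that attract no pairs are reported with ``n_pairs=0``.  Overlapping or
    unsorted bins raise :class:`ConfigError`.
    """
    bins = list(bins)
    for (lo, hi) in bins:
        if hi <= lo:
            raise ConfigError(f"empty or inverted bin ({lo}, {hi})")
    for (lo1, hi1), (lo2, _hi2) in zip(bins, bins[1:]):
        if lo2 < hi1:
            raise ConfigError(f"bins overlap or are unsorted at ({lo1},{hi1})/({lo2},..)")

    edges = np.array([lo for lo, _ in bins] + [bins[-1][1]], dtype=float)
    contiguous = all(hi == lo2 for (_, hi), (lo2, _) in zip(bins, bins[1:]))
    members: list[list[PairLD]] = [[] for _ in bins]
    for p in pairs:
        if p.distance_bp is None:
            continue
        kb = p.distance_bp / 1000.0
        if contiguous:
            k = int(np.searchsorted(edges, kb, side="right")) - 1
            if 0 <= k < len(bins):
                members[k].append(p)
        else:
            for k, (lo, hi) in enumerate(bins):
                if lo <= kb < hi:
                    members[k].append(p)
                    break
    return [_summarise(m, lo, hi) for m, (lo, hi) in zip(members, bins)]


def adjacent_pairs(
    g: GenotypeMatrix,
    n_haplotypes_mode: str = "per_pair",
    stats: ScanStats | None = None,
) -> list[PairLD]:
    """LD for consecutive marker pairs within each chromosome."""
    stats = stats if stats is not None else ScanStats()
    ids = g.markers["marker_id"].to_numpy()
    chroms = g.chromosomes
    pos = g.positions
    out: list[PairLD] = []
    for chrom in g.chromosome_labels():
        idx = g.marker_indices(chrom)
        for a, b in zip(idx, idx[1:]):
            try:
                out.append(
                    _pair_ld_fast(
                        g, ids, chroms, pos, int(a), int(b), n_haplotypes_mode,
                        EM_TOL, EM_MAX_ITER,
                    )
                )
            except (InsufficientDataError, MonomorphicMarkerError):
                stats.n_skipped += 1
                continue
            stats.n_pairs += 1
    return out


def cross_chromosome_mean(values: Iterable[float]) -> float:
    """Unweighted mean across per-chromosome summary values."""
    vals = np.asarray(list(values), dtype=float)
    return float(vals.mean())


def adjacent_summary(
    g: GenotypeMatrix,
    pairs: Sequence[PairLD] | None = None,
    n_haplotypes_mode: str = "per_pair",
) -> pd.DataFrame:
    """Per-chromosome adjacent-pair LD table plus an unweighted "Mean" row.

    Columns: pair count, mean/sd inter-marker distance (kb), mean/sd |D'|,
    mean/sd r2, and the percentage of pairs with r2 > 0.2 and > 0.8.
    Chromosomes contributing no computable pair are excluded with a warning.
    """
    import warnings

    if pairs is None:
        pairs = adjacent_pairs(g, n_haplotypes_mode)
    by_chrom: dict[str, list[PairLD]] = {}
    for p in pairs:
        by_chrom.setdefault(p.chromosome_i, []).append(p)

    rows = []
    for chrom in g.chromosome_labels():
        plist = by_chrom.get(chrom, [])
        if not plist:
            warnings.warn(f"chromosome {chrom}: no adjacent pair computable; excluded")
            continue
        dist = np.array([p.distance_bp for p in plist], dtype=float) / 1000.0
        dp = np.array([p.D_prime for p in plist])
        r2 = np.array([p.r2 for p in plist])
        sd = lambda v: float(v.std(ddof=1)) if v.size > 1 else 0.0  # noqa: E731
        rows.append(
            {
                "chromosome": chrom,
                "n_pairs": len(plist),
                "mean_distance_kb": float(dist.mean()),
                "sd_distance_kb": sd(dist),
                "mean_D_prime": float(dp.mean()),
                "sd_D_prime": sd(dp),
                "mean_r2": float(r2.mean()),
                "sd_r2": sd(r2),
                "pct_r2_gt_0.2": float((r2 > 0.2).mean() * 100.0),
                "pct_r2_gt_0.8": float((r2 > 0.8).mean() * 100.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        mean_row = {"chromosome": "Mean", "n_pairs": int(table["n_pairs"].sum())}
        for col in table.columns:
            if col not in ("chromosome", "n_pairs"):
                mean_row[col] = cross_chromosome_mean(table[col])
        table = pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
    return table
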