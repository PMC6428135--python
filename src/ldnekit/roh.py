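"""Runs of homozygosity by the PLINK-style sliding-window scan.

Per individual and chromosome, a fixed-size SNP window slides one marker at
a time; a window "passes" when it contains at most ``max_missing_in_window``
missing and ``max_het_in_window`` heterozygous calls.  Each SNP's hit rate
is the fraction of windows containing it that pass; SNPs at or above
``hit_proportion`` are candidate-homozygous.  Maximal candidate stretches
are split at inter-marker gaps above ``max_gap_bp``, trimmed so both ends
are homozygous non-missing calls, and emitted if they meet the length,
SNP-count and density rules.  Detection only inspects heterozygosity and
missingness, so it is invariant under allele relabelling (0 <-> 2).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import MISSING, GenotypeMatrix

#: Length classes (Mb, half-open) used to histogram segments.
LENGTH_CLASSES_MB: tuple[tuple[float, float, str], ...] = (
    (1, 5, "1 to 4.999 Mb"),
    (5, 10, "5 to 9.999 Mb"),
    (10, 15, "10 to 14.999 Mb"),
    (15, 20, "15 to 19.999 Mb"),
    (20, 25, "20 to 24.999 Mb"),
    (25, 50, "25 to 49.999 Mb"),
    (50, math.inf, ">50 Mb"),
)


@dataclasses.dataclass
class ROHParams:
    """Detection thresholds; defaults are the published medium-density settings."""

    window_snps: int = 20
    max_missing_in_window: int = 5
    max_het_in_window: int = 1
    min_length_bp: int = 1_000_000
    min_snps: int = 20
    min_density_bp_per_snp: int = 200_000
    max_gap_bp: int = 1_000_000
    hit_proportion: float = 0.05

    def __post_init__(self) -> None:
        if min(
            self.window_snps, self.min_length_bp, self.min_snps,
            self.min_density_bp_per_snp, self.max_gap_bp,
        ) <= 0 or min(self.max_missing_in_window, self.max_het_in_window) < 0:
            raise ValueError("ROH parameters must be positive")
        if not (0 < self.hit_proportion <= 1):
            raise ValueError("hit_proportion must lie in (0, 1]")


@dataclasses.dataclass
class ROHSegment:
    """One homozygous run; coordinates are 1-based inclusive SNP positions."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    length_class: str

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def classify_length(length_bp: int) -> str:
    """Length-class label for a segment.

    The published scheme starts at 1 Mb; segments below it (possible only
    when the minimum-length rule is relaxed) fall in a ``<1 Mb`` class.
    """
    mb = length_bp / 1e6
    for lo, hi, label in LENGTH_CLASSES_MB:
        if lo <= mb < hi:
            return label
    return "<1 Mb"


def _window_hit_rates(
    het: np.ndarray, miss: np.ndarray, params: ROHParams
) -> np.ndarray:
    """Per-SNP fraction of passing windows among windows containing the SNP."""
    m = het.size
    w = params.window_snps
    kernel = np.ones(w)
    het_in_win = np.convolve(het.astype(float), kernel, mode="valid")
    miss_in_win = np.convolve(miss.astype(float), kernel, mode="valid")
    passing = (
        (het_in_win <= params.max_het_in_window)
        & (miss_in_win <= params.max_missing_in_window)
    ).astype(float)
    # windows containing SNP k start at s in [max(0, k-w+1), min(k, m-w)]
    hits = np.convolve(passing, kernel, mode="full")[: m]
    k = np.arange(m)
    totals = np.minimum(k, m - w) - np.maximum(0, k - w + 1) + 1
    return hits / totals


def detect_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH segments for every individual on every chromosome."""
    params = params if params is not None else ROHParams()
    segments: list[ROHSegment] = []
    pos_all = g.positions
    warned: set[str] = set()
    for chrom in g.chromosome_labels():
        idx = g.marker_indices(chrom)
        if idx.size < params.window_snps:
            if chrom not in warned:
                warnings.warn(
                    f"chromosome {chrom}: {idx.size} markers < window of "
                    f"{params.window_snps} SNPs; skipped"
                )
                warned.add(chrom)
            continue
        pos = pos_all[idx].astype(np.int64)
        gaps = np.diff(pos)
        for s, sample in enumerate(g.samples):
            calls = g.calls[s, idx]
            het = calls == 1
            miss = calls == MISSING
            rates = _window_hit_rates(het, miss, params)
            candidate = rates >= params.hit_proportion
            segments.extend(
                _emit_segments(sample, chrom, pos, gaps, calls, candidate, params)
            )
    return segments


def _emit_segments(
    sample: str,
    chrom: str,
    pos: np.ndarray,
    gaps: np.ndarray,
    calls: np.ndarray,
    candidate: np.ndarray,
    params: ROHParams,
) -> list[ROHSegment]:
    out: list[ROHSegment] = []
    m = candidate.size
    k = 0
    while k < m:
        if not candidate[k]:
            k += 1
            continue
        end = k
        while end + 1 < m and candidate[end + 1]:
            end += 1
        # split the maximal candidate stretch at oversized gaps
        piece_start = k
        for cut in range(k, end + 1):
            boundary = cut == end or gaps[cut] > params.max_gap_bp
            if boundary:
                seg = _trim_and_check(
                    sample, chrom, pos, calls, piece_start, cut, params
                )
                if seg is not None:
                    out.append(seg)
                piece_start = cut + 1
        k = end + 1
    return out


def _trim_and_check(
    sample: str,
    chrom: str,
    pos: np.ndarray,
    calls: np.ndarray,
    lo: int,
    hi: int,
    params: ROHParams,
) -> ROHSegment | None:
    hom = (calls == 0) | (calls == 2)
    while lo <= hi and not hom[lo]:
        lo += 1
    while hi >= lo and not hom[hi]:
        hi -= 1
    if hi < lo:
        return None
    n_snps = hi - lo + 1
    length = int(pos[hi] - pos[lo]) + 1
    if n_snps < params.min_snps:
        return None
    if length < params.min_length_bp:
        return None
    if length / n_snps > params.min_density_bp_per_snp:
        return None
    return ROHSegment(
        sample_id=sample,
        chromosome=chrom,
        start_bp=int(pos[lo]),
        end_bp=int(pos[hi]),
        n_snps=n_snps,
        length_class=classify_length(length),
    )


def classify_roh(segments: Iterable[ROHSegment]) -> dict[str, int]:
    """Segment counts per length class (all classes present, zeros included)."""
    counts = {label: 0 for _, _, label in LENGTH_CLASSES_MB}
    for seg in segments:
        counts[classify_length(seg.length_bp)] += 1
    return counts


@dataclasses.dataclass
class ROHSummary:
    """Cohort-level ROH summaries."""

    per_individual: pd.DataFrame
    per_chromosome: pd.DataFrame
    mean_genome_fraction: float
    correlations: dict[str, tuple[float, int, float] | None]


def roh_summaries(
    segments: Sequence[ROHSegment],
    g: GenotypeMatrix | None = None,
    chromosome_lengths: Mapping[str, int] | None = None,
    adjacent_r2: Mapping[str, float] | None = None,
) -> ROHSummary:
    """Per-individual and per-chromosome ROH summaries and correlations.

    Chromosome lengths default to the maximum mapped position per chromosome
    of ``g``; pass ``chromosome_lengths`` to override.  Genome fraction per
    individual is total ROH length over total autosome length.  Pearson
    correlations of per-chromosome ROH count and summed length against
    chromosome length (and against ``adjacent_r2`` when given) are reported
    as (r, n, p), or None when undefined (< 3 chromosomes or zero variance).
    """
    if chromosome_lengths is None:
        if g is None:
            raise ValueError(
                "chromosome lengths unavailable: pass the genotype matrix or "
                "supply chromosome_lengths explicitly"
            )
        chromosome_lengths = {
            chrom: int(g.positions[g.marker_indices(chrom)].max())
            for chrom in g.chromosome_labels()
        }
    genome_bp = float(sum(chromosome_lengths.values()))

    samples = list(g.samples) if g is not None else sorted(
        {seg.sample_id for seg in segments}
    )
    per_ind_count = {s: 0 for s in samples}
    per_ind_len = {s: 0 for s in samples}
    for seg in segments:
        per_ind_count.setdefault(seg.sample_id, 0)
        per_ind_len.setdefault(seg.sample_id, 0)
        per_ind_count[seg.sample_id] += 1
        per_ind_len[seg.sample_id] += seg.length_bp
    per_individual = pd.DataFrame(
        {
            "sample_id": list(per_ind_count),
            "n_segments": list(per_ind_count.values()),
            "total_bp": list(per_ind_len.values()),
        }
    )
    per_individual["genome_fraction"] = per_individual["total_bp"] / genome_bp

    chroms = list(chromosome_lengths)
    per_chrom_count = {c: 0 for c in chroms}
    per_chrom_len = {c: 0 for c in chroms}
    for seg in segments:
        per_chrom_count.setdefault(seg.chromosome, 0)
        per_chrom_len.setdefault(seg.chromosome, 0)
        per_chrom_count[seg.chromosome] += 1
        per_chrom_len[seg.chromosome] += seg.length_bp
    per_chromosome = pd.DataFrame(
        {
            "chromosome": list(per_chrom_count),
            "n_segments": list(per_chrom_count.values()),
            "total_bp": list(per_chrom_len.values()),
            "length_bp": [
                chromosome_lengths.get(c, np.nan) for c in per_chrom_count
            ],
        }
    )

    def corr(x: np.ndarray, y: np.ndarray):
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            return None
        r, p = sps.pearsonr(x, y)
        return (float(r), int(x.size), float(p))

    lengths = per_chromosome["length_bp"].to_numpy(dtype=float)
    correlations: dict[str, tuple[float, int, float] | None] = {
        "count_vs_chrom_length": corr(
            lengths, per_chromosome["n_segments"].to_numpy(dtype=float)
        ),
        "total_bp_vs_chrom_length": corr(
            lengths, per_chromosome["total_bp"].to_numpy(dtype=float)
        ),
    }
    if adjacent_r2 is not None:
        common = [c for c in per_chromosome["chromosome"] if c in adjacent_r2]
        sub = per_chromosome.set_index("chromosome").loc[common]
        r2 = np.array([adjacent_r2[c] for c in common], dtype=float)
        correlations["count_vs_adjacent_r2"] = corr(
            r2, sub["n_segments"].to_numpy(dtype=float)
        )
        correlations["total_bp_vs_adjacent_r2"] = corr(
            r2, sub["total_bp"].to_numpy(dtype=float)
        )

    mean_fraction = (
        float(per_individual["genome_fraction"].mean()) if len(per_individual) else 0.0
    )
    return ROHSummary(
        per_individual=per_individual,
        per_chromosome=per_chromosome,
        mean_genome_fraction=mean_fraction,
        correlations=correlations,
    )
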