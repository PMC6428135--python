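"""Marker and sample quality control for SNP-array genotypes.

The cascade mirrors standard SNP-chip practice: sample call-rate filter,
then marker call-rate filter, then a Hardy-Weinberg exact test, then minor
allele frequency thresholding, with optional random thinning so datasets
filtered at different MAF cut-offs can be compared at equal marker counts.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import field

import numpy as np

from .errors import EmptyCohortError
from .genotype_io import MISSING, GenotypeMatrix


@dataclasses.dataclass
class HWEResult:
    """Genotype counts and the exact Hardy-Weinberg equilibrium p-value."""

    n_hom_a: int
    n_het: int
    n_hom_b: int
    p_value: float


@dataclasses.dataclass
class QCReport:
    """Accounting of what each QC stage removed and retained.

    ``stage_counts`` records ``(stage, n_samples, n_markers)`` after each
    stage, starting at ``("input", ...)``, so counts telescope.
    """

    samples_removed: list[tuple[str, str]] = field(default_factory=list)
    markers_removed: dict[str, int] = field(default_factory=dict)
    markers_retained: dict[str, int] = field(default_factory=dict)
    stage_counts: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, stage: str, g: GenotypeMatrix) -> None:
        self.stage_counts.append((stage, g.n_samples, g.n_markers))


def call_rate_filter(
    g: GenotypeMatrix,
    sample_min: float = 0.9,
    marker_min: float = 0.9,
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples, then markers, whose call rate is strictly below threshold.

    Samples are filtered first; marker call rates are then recomputed on the
    surviving samples, matching the usual order of SNP-chip QC.
    """
    if not (0 <= sample_min <= 1 and 0 <= marker_min <= 1):
        raise ValueError("call-rate thresholds must lie in [0, 1]")
    report = report if report is not None else QCReport()
    if not report.stage_counts:
        report.record("input", g)

    sample_rates = g.sample_call_rate()
    keep_samples = np.flatnonzero(sample_rates >= sample_min)
    for i in np.flatnonzero(sample_rates < sample_min):
        report.samples_removed.append(
            (g.samples[i], f"call rate {sample_rates[i]:.4f} < {sample_min}")
        )
    if keep_samples.size == 0:
        raise EmptyCohortError(
            f"sample call-rate filter at {sample_min} removed all {g.n_samples} samples"
        )
    g = g.take_samples(keep_samples)
    report.record("sample_call_rate", g)

    marker_rates = g.marker_call_rate()
    keep_markers = np.flatnonzero(marker_rates >= marker_min)
    report.markers_removed["marker_call_rate"] = g.n_markers - keep_markers.size
    g = g.take_markers(keep_markers)
    report.record("marker_call_rate", g)
    return g, report


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> HWEResult:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts with the right parity, the probabilities of configurations no more
    probable than the observed one (probability-ordering, no mid-p).
    The p-value is symmetric in ``n_hom_a`` and ``n_hom_b``.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n < 1:
        raise ValueError("at least one genotyped individual is required")
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    if n_a == 0 or n_b == 0:  # monomorphic: single attainable configuration
        return HWEResult(n_hom_a, n_het, n_hom_b, 1.0)

    hets = range(n_a % 2, min(n_a, n_b) + 1, 2)
    log_weights = []
    for h in hets:
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        log_weights.append(
            h * math.log(2.0)
            - math.lgamma(a + 1)
            - math.lgamma(h + 1)
            - math.lgamma(b + 1)
        )
    lw = np.array(log_weights)
    lw -= lw.max()
    probs = np.exp(lw)
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_het)]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return HWEResult(n_hom_a, n_het, n_hom_b, min(p, 1.0))


def hwe_test_markers(g: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value per marker (1.0 for monomorphic or fully missing)."""
    pvals = np.ones(g.n_markers)
    for k in range(g.n_markers):
        col = g.calls[:, k]
        obs = col[col != MISSING]
        if obs.size == 0:
            continue
        n_hom_a = int((obs == 0).sum())
        n_het = int((obs == 1).sum())
        n_hom_b = int((obs == 2).sum())
        pvals[k] = hwe_exact_test(n_hom_a, n_het, n_hom_b).p_value
    return pvals


def hwe_filter(
    g: GenotypeMatrix, p_threshold: float = 0.01, report: QCReport | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers whose exact HWE p-value is below ``p_threshold``."""
    report = report if report is not None else QCReport()
    pvals = hwe_test_markers(g)
    keep = np.flatnonzero(pvals >= p_threshold)
    report.markers_removed["hwe"] = g.n_markers - keep.size
    g = g.take_markers(keep)
    report.record("hwe", g)
    return g, report


def maf_filter(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Retain markers with minor allele frequency >= ``threshold``.

    Frequencies are computed on non-missing calls; fully-missing markers are
    removed for any positive threshold.
    """
    if not (0 <= threshold <= 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    maf = g.minor_allele_freq()
    with np.errstate(invalid="ignore"):
        keep = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) >= threshold)
    return g.take_markers(keep)


def thin_markers(g: GenotypeMatrix, target_count: int, seed: int) -> GenotypeMatrix:
    """Uniform random subset of ``target_count`` markers, map order preserved."""
    if target_count > g.n_markers:
        raise ValueError(
            f"cannot thin to {target_count} markers: only {g.n_markers} available"
        )
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(g.n_markers, size=target_count, replace=False))
    return g.take_markers(keep)


def qc_pipeline(
    g: GenotypeMatrix,
    sample_min: float = 0.9,
    marker_min: float = 0.9,
    hwe_p: float = 0.01,
    maf: float | None = None,
    thin_to: int | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full cascade: call rates -> HWE -> MAF -> optional thinning."""
    report = QCReport()
    report.record("input", g)
    g, report = call_rate_filter(g, sample_min, marker_min, report)
    g, report = hwe_filter(g, hwe_p, report)
    if maf is not None:
        before = g.n_markers
        g = maf_filter(g, maf)
        report.markers_removed[f"maf_{maf}"] = before - g.n_markers
        report.markers_retained[f"maf_{maf}"] = g.n_markers
        report.record(f"maf_{maf}", g)
    if thin_to is not None:
        before = g.n_markers
        g = thin_markers(g, thin_to, seed)
        report.markers_removed["thinning"] = before - g.n_markers
        report.record("thinning", g)
    return g, report
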