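"""Historical effective population size from distance-binned LD.

Each inter-marker distance class yields one point estimate: with Sved's
mapping f(c) = d(1 - d/2) converting physical distance d (Morgans, at a
uniform 1 cM/Mb so 1 bp = 1e-8 Morgans) into a recombination fraction, the
expected equilibrium LD E(r2) = 1 / (1 + 4 N f(c)) is inverted as

    N_T(t) = 1 / (4 f(c)) * (1 / E(r2_adj | c) - a),

where r2_adj = r2 - 1/(2N_ind) removes the finite-sample inflation of r2
(N_ind diploid individuals) and the constant ``a`` accounts for mutation
(a=1 here).  The estimate for a bin refers to t = 1/(2 f(c)) generations
ago, so short distances probe the ancient population and long distances the
recent one.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np

from .errors import ConfigError, UndefinedEstimateError
from .ld import PairLD


@dataclasses.dataclass
class MappingSpec:
    """Distance-to-recombination mapping configuration."""

    morgans_per_bp: float = 1e-8
    mapping: str = "sved"
    mutation_constant_a: float = 1.0

    def __post_init__(self) -> None:
        if self.morgans_per_bp <= 0:
            raise ValueError("morgans_per_bp must be positive")
        if self.mapping != "sved":
            raise ValueError(f"unsupported mapping {self.mapping!r}")


@dataclasses.dataclass
class NeEstimate:
    """One (generations-ago, Ne) point from one distance bin.

    ``Ne`` is None when the bin is empty or its mean adjusted r2 cannot be
    inverted (the ``note`` says why).
    """

    bin_lo_bp: int
    bin_hi_bp: int
    mean_distance_bp: float
    c: float
    t_generations: float
    mean_r2_adj: float
    Ne: float | None
    n_pairs: int
    note: str = ""


def sved_mapping(distance_bp: float, spec: MappingSpec | None = None) -> tuple[float, float]:
    """(d in Morgans, recombination fraction f(c) = d(1 - d/2)) for a distance."""
    spec = spec if spec is not None else MappingSpec()
    if distance_bp < 0:
        raise ValueError("distance must be non-negative")
    d = distance_bp * spec.morgans_per_bp
    if d > 2:
        raise ValueError(
            f"distance of {d:.3f} Morgans exceeds the mapping's support "
            f"(max {2 / spec.morgans_per_bp:.0f} bp at this map density)"
        )
    return d, d * (1.0 - d / 2.0)


def adjust_r2(r2: float, n_individuals: int) -> float:
    """Sampling-bias adjustment r2 - 1/(2N) for N diploid individuals.

    May be negative; negative values are flagged by the caller and excluded
    from bin means.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    return r2 - 1.0 / (2.0 * n_individuals)


def ne_point(mean_r2_adj: float, f_c: float, a: float = 1.0) -> float:
    """Invert the Sved expectation: Ne = (1 / (4 f_c)) (1 / mean_r2_adj - a)."""
    if f_c <= 0:
        raise UndefinedEstimateError("recombination fraction must be positive")
    if mean_r2_adj <= 0:
        raise UndefinedEstimateError("mean adjusted r2 must be positive")
    if 1.0 / mean_r2_adj - a <= 0:
        raise UndefinedEstimateError(
            f"mean adjusted r2 {mean_r2_adj:.4f} is at or above the 1/a ceiling"
        )
    return (1.0 / (4.0 * f_c)) * (1.0 / mean_r2_adj - a)


def geometric_bin_edges(
    min_distance_bp: float, max_distance_bp: float, n_bins: int
) -> np.ndarray:
    if not (0 < min_distance_bp < max_distance_bp):
        raise ConfigError("need 0 < min distance < max distance")
    if n_bins < 1:
        raise ConfigError("need at least one bin")
    return np.geomspace(min_distance_bp, max_distance_bp, n_bins + 1)


def ne_trajectory(
    pairs: Sequence[PairLD],
    spec: MappingSpec | None = None,
    n_individuals: int | None = None,
    bin_edges: Sequence[float] | None = None,
    n_bins: int = 14,
    min_distance_bp: float = 20_000,
    max_distance_bp: float = 50_000_000,
) -> list[NeEstimate]:
    """Ne at a ladder of past generations from distance-binned adjusted r2.

    Pairs are assigned to half-open distance bins (geometric spacing by
    default); per bin the mean of r2_adj = r2 - 1/(2N) over member pairs is
    inverted through :func:`ne_point` at the bin's arithmetic mean distance.
    Pairs whose adjusted r2 is negative are excluded from the means.  Bins
    that are empty or uninvertible are reported with ``Ne=None`` rather than
    dropped.  Rows are sorted by increasing t (decreasing distance).
    """
    spec = spec if spec is not None else MappingSpec()
    if n_individuals is None:
        raise ValueError("n_individuals (diploid sample size) is required")
    if bin_edges is None:
        bin_edges = geometric_bin_edges(min_distance_bp, max_distance_bp, n_bins)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ConfigError("bin edges must be increasing with at least two values")

    dists: list[list[float]] = [[] for _ in range(edges.size - 1)]
    r2adj: list[list[float]] = [[] for _ in range(edges.size - 1)]
    for p in pairs:
        if p.distance_bp is None:
            continue
        d = float(p.distance_bp)
        if not (edges[0] <= d < edges[-1]):
            continue
        k = int(np.searchsorted(edges, d, side="right")) - 1
        adj = adjust_r2(p.r2, n_individuals)
        if adj < 0:
            continue  # flagged: below the sampling floor
        dists[k].append(d)
        r2adj[k].append(adj)

    a = spec.mutation_constant_a
    rows: list[NeEstimate] = []
    for k in range(edges.size - 1):
        lo, hi = int(edges[k]), int(edges[k + 1])
        if not dists[k]:
            mid = math.sqrt(edges[k] * edges[k + 1])
            _, f_c = sved_mapping(mid, spec)
            rows.append(
                NeEstimate(lo, hi, mid, f_c, 1.0 / (2.0 * f_c), math.nan, None,
                           0, note="no pairs in bin")
            )
            continue
        mean_d = float(np.mean(dists[k]))
        mean_adj = float(np.mean(r2adj[k]))
        _, f_c = sved_mapping(mean_d, spec)
        t = 1.0 / (2.0 * f_c)
        try:
            ne = ne_point(mean_adj, f_c, a)
            note = ""
        except UndefinedEstimateError as exc:
            ne = None
            note = str(exc)
        rows.append(
            NeEstimate(lo, hi, mean_d, f_c, t, mean_adj, ne, len(dists[k]), note)
        )
    rows.sort(key=lambda r: r.t_generations)
    return rows
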