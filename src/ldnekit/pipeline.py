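"""End-to-end orchestration: QC -> LD -> ROH -> Ne, with report tables.

``run_all`` executes the whole cascade once per MAF threshold and writes
tab-delimited tables: a distance-binned LD decay table, per-chromosome
adjacent-pair tables, ROH segment/summary tables, and an Ne trajectory
table with one column per MAF dataset plus their mean.  A JSON manifest
records seeds, versions and per-stage counts so every report number is
recomputable from stage outputs.  Reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from dataclasses import field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .errors import AlignmentError
from .genotype_io import (
    BOVINE_AUTOSOMES,
    GenotypeMatrix,
    filter_autosomes,
    read_ped_map,
)
from .ld import (
    DEFAULT_BINS_KB,
    DecayBin,
    adjacent_summary,
    bin_decay_table,
    nonsyntenic_background,
    scan_syntenic_pairs,
)
from .ne import MappingSpec, NeEstimate, ne_trajectory
from .qc import call_rate_filter, hwe_filter, maf_filter, thin_markers, QCReport
from .roh import ROHParams, detect_roh, roh_summaries


@dataclasses.dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    ped_path: str
    map_path: str
    out_dir: str
    autosomes: tuple[str, ...] = BOVINE_AUTOSOMES
    sample_call_rate: float = 0.9
    marker_call_rate: float = 0.9
    hwe_p: float = 0.01
    maf_thresholds: tuple[float, ...] = (0.01, 0.05, 0.1)
    thin_to_smallest: bool = True
    ld_max_distance_bp: int = 50_000_000
    bins_kb: tuple[tuple[float, float], ...] = DEFAULT_BINS_KB
    nonsyntenic_n: int | None = None
    n_haplotypes_mode: str = "global"
    roh_params: ROHParams = field(default_factory=ROHParams)
    mapping: MappingSpec = field(default_factory=MappingSpec)
    ne_n_bins: int = 14
    ne_min_distance_bp: int = 20_000
    ne_max_distance_bp: int = 50_000_000
    seed: int = 0


def _maf_label(t: float) -> str:
    return f"maf{t:g}"


def _decay_frame(
    per_maf: Mapping[str, list[DecayBin]],
    background: Mapping[str, DecayBin] | None = None,
) -> pd.DataFrame:
    """Decay-table layout: one row per distance class, stat columns per MAF."""
    labels = list(per_maf)
    bins = per_maf[labels[0]]
    rows = []
    for k, b in enumerate(bins):
        row: dict = {"distance_class_kb": f"{b.lo_kb:g}-{b.hi_kb:g}"}
        for lab in labels:
            bb = per_maf[lab][k]
            row[f"n_pairs_{lab}"] = bb.n_pairs
            row[f"mean_D_prime_{lab}"] = round(bb.mean_D_prime, 3)
            row[f"mean_r2_{lab}"] = round(bb.mean_r2, 3)
            row[f"mean_r2_corrected_{lab}"] = round(bb.mean_r2_corrected, 3)
        rows.append(row)
    if background:
        row = {"distance_class_kb": "non-syntenic"}
        for lab in labels:
            bb = background[lab]
            row[f"n_pairs_{lab}"] = bb.n_pairs
            row[f"mean_D_prime_{lab}"] = round(bb.mean_D_prime, 3)
            row[f"mean_r2_{lab}"] = round(bb.mean_r2, 3)
            row[f"mean_r2_corrected_{lab}"] = round(bb.mean_r2_corrected, 3)
        rows.append(row)
    return pd.DataFrame(rows)


def mean_trajectory(
    trajectories: Sequence[Sequence[NeEstimate]], ndigits: int | None = 0
) -> list[dict]:
    """Per-generation unweighted mean Ne across datasets sharing a bin grid.

    Every trajectory must use identical distance bins; otherwise an
    :class:`AlignmentError` is raised.  Rows where any dataset is undefined
    yield a None mean.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    first = trajectories[0]
    for traj in trajectories[1:]:
        if len(traj) != len(first) or any(
            (a.bin_lo_bp, a.bin_hi_bp) != (b.bin_lo_bp, b.bin_hi_bp)
            for a, b in zip(traj, first)
        ):
            raise AlignmentError("trajectories do not share the same bin grid")
    rows = []
    for k in range(len(first)):
        points = [traj[k] for traj in trajectories]
        nes = [p.Ne for p in points]
        if any(ne is None for ne in nes):
            mean_ne = None
        else:
            mean_ne = float(np.mean(nes))
            if ndigits is not None:
                mean_ne = round(mean_ne, ndigits) if ndigits else int(round(mean_ne))
        rows.append(
            {
                "bin_lo_bp": first[k].bin_lo_bp,
                "bin_hi_bp": first[k].bin_hi_bp,
                "t_generations": float(np.mean([p.t_generations for p in points])),
                "mean_Ne": mean_ne,
            }
        )
    return rows


def correlation_summaries(
    chromosome_lengths: Mapping[str, float],
    ld_means: Mapping[str, float] | None = None,
    roh_counts: Mapping[str, float] | None = None,
    roh_sums: Mapping[str, float] | None = None,
) -> dict[str, tuple[float, int, float] | None]:
    """Pearson correlations among per-chromosome summaries.

    All provided mappings must cover exactly the chromosomes of
    ``chromosome_lengths``; a mismatch raises :class:`AlignmentError`.
    Each result is (r, n, two-sided p), or None when fewer than three
    chromosomes (or zero variance) make the correlation undefined.
    """
    chroms = list(chromosome_lengths)
    named = {"ld_means": ld_means, "roh_counts": roh_counts, "roh_sums": roh_sums}
    for name, mapping in named.items():
        if mapping is not None and set(mapping) != set(chroms):
            raise AlignmentError(
                f"{name} chromosome set does not match chromosome_lengths"
            )

    def corr(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            return None
        r, p = sps.pearsonr(x, y)
        return (float(r), int(x.size), float(p))

    lengths = [chromosome_lengths[c] for c in chroms]
    out: dict[str, tuple[float, int, float] | None] = {}
    if ld_means is not None:
        out["ld_vs_chrom_length"] = corr(lengths, [ld_means[c] for c in chroms])
    if roh_counts is not None:
        out["roh_count_vs_chrom_length"] = corr(lengths, [roh_counts[c] for c in chroms])
    if roh_sums is not None:
        out["roh_sum_vs_chrom_length"] = corr(lengths, [roh_sums[c] for c in chroms])
    if ld_means is not None and roh_sums is not None:
        out["ld_vs_roh_sum"] = corr(
            [ld_means[c] for c in chroms], [roh_sums[c] for c in chroms]
        )
    return out


def run_all(cfg: RunConfig, g: GenotypeMatrix | None = None) -> dict:
    """Execute every stage per MAF threshold and write report tables.

    Returns the manifest (also written as ``manifest.json``); tables land in
    ``cfg.out_dir``.  Any stage failure propagates with the stage named.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "tables": [],
    }

    def stage(name: str):
        manifest["stages"].setdefault(name, {})
        return manifest["stages"][name]

    if g is None:
        g = read_ped_map(cfg.ped_path, cfg.map_path)
    g = filter_autosomes(g, cfg.autosomes)
    stage("input")["n_samples"] = g.n_samples
    stage("input")["n_markers"] = g.n_markers

    report = QCReport()
    report.record("input", g)
    g, report = call_rate_filter(g, cfg.sample_call_rate, cfg.marker_call_rate, report)
    g_base, report = hwe_filter(g, cfg.hwe_p, report)
    stage("qc")["stage_counts"] = [list(t) for t in report.stage_counts]
    stage("qc")["samples_removed"] = [list(t) for t in report.samples_removed]
    stage("qc")["markers_removed"] = dict(report.markers_removed)

    # --- MAF datasets (thinned to a common size for comparability) -------
    datasets: dict[str, GenotypeMatrix] = {}
    for t in cfg.maf_thresholds:
        datasets[_maf_label(t)] = maf_filter(g_base, t)
    if cfg.thin_to_smallest and datasets:
        target = min(d.n_markers for d in datasets.values())
        datasets = {
            lab: (thin_markers(d, target, cfg.seed) if d.n_markers > target else d)
            for lab, d in datasets.items()
        }
    stage("maf_datasets")["n_markers"] = {
        lab: d.n_markers for lab, d in datasets.items()
    }

    # --- LD decay + adjacent summaries per MAF ---------------------------
    decay_per_maf: dict[str, list[DecayBin]] = {}
    background: dict[str, DecayBin] = {}
    trajectories: list[list[NeEstimate]] = []
    pair_counts: dict[str, dict] = {}
    for lab, d in datasets.items():
        pairs, scan_stats = scan_syntenic_pairs(
            d, cfg.ld_max_distance_bp, cfg.n_haplotypes_mode
        )
        pair_counts[lab] = {
            "n_pairs": scan_stats.n_pairs,
            "n_skipped": scan_stats.n_skipped,
            "n_unconverged": scan_stats.n_unconverged,
        }
        decay_per_maf[lab] = bin_decay_table(pairs, cfg.bins_kb)
        if cfg.nonsyntenic_n:
            background[lab] = nonsyntenic_background(
                d, cfg.nonsyntenic_n, cfg.seed, cfg.n_haplotypes_mode
            )
        adj = adjacent_summary(d, n_haplotypes_mode=cfg.n_haplotypes_mode)
        adj_path = out / f"adjacent_{lab}.tsv"
        adj.to_csv(adj_path, sep="\t", index=False, float_format="%.6g")
        manifest["tables"].append(adj_path.name)
        trajectories.append(
            ne_trajectory(
                pairs,
                cfg.mapping,
                n_individuals=d.n_samples,
                n_bins=cfg.ne_n_bins,
                min_distance_bp=cfg.ne_min_distance_bp,
                max_distance_bp=cfg.ne_max_distance_bp,
            )
        )
    stage("ld")["pair_counts"] = pair_counts

    decay = _decay_frame(decay_per_maf, background or None)
    decay_path = out / "ld_decay.tsv"
    decay.to_csv(decay_path, sep="\t", index=False, float_format="%.6g")
    manifest["tables"].append(decay_path.name)

    # --- ROH on the pre-MAF dataset --------------------------------------
    segments = detect_roh(g_base, cfg.roh_params)
    seg_frame = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chromosome": s.chromosome,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snps": s.n_snps,
                "length_bp": s.length_bp,
                "length_class": s.length_class,
            }
            for s in segments
        ],
        columns=[
            "sample_id", "chromosome", "start_bp", "end_bp",
            "n_snps", "length_bp", "length_class",
        ],
    )
    seg_path = out / "roh_segments.tsv"
    seg_frame.to_csv(seg_path, sep="\t", index=False)
    manifest["tables"].append(seg_path.name)
    summary = roh_summaries(segments, g_base)
    ind_path = out / "roh_per_individual.tsv"
    summary.per_individual.to_csv(ind_path, sep="\t", index=False, float_format="%.6g")
    chrom_path = out / "roh_per_chromosome.tsv"
    summary.per_chromosome.to_csv(chrom_path, sep="\t", index=False, float_format="%.6g")
    manifest["tables"] += [ind_path.name, chrom_path.name]
    stage("roh")["n_segments"] = len(segments)
    stage("roh")["mean_genome_fraction"] = summary.mean_genome_fraction

    # --- Ne trajectory table ---------------------------------------------
    labels = list(datasets)
    mean_rows = mean_trajectory(trajectories, ndigits=0)
    ne_rows = []
    for k, mean_row in enumerate(mean_rows):
        row = {
            "t_generations": round(mean_row["t_generations"], 1),
            "bin_lo_bp": mean_row["bin_lo_bp"],
            "bin_hi_bp": mean_row["bin_hi_bp"],
        }
        for lab, traj in zip(labels, trajectories):
            ne = traj[k].Ne
            row[f"Ne_{lab}"] = "NA" if ne is None else int(round(ne))
        row["mean_Ne"] = "NA" if mean_row["mean_Ne"] is None else mean_row["mean_Ne"]
        ne_rows.append(row)
    ne_frame = pd.DataFrame(ne_rows)
    ne_path = out / "ne_trajectory.tsv"
    ne_frame.to_csv(ne_path, sep="\t", index=False)
    manifest["tables"].append(ne_path.name)
    stage("ne")["n_bins"] = cfg.ne_n_bins

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
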