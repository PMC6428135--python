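"""PLINK text PED/MAP input/output and the in-memory genotype matrix.

Genotypes are stored as alt-allele dosages: for each marker the matrix holds
0, 1 or 2 copies of ``allele_b`` (or :data:`MISSING`).  ``allele_b`` defaults
to the lexicographically later of the two alleles observed in the file, which
is harmless for LD and homozygosity work because r2, |D'| and ROH calls are
invariant under allele relabelling.  Coordinates are 1-based inclusive base
pairs, the MAP convention.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Sentinel genotype code for a missing call.
MISSING: int = -1

#: Default analysis chromosomes: the 29 cattle autosomes.
BOVINE_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 30))

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]

#: Placeholder allele label used when an allele was never observed in a file.
UNKNOWN_ALLELE = "."


def _chrom_sort_key(label: str) -> tuple[int, int, str]:
    """Natural ordering: numeric labels first in numeric order, then lexicographic."""
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


@dataclasses.dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a cohort, bound to a marker map.

    Attributes
    ----------
    samples:
        Sample identifiers, one per row of ``calls``.
    markers:
        DataFrame with columns ``marker_id, chromosome, position_bp,
        allele_a, allele_b``, sorted by (chromosome, position_bp).
    calls:
        ``int8`` array of shape (n_samples, n_markers); each non-missing cell
        counts copies of ``allele_b``; missing cells hold :data:`MISSING`.
    """

    samples: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def positions(self) -> np.ndarray:
        return self.markers["position_bp"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.markers["chromosome"].to_numpy()

    def chromosome_labels(self) -> list[str]:
        """Distinct chromosome labels in map order."""
        seen: dict[str, None] = {}
        for c in self.markers["chromosome"]:
            seen.setdefault(c, None)
        return list(seen)

    def marker_indices(self, chromosome: str) -> np.ndarray:
        return np.flatnonzero(self.chromosomes == chromosome)

    # -- derived statistics ----------------------------------------------
    def allele_b_freq(self) -> np.ndarray:
        """Frequency of ``allele_b`` per marker over non-missing calls (NaN if none)."""
        calls = self.calls.astype(float)
        calls[self.calls == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(calls, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_b_freq()
        return np.minimum(p, 1.0 - p)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    def marker_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return (self.calls != MISSING).mean(axis=0)

    # -- subsetting -------------------------------------------------------
    def take_markers(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index].copy(),
        )

    def take_samples(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            markers=self.markers.copy(),
            calls=self.calls[index, :].copy(),
        )

    def alleles(self) -> dict[str, tuple[str, str]]:
        """Mapping marker_id -> (allele_a, allele_b), usable as a read reference."""
        return {
            row.marker_id: (row.allele_a, row.allele_b)
            for row in self.markers.itertuples()
        }


def read_ped_map(
    ped_path,
    map_path,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> GenotypeMatrix:
    """Read whitespace-delimited PLINK text PED/MAP files.

    Parameters
    ----------
    ped_path, map_path:
        Paths to the PED (6 leading columns, then two allele tokens per
        marker) and MAP (3 or 4 columns: chromosome, id, [cM,] bp) files.
    alleles:
        Optional reference orientation, ``marker_id -> (allele_a, allele_b)``.
        Without it, ``allele_b`` is the lexicographically later observed
        allele; markers where only one allele is observed are coded 0.

    Returns
    -------
    GenotypeMatrix
        Markers sorted by (chromosome, position_bp); ``0 0`` (or any pair
        containing the ``0`` missing code) becomes :data:`MISSING`.
    """
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) == 4:
                chrom, marker_id, _cm, pos_tok = tokens
            elif len(tokens) == 3:
                chrom, marker_id, pos_tok = tokens
            else:
                raise ParseError(
                    f"{map_path}: line {lineno}: expected 3 or 4 columns, got {len(tokens)}"
                )
            try:
                pos = int(pos_tok)
            except ValueError as exc:
                raise ParseError(
                    f"{map_path}: line {lineno}: non-numeric position {pos_tok!r}"
                ) from exc
            if pos < 1:
                raise ParseError(f"{map_path}: line {lineno}: position must be >= 1")
            map_rows.append((chrom, marker_id, pos))

    ids = [m for _, m, _ in map_rows]
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate marker id(s) in {map_path}: {dupes[:5]}")
    n_markers = len(map_rows)

    samples: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 6 + 2 * n_markers:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_markers} columns "
                    f"for {n_markers} markers, got {len(tokens)}"
                )
            samples.append(tokens[1])
            allele_rows.append(
                [(tokens[6 + 2 * k], tokens[7 + 2 * k]) for k in range(n_markers)]
            )

    calls = np.full((len(samples), n_markers), MISSING, dtype=np.int8)
    allele_a_col: list[str] = []
    allele_b_col: list[str] = []
    for k, (_chrom, marker_id, _pos) in enumerate(map_rows):
        observed: set[str] = set()
        for row in allele_rows:
            a1, a2 = row[k]
            if a1 != "0":
                observed.add(a1)
            if a2 != "0":
                observed.add(a2)
        if alleles is not None and marker_id in alleles:
            a_lab, b_lab = alleles[marker_id]
            extra = observed - {a_lab, b_lab}
            if extra:
                raise ValidationError(
                    f"marker {marker_id}: observed allele(s) {sorted(extra)} not in "
                    f"supplied reference pair ({a_lab}, {b_lab})"
                )
        elif len(observed) > 2:
            raise ValidationError(
                f"marker {marker_id}: more than two alleles observed: {sorted(observed)}"
            )
        elif len(observed) == 2:
            a_lab, b_lab = sorted(observed)
        elif len(observed) == 1:
            a_lab, b_lab = observed.pop(), UNKNOWN_ALLELE
        else:
            a_lab, b_lab = UNKNOWN_ALLELE, UNKNOWN_ALLELE
        allele_a_col.append(a_lab)
        allele_b_col.append(b_lab)
        for s, row in enumerate(allele_rows):
            a1, a2 = row[k]
            if a1 == "0" or a2 == "0":
                continue
            calls[s, k] = (a1 == b_lab) + (a2 == b_lab)

    markers = pd.DataFrame(
        {
            "marker_id": ids,
            "chromosome": [c for c, _, _ in map_rows],
            "position_bp": [p for _, _, p in map_rows],
            "allele_a": allele_a_col,
            "allele_b": allele_b_col,
        }
    )
    order = sorted(
        range(n_markers),
        key=lambda k: (_chrom_sort_key(markers["chromosome"][k]), markers["position_bp"][k]),
    )
    markers = markers.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


def write_ped_map(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write ``g`` as PLINK text PED/MAP, readable back by :func:`read_ped_map`."""
    with open(map_path, "w") as fh:
        for row in g.markers.itertuples():
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}\n")
    a = g.markers["allele_a"].to_numpy()
    b = g.markers["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for s, sample in enumerate(g.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for k in range(g.n_markers):
                code = g.calls[s, k]
                if code == MISSING:
                    fields += ["0", "0"]
                elif code == 0:
                    fields += [a[k], a[k]]
                elif code == 1:
                    fields += [a[k], b[k]]
                else:
                    fields += [b[k], b[k]]
            fh.write(" ".join(fields) + "\n")


def validate(g: GenotypeMatrix) -> list[str]:
    """Report invariant violations as a sorted list of finding strings.

    An empty list means the matrix satisfies every structural invariant
    (dimensions, call-code range, marker ordering, unique ids/positions).
    """
    findings: list[str] = []
    ids = g.markers["marker_id"]
    for marker_id in ids[ids.duplicated()].unique():
        findings.append(f"duplicate marker id: {marker_id}")

    chrom_pos = g.markers[["chromosome", "position_bp"]]
    for (chrom, pos), _sub in chrom_pos[chrom_pos.duplicated()].groupby(
        ["chromosome", "position_bp"]
    ):
        findings.append(f"duplicate position: chromosome {chrom} at {pos} bp")

    keys = [
        (_chrom_sort_key(c), int(p))
        for c, p in zip(g.markers["chromosome"], g.markers["position_bp"])
    ]
    if keys != sorted(keys):
        findings.append("markers not sorted by (chromosome, position_bp)")

    if (g.markers["position_bp"] < 1).any():
        findings.append("position_bp below 1")

    bad = (g.calls != MISSING) & ((g.calls < 0) | (g.calls > 2))
    for s, k in zip(*np.nonzero(bad)):
        findings.append(
            f"out-of-range call code {int(g.calls[s, k])} at sample "
            f"{g.samples[s]}, marker {g.markers['marker_id'][k]}"
        )
    return sorted(findings)


def filter_autosomes(
    g: GenotypeMatrix, autosomes: Iterable[str] = BOVINE_AUTOSOMES
) -> GenotypeMatrix:
    """Keep only markers whose chromosome label is in ``autosomes``."""
    allowed = set(autosomes)
    keep = np.flatnonzero([c in allowed for c in g.chromosomes])
    return g.take_markers(keep)
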