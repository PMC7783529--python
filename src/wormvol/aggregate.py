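"""Tissue-level composition statistics: totals, fractions, rankings,
per-genome normalization, and size-distribution summaries.

Volume, nuclei, and genome fractions are normalized over the tissues
remaining after exclusions (the extracellular cuticle is excluded from
volume-fraction analyses by default at the CLI layer), and the germline
pseudo-record can be toggled in or out to report somatic-only versus
whole-animal composition.

"Fraction below" a size threshold uses strict inequality
(value < threshold); raw fractions are retained and rounded only at
report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping, Sequence

import numpy as np

from wormvol.anatomy import CellRecord, genome_equivalents
from wormvol.volumetrics import VolumeMeasurement

__all__ = [
    "TissueSummary",
    "DistributionStats",
    "RankedTissues",
    "ExtremeRatios",
    "summarize_tissues",
    "volume_per_genome",
    "distribution_stats",
    "rank_tissues",
    "extreme_ratios",
    "write_tissue_summary_csv",
    "write_distribution_csv",
]


@dataclass(frozen=True)
class TissueSummary:
    """Aggregated volume, nuclei, and genome statistics for one tissue.

    Fractions are relative to the tissues included in the same
    summarization call (after exclusions and the germline toggle).
    ``mean_volume_per_genome`` is the mean over the tissue's cells of
    cell volume divided by that cell's diploid-genome equivalents
    (cells with zero genome equivalents are left out of this mean).
    """

    tissue: str
    total_volume: float
    volume_fraction: float
    n_cells: int
    nuclei_total: int
    genome_equivalents_total: float
    nuclei_fraction: float
    genome_fraction: float
    mean_cell_volume: float
    mean_volume_per_genome: float


@dataclass(frozen=True)
class DistributionStats:
    """Fractions of cells strictly below each volume threshold."""

    thresholds: tuple[float, ...]
    fractions_below: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        fb = self.fractions_below
        if any(b < a for a, b in zip(fb, fb[1:])):
            raise ValueError("fractions_below must be nondecreasing")


@dataclass(frozen=True)
class RankedTissues:
    order: tuple[str, ...]
    has_ties: bool


@dataclass(frozen=True)
class ExtremeRatios:
    """Largest-to-second-largest cell ratio and, per tissue, the ratio of
    its mean per-genome volume to the mean over all other tissues'
    cells."""

    largest_cell: str
    second_largest_cell: str
    largest_to_second: float
    per_genome_ratio: Mapping[str, float]


def _join(
    measurements: Sequence[VolumeMeasurement],
    records: Sequence[CellRecord],
) -> list[tuple[VolumeMeasurement, CellRecord]]:
    by_cell = {r.cell: r for r in records}
    orphans = [m.cell for m in measurements if m.cell not in by_cell]
    if orphans:
        raise ValueError(
            "measurements without anatomy records: " + ", ".join(sorted(orphans))
        )
    return [(m, by_cell[m.cell]) for m in measurements]


def summarize_tissues(
    measurements: Sequence[VolumeMeasurement],
    records: Sequence[CellRecord],
    include_germline: bool = True,
    exclude: AbstractSet[str] = frozenset(),
) -> list[TissueSummary]:
    """Aggregate per-cell measurements into per-tissue summaries.

    Every measurement must have a matching :class:`CellRecord` (strict
    join on cell name).  Tissue membership is taken from the anatomy
    record.  ``include_germline=False`` drops non-somatic cells before
    aggregating; ``exclude`` removes whole tissues from the output (and
    hence from fraction normalization) without affecting the totals of
    the remaining tissues.
    """
    pairs = _join(measurements, records)
    if not include_germline:
        pairs = [(m, r) for m, r in pairs if r.somatic]
    pairs = [(m, r) for m, r in pairs if r.tissue not in exclude]
    if not pairs:
        raise ValueError("no cells remain after exclusions")

    tissues: dict[str, list[tuple[VolumeMeasurement, CellRecord]]] = {}
    for m, r in pairs:
        tissues.setdefault(r.tissue, []).append((m, r))

    totals = {
        t: math.fsum(m.calibrated_volume for m, _ in cells)
        for t, cells in tissues.items()
    }
    nuclei = {t: sum(r.nuclei for _, r in cells) for t, cells in tissues.items()}
    genomes = {
        t: math.fsum(genome_equivalents(r) for _, r in cells)
        for t, cells in tissues.items()
    }
    grand_volume = math.fsum(totals.values())
    grand_nuclei = sum(nuclei.values())
    grand_genomes = math.fsum(genomes.values())

    summaries = []
    for t in sorted(tissues):
        cells = tissues[t]
        per_genome = [
            m.calibrated_volume / genome_equivalents(r)
            for m, r in cells
            if genome_equivalents(r) > 0
        ]
        summaries.append(
            TissueSummary(
                tissue=t,
                total_volume=totals[t],
                volume_fraction=totals[t] / grand_volume,
                n_cells=len(cells),
                nuclei_total=nuclei[t],
                genome_equivalents_total=genomes[t],
                nuclei_fraction=(
                    nuclei[t] / grand_nuclei if grand_nuclei else 0.0
                ),
                genome_fraction=(
                    genomes[t] / grand_genomes if grand_genomes else 0.0
                ),
                mean_cell_volume=totals[t] / len(cells),
                mean_volume_per_genome=(
                    math.fsum(per_genome) / len(per_genome)
                    if per_genome
                    else float("nan")
                ),
            )
        )
    return summaries


def volume_per_genome(
    measurement: VolumeMeasurement, record: CellRecord
) -> float:
    """Calibrated volume divided by diploid-genome equivalents.

    Undefined (raises) for zero-genome records such as the cuticle;
    those are excluded from per-genome analyses upstream.
    """
    g = genome_equivalents(record)
    if g <= 0:
        raise ValueError(
            f"{record.cell}: volume per genome undefined for "
            f"{g} genome equivalents"
        )
    return measurement.calibrated_volume / g


def distribution_stats(
    per_cell_values: Sequence[float],
    thresholds: Sequence[float],
) -> DistributionStats:
    """Fraction of values strictly below each threshold."""
    values = np.asarray(per_cell_values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty value list")
    if np.any(values < 0):
        raise ValueError("volumes must be nonnegative")
    ths = sorted(float(t) for t in thresholds)
    fracs = tuple(float(np.mean(values < t)) for t in ths)
    return DistributionStats(
        thresholds=tuple(ths),
        fractions_below=fracs,
        values=tuple(float(v) for v in values),
    )


def rank_tissues(summaries: Sequence[TissueSummary]) -> RankedTissues:
    """Order tissues by descending total volume; ties broken
    lexicographically and flagged."""
    if not summaries:
        raise ValueError("no summaries to rank")
    ordered = sorted(summaries, key=lambda s: (-s.total_volume, s.tissue))
    volumes = [s.total_volume for s in ordered]
    has_ties = len(volumes) != len(set(volumes))
    return RankedTissues(
        order=tuple(s.tissue for s in ordered), has_ties=has_ties
    )


def extreme_ratios(
    measurements: Sequence[VolumeMeasurement],
    records: Sequence[CellRecord],
) -> ExtremeRatios:
    """Largest/second-largest cell-volume ratio and per-tissue mean
    per-genome volume relative to the mean over all other cells.

    Cells with zero genome equivalents are excluded from the per-genome
    ratios.
    """
    pairs = _join(measurements, records)
    if len(pairs) < 2:
        raise ValueError("need at least 2 cells")
    by_volume = sorted(pairs, key=lambda p: -p[0].calibrated_volume)
    (m1, _), (m2, _) = by_volume[0], by_volume[1]
    if m2.calibrated_volume <= 0:
        raise ValueError("second-largest cell has non-positive volume")

    genome_pairs = [
        (r.tissue, volume_per_genome(m, r))
        for m, r in pairs
        if genome_equivalents(r) > 0
    ]
    ratios: dict[str, float] = {}
    tissues = {t for t, _ in genome_pairs}
    for t in sorted(tissues):
        inside = [v for tt, v in genome_pairs if tt == t]
        outside = [v for tt, v in genome_pairs if tt != t]
        if inside and outside:
            ratios[t] = (math.fsum(inside) / len(inside)) / (
                math.fsum(outside) / len(outside)
            )
    return ExtremeRatios(
        largest_cell=m1.cell,
        second_largest_cell=m2.cell,
        largest_to_second=m1.calibrated_volume / m2.calibrated_volume,
        per_genome_ratio=ratios,
    )


def write_tissue_summary_csv(
    summaries: Sequence[TissueSummary],
    path: str | Path,
    header_lines: Iterable[str] = (),
) -> Path:
    path = Path(path)
    cols = (
        "tissue,total_volume_um3,volume_fraction,n_cells,nuclei_total,"
        "genome_equivalents_total,nuclei_fraction,genome_fraction,"
        "mean_cell_volume_um3,mean_volume_per_genome_um3"
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(cols + "\n")
        for s in summaries:
            fh.write(
                f"{s.tissue},{s.total_volume!r},{s.volume_fraction!r},"
                f"{s.n_cells},{s.nuclei_total},{s.genome_equivalents_total!r},"
                f"{s.nuclei_fraction!r},{s.genome_fraction!r},"
                f"{s.mean_cell_volume!r},{s.mean_volume_per_genome!r}\n"
            )
    return path


def write_distribution_csv(
    stats: DistributionStats,
    path: str | Path,
    header_lines: Iterable[str] = (),
) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("threshold_um3,fraction_below,percent_below\n")
        for t, f in zip(stats.thresholds, stats.fractions_below):
            fh.write(f"{t!r},{f!r},{round(100 * f)}\n")
    return path
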