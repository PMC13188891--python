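"""Genome maps for backcross simulation.

A :class:`GenomeMap` is an ordered collection of chromosomes, each with a
physical length (bp), a genetic length (cM) and a sorted set of 1-based
marker positions. Lepidopteran assemblies often carry a residual "virtual"
unanchored group conventionally labelled ``chr0``; it is treated as just
another chromosome here.

Coordinates are 1-based inclusive throughout the package; only BED export
converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import GenomeMapError, InvalidParameterError

#: Chromosome label of the causal locus in the default simulated genome.
DEFAULT_R2_CHROM = "chr9"
#: Approximate physical position (bp) of the causal locus on that chromosome,
#: inside the fine-mapped aminopeptidase-N cluster region.
DEFAULT_R2_POS_HINT = 2_100_000


@dataclass(frozen=True)
class ChromosomeMap:
    """One chromosome: label, physical/genetic length, marker positions."""

    label: str
    physical_length: int
    genetic_length: float
    markers: np.ndarray  # sorted 1-based bp positions, int64

    def __post_init__(self):
        if self.physical_length <= 0:
            raise GenomeMapError(f"{self.label}: physical_length must be positive")
        if self.genetic_length < 0:
            raise GenomeMapError(f"{self.label}: genetic_length must be >= 0")
        markers = np.asarray(self.markers, dtype=np.int64)
        object.__setattr__(self, "markers", markers)
        if markers.ndim != 1:
            raise GenomeMapError(f"{self.label}: markers must be a 1-D sequence")
        if markers.size:
            if markers[0] < 1 or markers[-1] > self.physical_length:
                raise GenomeMapError(
                    f"{self.label}: marker positions must lie in [1, physical_length]"
                )
            if np.any(np.diff(markers) <= 0):
                raise GenomeMapError(f"{self.label}: marker positions must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return int(self.markers.size)

    def marker_index(self, pos: int) -> int:
        """Index of the marker at physical position ``pos`` (exact match)."""
        i = int(np.searchsorted(self.markers, pos))
        if i == self.n_markers or self.markers[i] != pos:
            raise GenomeMapError(f"{self.label}: no marker at position {pos}")
        return i

    def nearest_marker(self, pos: int) -> int:
        """Physical position of the marker closest to ``pos``."""
        if not self.n_markers:
            raise GenomeMapError(f"{self.label}: chromosome has no markers")
        i = int(np.clip(np.searchsorted(self.markers, pos), 1, self.n_markers - 1))
        lo, hi = self.markers[i - 1], self.markers[i]
        return int(lo if abs(pos - lo) <= abs(hi - pos) else hi)

    def genetic_pos(self, bp) -> np.ndarray:
        """Genetic coordinate (cM) of physical position(s), uniform cM/bp."""
        return np.asarray(bp, dtype=float) / self.physical_length * self.genetic_length


@dataclass(frozen=True)
class GenomeMap:
    chromosomes: tuple[ChromosomeMap, ...]

    def __post_init__(self):
        labels = [c.label for c in self.chromosomes]
        if len(set(labels)) != len(labels):
            raise GenomeMapError("duplicate chromosome labels")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.chromosomes]

    def __getitem__(self, label: str) -> ChromosomeMap:
        for c in self.chromosomes:
            if c.label == label:
                return c
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(c.label == label for c in self.chromosomes)

    def __iter__(self):
        return iter(self.chromosomes)

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chromosomes)


def build_genome_map(
    n_chromosomes: int,
    physical_lengths: Sequence[int] | int,
    genetic_lengths: Sequence[float] | float,
    marker_spacing: int,
    labels: Sequence[str] | None = None,
) -> GenomeMap:
    """Build a genome map with markers at regular spacing.

    Markers are placed deterministically at ``spacing, 2*spacing, ...`` up to
    the chromosome's physical length. Scalar lengths are broadcast to all
    chromosomes. Labels default to ``chr1..chrN``.
    """
    if n_chromosomes < 1:
        raise InvalidParameterError("n_chromosomes must be >= 1")
    if marker_spacing <= 0:
        raise InvalidParameterError("marker_spacing must be positive")
    phys = np.broadcast_to(np.asarray(physical_lengths, dtype=np.int64), (n_chromosomes,))
    gen = np.broadcast_to(np.asarray(genetic_lengths, dtype=float), (n_chromosomes,))
    if np.any(phys <= 0):
        raise InvalidParameterError("physical lengths must be positive")
    if np.any(gen < 0):
        raise InvalidParameterError("genetic lengths must be non-negative")
    if labels is None:
        labels = [f"chr{i + 1}" for i in range(n_chromosomes)]
    elif len(labels) != n_chromosomes:
        raise InvalidParameterError("labels length must equal n_chromosomes")
    chroms = tuple(
        ChromosomeMap(
            label=str(lab),
            physical_length=int(p),
            genetic_length=float(g),
            markers=np.arange(marker_spacing, int(p) + 1, marker_spacing, dtype=np.int64),
        )
        for lab, p, g in zip(labels, phys, gen)
    )
    return GenomeMap(chromosomes=chroms)


def default_genome(
    markers_per_chromosome: int = 200,
    physical_length: int = 12_500_000,
    genetic_length: float = 50.0,
    n_anchored: int = 31,
    include_unanchored: bool = True,
) -> GenomeMap:
    """A cabbage-looper-like genome: 31 anchored chromosomes plus ``chr0``.

    The default genetic length of 50 cM corresponds to one expected crossover
    per bivalent per male meiosis; cM/bp is uniform within a chromosome.
    """
    labels = [f"chr{i + 1}" for i in range(n_anchored)]
    if include_unanchored:
        labels.append("chr0")
    spacing = max(1, physical_length // markers_per_chromosome)
    return build_genome_map(
        n_chromosomes=len(labels),
        physical_lengths=physical_length,
        genetic_lengths=genetic_length,
        marker_spacing=spacing,
        labels=labels,
    )


def default_r2_locus(gmap: GenomeMap) -> tuple[str, int]:
    """Default causal-locus marker: nearest marker to the fine-mapped region.

    Falls back to the middle marker of the first chromosome when the map has
    no ``chr9``.
    """
    if DEFAULT_R2_CHROM in gmap:
        chrom = gmap[DEFAULT_R2_CHROM]
        return chrom.label, chrom.nearest_marker(DEFAULT_R2_POS_HINT)
    chrom = gmap.chromosomes[0]
    return chrom.label, int(chrom.markers[chrom.n_markers // 2])
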