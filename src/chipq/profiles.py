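"""Regions x bins signal matrices, metagene profiles and coverage tracks.

The heatmap analogue is a SignalMatrix: one row per region (ordered by
increasing Q when an ordering table is supplied), one column per fixed-width
bin across a +/-flank window around the anchor, each cell the RPM-normalized
count of fragments overlapping that bin. The metagene ("average signal
intensity") profile is the column mean. A coverage track is the per-base
RPM pileup over one locus, writable as bedGraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import FragmentSet, GenomicInterval, RegionSet, write_bedgraph
from .occupancy import QTable, rank_regions

logger = logging.getLogger(__name__)

__all__ = ["SignalMatrix", "signal_matrix", "average_profile", "coverage_track"]


@dataclass
class SignalMatrix:
    """RPM signal in fixed bins around an anchor, one row per region."""

    values: np.ndarray          # (n_regions, n_bins) float
    row_names: list[str]
    bin_edges: np.ndarray       # offsets from anchor, length n_bins+1
    anchor: str                 # gene_centre or gene_start
    flank: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.row_names), len(self.bin_edges) - 1):
            raise ValueError("shape mismatch between values, rows and bins")
        if np.any(self.values < 0):
            raise ValueError("negative signal")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=[f"{m:g}" for m in self.bin_midpoints])
        df.insert(0, "name", self.row_names)
        with open(path, "w") as fh:
            fh.write(f"# anchor={self.anchor} flank={self.flank} "
                     f"bin_size={self.bin_size}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignalMatrix":
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        flank = int(meta.get("flank", 10000))
        bin_size = int(meta.get("bin_size", 50))
        edges = np.arange(-flank, flank + bin_size, bin_size)
        return cls(df.drop(columns="name").to_numpy(dtype=float),
                   df["name"].tolist(), edges,
                   meta.get("anchor", "gene_centre"), flank, bin_size)


def signal_matrix(fragments: FragmentSet, regions: RegionSet,
                  order: QTable | None = None, flank: int = 10000,
                  bin_size: int = 50, anchor: str = "gene_centre",
                  orient_by_strand: bool | None = None) -> SignalMatrix:
    """Build the heatmap matrix of RPM-binned signal around each region.

    Rows follow increasing Q when ``order`` is given, else the region-set
    order. ``orient_by_strand`` reverses minus-strand rows so upstream is
    always on the left; it defaults to on for start anchoring and off for
    centre anchoring. Bins falling outside chromosome bounds stay zero.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    if anchor not in ("gene_centre", "gene_start"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if orient_by_strand is None:
        orient_by_strand = anchor == "gene_start"

    if order is not None:
        missing = set(regions.names) - set(order.names)
        if missing:
            raise ValueError(f"ordering table does not cover regions: "
                             f"{sorted(missing)[:5]}")
        ranked = rank_regions(order)
        row_names = [n for n in ranked.names if n in regions]
    else:
        row_names = regions.names

    n_bins = 2 * flank // bin_size
    edges_rel = np.arange(-flank, flank + bin_size, bin_size)
    scale = 1e6 / fragments.total_fragments if fragments.total_fragments else 1.0
    values = np.zeros((len(row_names), n_bins), dtype=float)

    clipped = 0
    for i, name in enumerate(row_names):
        iv = regions[name]
        a = iv.centre if anchor == "gene_centre" else iv.five_prime
        lo_edges = a + edges_rel[:-1]
        hi_edges = a + edges_rel[1:]
        valid = lo_edges >= 0
        if not valid.all():
            clipped += 1
        counts = np.zeros(n_bins, dtype=np.int64)
        counts[valid] = fragments.count_overlaps(
            iv.chrom, lo_edges[valid], hi_edges[valid])
        row = counts * scale
        if orient_by_strand and iv.strand == "-":
            row = row[::-1]
        values[i] = row
    if clipped:
        logger.info("%d regions had bins clipped at a chromosome edge", clipped)
    return SignalMatrix(values, row_names, edges_rel, anchor, flank, bin_size)


def average_profile(matrices: SignalMatrix | Sequence[SignalMatrix]
                    ) -> np.ndarray | list[np.ndarray]:
    """Per-bin mean signal (metagene profile); a list of matrices on a
    shared bin axis yields one vector per matrix, order preserved."""
    if isinstance(matrices, SignalMatrix):
        if matrices.values.size == 0:
            raise ValueError("empty matrix")
        return matrices.values.mean(axis=0)
    mats = list(matrices)
    if not mats:
        raise ValueError("no matrices supplied")
    ref = mats[0].bin_edges
    for m in mats[1:]:
        if len(m.bin_edges) != len(ref) or np.any(m.bin_edges != ref):
            raise ValueError("overlaid matrices must share the bin axis")
    return [average_profile(m) for m in mats]


def coverage_track(fragments: FragmentSet, interval: GenomicInterval,
                   flank: int = 0) -> tuple[int, np.ndarray]:
    """Per-base RPM coverage over [start-flank, end+flank).

    Returns (track start coordinate, values). The value at position p is
    1e6/library_size times the number of fragments covering p.
    """
    lo = max(0, interval.start - flank)
    hi = interval.end + flank
    cov = fragments.coverage(interval.chrom, lo, hi).astype(float)
    if fragments.total_fragments:
        cov *= 1e6 / fragments.total_fragments
    return lo, cov


def write_coverage_bedgraph(path: str | Path, fragments: FragmentSet,
                            interval: GenomicInterval, flank: int = 0) -> None:
    lo, cov = coverage_track(fragments, interval, flank)
    write_bedgraph(path, interval.chrom, lo, cov)
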