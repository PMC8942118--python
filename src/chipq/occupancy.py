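"""Windowed occupancy quantification ("Q-values").

A region's Q-value is the number of ChIP fragments overlapping a fixed
window anchored at the gene start (strand-aware 5' end) or centre,
normalized to reads per million of the library. This is an occupancy score,
not a multiple-testing-adjusted p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import FragmentSet, GenomicInterval, RegionSet

__all__ = ["QuantConfig", "QTable", "quantify", "rank_regions", "top_n",
           "locus_signal"]


@dataclass(frozen=True)
class QuantConfig:
    """Quantification window and normalization settings.

    window_upstream/window_downstream are measured from the anchor in the
    gene's 5'->3' orientation (for unstranded or centre-anchored regions,
    upstream means lower coordinates).
    """

    window_upstream: int = 500
    window_downstream: int = 500
    anchor: str = "gene_start"  # or "gene_centre"
    rpm_normalize: bool = True
    per_kb_normalize: bool = False

    def __post_init__(self) -> None:
        if self.window_upstream + self.window_downstream <= 0:
            raise ValueError("window must have positive length")
        if self.anchor not in ("gene_start", "gene_centre"):
            raise ValueError(f"unknown anchor {self.anchor!r}")

    def window(self, iv: GenomicInterval) -> tuple[int, int]:
        """Genomic [start, end) of the quantification window for a region."""
        if self.anchor == "gene_centre":
            a = iv.centre
        else:
            a = iv.five_prime
        if iv.strand == "-" and self.anchor == "gene_start":
            lo = a - self.window_downstream
            hi = a + self.window_upstream
        else:
            lo = a - self.window_upstream
            hi = a + self.window_downstream
        return max(0, lo), hi


@dataclass
class QTable:
    """Per-region occupancy: raw window counts and normalized Q-values."""

    data: pd.DataFrame  # columns: name, chrom, start, end, strand, raw_count, Q
    config: QuantConfig
    library_size: int

    COLUMNS = ["name", "chrom", "start", "end", "strand", "raw_count", "Q"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"QTable missing columns {missing}")
        if (self.data["Q"] < 0).any():
            raise ValueError("negative Q-value")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def names(self) -> list[str]:
        return self.data["name"].tolist()

    def q(self, name: str) -> float:
        return float(self.data.set_index("name").loc[name, "Q"])

    def q_series(self) -> pd.Series:
        return self.data.set_index("name")["Q"]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# library_size={self.library_size}"
                     f" window_upstream={self.config.window_upstream}"
                     f" window_downstream={self.config.window_downstream}"
                     f" anchor={self.config.anchor}"
                     f" rpm={int(self.config.rpm_normalize)}"
                     f" per_kb={int(self.config.per_kb_normalize)}\n")
            self.data.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QTable":
        meta: dict[str, str] = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        cfg = QuantConfig(
            window_upstream=int(meta.get("window_upstream", 500)),
            window_downstream=int(meta.get("window_downstream", 500)),
            anchor=meta.get("anchor", "gene_start"),
            rpm_normalize=bool(int(meta.get("rpm", 1))),
            per_kb_normalize=bool(int(meta.get("per_kb", 0))),
        )
        return cls(df, cfg, int(meta.get("library_size", len(df))))


def quantify(fragments: FragmentSet, regions: RegionSet,
             config: QuantConfig | None = None) -> QTable:
    """Count fragments overlapping each region's window (>=1 bp overlap) and
    normalize to reads per million (and optionally per kb of window)."""
    config = config or QuantConfig()
    if len(regions) == 0:
        raise ValueError("empty RegionSet")
    if config.rpm_normalize and fragments.total_fragments <= 0:
        raise ValueError("library size must be positive for RPM normalization")

    rows = {c: [] for c in ("name", "chrom", "start", "end", "strand")}
    windows: dict[str, list[tuple[int, int, int]]] = {}
    for idx, iv in enumerate(regions):
        lo, hi = config.window(iv)
        if hi <= lo:
            raise ValueError(f"zero-length window for {iv.name}")
        windows.setdefault(iv.chrom, []).append((idx, lo, hi))
        rows["name"].append(iv.name)
        rows["chrom"].append(iv.chrom)
        rows["start"].append(iv.start)
        rows["end"].append(iv.end)
        rows["strand"].append(iv.strand)

    raw = np.zeros(len(regions), dtype=np.int64)
    for chrom, ws in windows.items():
        idxs = np.array([w[0] for w in ws])
        los = np.array([w[1] for w in ws])
        his = np.array([w[2] for w in ws])
        raw[idxs] = fragments.count_overlaps(chrom, los, his)

    q = raw.astype(float)
    if config.rpm_normalize:
        q = q * 1e6 / fragments.total_fragments
    if config.per_kb_normalize:
        q = q / ((config.window_upstream + config.window_downstream) / 1000.0)

    df = pd.DataFrame(rows)
    df["raw_count"] = raw
    df["Q"] = q
    return QTable(df, config, fragments.total_fragments)


def rank_regions(q: QTable) -> QTable:
    """Sort rows by increasing Q; ties broken by (chrom, start)."""
    df = q.data.sort_values(["Q", "chrom", "start"], kind="mergesort")
    return QTable(df.reset_index(drop=True), q.config, q.library_size)


def top_n(q: QTable, n: int, regions: RegionSet | None = None) -> RegionSet:
    """The n highest-Q regions as a RegionSet.

    Boundary ties are resolved by (chrom, start), lowest first, so the
    selection is deterministic. If the originating RegionSet is supplied its
    assembly label is propagated.
    """
    if not (1 <= n <= len(q)):
        raise ValueError(f"n={n} out of range 1..{len(q)}")
    df = q.data.sort_values(["Q", "chrom", "start"],
                            ascending=[False, True, True], kind="mergesort")
    picked = df.head(n)
    ivs = [GenomicInterval(r.chrom, r.start, r.end, r.name,
                           r.strand if r.strand in ("+", "-") else ".")
           for r in picked.itertuples()]
    return RegionSet(ivs, regions.assembly if regions is not None else "")


def locus_signal(fragments: FragmentSet, locus: GenomicInterval,
                 flank_upstream: int, flank_downstream: int,
                 anchor: str = "gene_start",
                 bin_size: int = 50) -> tuple[float, pd.DataFrame]:
    """Q-value and a binned coverage track for one named locus.

    The window is [anchor-flank_upstream, anchor+flank_downstream) with the
    anchor at the strand-aware start (``gene_start``) or the centre
    (``gene_centre``); counting follows the quantify contract. Returns
    (Q in RPM, track DataFrame with bin start/end/RPM columns).
    """
    cfg = QuantConfig(window_upstream=flank_upstream,
                      window_downstream=flank_downstream, anchor=anchor)
    lo, hi = cfg.window(locus)
    raw = int(fragments.count_overlaps(locus.chrom, [lo], [hi])[0])
    q = raw * 1e6 / fragments.total_fragments if fragments.total_fragments else 0.0

    edges = np.arange(lo, hi + bin_size, bin_size)
    edges = edges[edges <= hi]
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    counts = fragments.count_overlaps(locus.chrom, edges[:-1], edges[1:])
    rpm = counts * 1e6 / fragments.total_fragments if fragments.total_fragments \
        else counts.astype(float)
    track = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                          "rpm": rpm})
    return q, track
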