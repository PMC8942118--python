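"""Genomic containers and format I/O.

Provides the interval/fragment/genome/chain containers the pipeline operates
on, readers and writers for BED6, SAM/BAM, FASTA, UCSC chain and bedGraph,
and chain-based coordinate liftover between assemblies.

Coordinates are 0-based half-open throughout (BED convention); display
strings are 1-based inclusive.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "FragmentSet",
    "ChainMap",
    "Genome",
    "LiftoverResult",
    "read_regions",
    "read_fragments",
    "read_chain",
    "liftover",
    "extract_sequence",
    "write_bedgraph",
    "read_bedgraph",
]


class ParseError(ValueError):
    """A malformed line in an input file."""


# ---------------------------------------------------------------------------
# intervals and region sets


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A named, stranded genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2

    @property
    def five_prime(self) -> int:
        """Strand-aware gene start (5' end); unstranded intervals use start."""
        return self.end if self.strand == "-" else self.start

    def display(self) -> str:
        """1-based inclusive display string."""
        return f"{self.chrom}:{self.start + 1}-{self.end}({self.strand})"


class RegionSet:
    """An ordered, name-unique collection of genomic intervals.

    Intervals are kept sorted by (chrom, start); duplicate names are
    rejected so downstream tables can key on the name.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], assembly: str = ""):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        names = [iv.name for iv in ivs]
        dupes = {n for n in names if names.count(n) > 1} if len(set(names)) != len(names) else set()
        if dupes:
            raise ValueError(f"duplicate region names: {sorted(dupes)[:5]}")
        self._intervals: list[GenomicInterval] = ivs
        self._by_name = {iv.name: iv for iv in ivs}
        self.assembly = assembly

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, key: int | str) -> GenomicInterval:
        if isinstance(key, str):
            return self._by_name[key]
        return self._intervals[key]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [iv.name for iv in self._intervals]

    def subset(self, names: Iterable[str]) -> "RegionSet":
        wanted = set(names)
        return RegionSet([iv for iv in self if iv.name in wanted], self.assembly)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self:
                strand = iv.strand if iv.strand != "." else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{strand}\n")

    def __repr__(self) -> str:
        return f"RegionSet(n={len(self)}, assembly={self.assembly!r})"


def read_regions(path: str | Path, format: str = "BED6", assembly: str = "") -> RegionSet:
    """Read a region annotation table (BED6 or a headered TSV).

    Missing names are generated as ``chrom:start-end``. Lines starting with
    ``#``, ``track`` or ``browser`` are skipped.
    """
    path = Path(path)
    intervals = []
    if format.upper().startswith("BED"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") \
                    else f"{chrom}:{start}-{end}"
                strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
                try:
                    intervals.append(GenomicInterval(chrom, start, end, name, strand))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
    elif format.lower() in ("tsv", "tsv-table"):
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        cols = {c.lower(): c for c in df.columns}
        for req in ("chrom", "start", "end"):
            if req not in cols:
                raise ParseError(f"{path}: TSV table needs a '{req}' column")
        for _, row in df.iterrows():
            name = str(row[cols["name"]]) if "name" in cols else \
                f"{row[cols['chrom']]}:{row[cols['start']]}-{row[cols['end']]}"
            strand = str(row[cols["strand"]]) if "strand" in cols else "."
            intervals.append(GenomicInterval(str(row[cols["chrom"]]),
                                             int(row[cols["start"]]),
                                             int(row[cols["end"]]), name,
                                             strand if strand in ("+", "-") else "."))
    else:
        raise ValueError(f"unknown region format {format!r}")
    return RegionSet(intervals, assembly)


# ---------------------------------------------------------------------------
# fragment sets


class FragmentSet:
    """A sequencing library as DNA-fragment intervals.

    Fragments are stored per chromosome as parallel start/end arrays; an
    independently sorted copy of each supports O(log F) overlap counting.
    ``total_fragments`` is the library size used for reads-per-million
    normalization and defaults to the number of stored fragments.
    """

    def __init__(self, fragments: Mapping[str, np.ndarray] | Iterable[tuple[str, int, int]],
                 total_fragments: int | None = None, source: dict | None = None):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        if isinstance(fragments, Mapping):
            data = {c: np.asarray(a, dtype=np.int64).reshape(-1, 2)
                    for c, a in fragments.items()}
        else:
            for chrom, start, end in fragments:
                by_chrom.setdefault(chrom, []).append((start, end))
            data = {c: np.array(v, dtype=np.int64).reshape(-1, 2)
                    for c, v in by_chrom.items()}
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._starts_sorted: dict[str, np.ndarray] = {}
        self._ends_sorted: dict[str, np.ndarray] = {}
        n = 0
        for chrom, arr in sorted(data.items()):
            if arr.size == 0:
                continue
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError(f"fragment with end <= start on {chrom}")
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            arr = arr[order]
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]
            self._starts_sorted[chrom] = arr[:, 0]  # already sorted by start
            self._ends_sorted[chrom] = np.sort(arr[:, 1])
            n += len(arr)
        self.n_stored = n
        if total_fragments is None:
            total_fragments = n
        if total_fragments < n:
            raise ValueError("total_fragments below the number of stored fragments")
        self.total_fragments = int(total_fragments)
        self.source = source or {}

    @property
    def chroms(self) -> list[str]:
        return list(self._starts)

    def fragments(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome, sorted by start."""
        if chrom not in self._starts:
            z = np.empty(0, dtype=np.int64)
            return z, z
        return self._starts[chrom], self._ends[chrom]

    def __len__(self) -> int:
        return self.n_stored

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chroms:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield chrom, int(s), int(e)

    def count_overlaps(self, chrom: str, starts, ends) -> np.ndarray:
        """Number of fragments overlapping each window [start, end) by >=1 bp."""
        starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        if chrom not in self._starts:
            return np.zeros(len(starts), dtype=np.int64)
        # fragments with frag.start < window.end, minus those fully left
        # of the window (frag.end <= window.start)
        a = np.searchsorted(self._starts_sorted[chrom], ends, side="left")
        b = np.searchsorted(self._ends_sorted[chrom], starts, side="right")
        return a - b

    def coverage(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base fragment coverage over [start, end)."""
        out = np.zeros(end - start + 1, dtype=np.int64)
        s, e = self.fragments(chrom)
        if len(s):
            cs = np.clip(s - start, 0, end - start)
            ce = np.clip(e - start, 0, end - start)
            keep = ce > cs
            np.add.at(out, cs[keep], 1)
            np.add.at(out, ce[keep], -1)
        return np.cumsum(out)[:-1]

    # -- I/O ---------------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        """Write fragments as 3-column BED, with the library size recorded
        in a leading comment so RPM scaling survives a round trip."""
        with open(path, "w") as fh:
            fh.write(f"# total_fragments={self.total_fragments}\n")
            for chrom, s, e in self:
                fh.write(f"{chrom}\t{s}\t{e}\n")

    def to_sam(self, path: str | Path, chrom_lengths: Mapping[str, int],
               read_length: int = 50) -> None:
        """Write fragments as properly paired SAM records whose TLEN spans
        the template, so fragment inference round-trips exactly."""
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
            "CO": [f"total_fragments={self.total_fragments}"],
        }
        tid = {c: i for i, c in enumerate(chrom_lengths)}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i, (chrom, s, e) in enumerate(self):
                rl = min(read_length, e - s)
                for mate in (0, 1):
                    a = pysam.AlignedSegment()
                    a.query_name = f"frag{i}"
                    a.reference_id = tid[chrom]
                    a.next_reference_id = tid[chrom]
                    a.mapping_quality = 60
                    a.cigarstring = f"{rl}M"
                    a.query_sequence = "N" * rl
                    if mate == 0:
                        a.flag = 99  # paired, proper, mate reverse, first
                        a.reference_start = s
                        a.next_reference_start = e - rl
                        a.template_length = e - s
                    else:
                        a.flag = 147  # paired, proper, reverse, second
                        a.reference_start = e - rl
                        a.next_reference_start = s
                        a.template_length = -(e - s)
                    out.write(a)


def read_fragments(path: str | Path, format: str | None = None,
                   single_end_extension: int = 200,
                   total_fragments: int | None = None) -> FragmentSet:
    """Read a fragment library from SAM/BAM or BED.

    Properly paired mates are collapsed to one fragment spanning the
    template; single-end reads (and paired reads whose mate is missing or
    unmapped, with a warning) are extended to ``single_end_extension`` bp in
    the 3' direction of their strand. BED intervals are taken verbatim.

    A ``total_fragments=N`` comment (BED ``#`` line or SAM ``@CO``) overrides
    the stored-fragment count as the library size; an explicit
    ``total_fragments`` argument takes precedence over both.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".sam": "SAM", ".bam": "BAM", ".bed": "BED"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer fragment format from {path.name}")
    fmt = format.upper()
    declared_total = None
    frags: list[tuple[str, int, int]] = []
    if fmt == "BED":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith(("#", "track", "browser")):
                    if "total_fragments=" in line:
                        declared_total = int(line.split("total_fragments=")[1].split()[0])
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
                s, e = int(fields[1]), int(fields[2])
                if e <= s:
                    raise ParseError(f"{path}:{lineno}: end <= start")
                frags.append((fields[0], s, e))
    elif fmt in ("SAM", "BAM"):
        mode = "rb" if fmt == "BAM" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for co in fh.header.get("CO", []):
                if "total_fragments=" in co:
                    declared_total = int(co.split("total_fragments=")[1].split()[0])
            n_orphans = 0
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                chrom = aln.reference_name
                if aln.is_paired:
                    if aln.is_proper_pair and not aln.mate_is_unmapped \
                            and aln.template_length != 0:
                        # count each template once, from the leftmost mate
                        if aln.template_length > 0:
                            frags.append((chrom, aln.reference_start,
                                          aln.reference_start + aln.template_length))
                        continue
                    n_orphans += 1  # fall through: treat as single-end
                start, end = aln.reference_start, aln.reference_end
                if aln.is_reverse:
                    start = max(0, end - single_end_extension)
                else:
                    end = start + single_end_extension
                frags.append((chrom, start, end))
            if n_orphans:
                logger.warning("%s: %d paired reads without usable mates "
                               "treated as single-end", path.name, n_orphans)
    else:
        raise ValueError(f"unknown fragment format {format!r}")
    total = total_fragments if total_fragments is not None else \
        (declared_total if declared_total is not None else None)
    return FragmentSet(frags, total_fragments=total,
                       source={"path": str(path), "format": fmt,
                               "single_end_extension": single_end_extension})


# ---------------------------------------------------------------------------
# genome sequence access


class Genome:
    """A FASTA-backed or in-memory genome sequence store."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, rebuild=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str]) -> "Genome":
        return cls(sequences)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def sequence(self, chrom: str) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._seqs[chrom]


def extract_sequence(genome: Genome, interval: GenomicInterval, flank: int = 0) -> str:
    """Forward-strand sequence of [start-flank, end+flank), clipped to the
    chromosome, upper-cased."""
    seq = genome.sequence(interval.chrom)
    lo = max(0, interval.start - flank)
    hi = min(len(seq), interval.end + flank)
    return seq[lo:hi]


# ---------------------------------------------------------------------------
# chain files and liftover


@dataclass
class ChainBlock:
    src_start: int
    src_end: int
    tgt_start: int  # forward-strand coordinates on the target
    tgt_end: int


@dataclass
class Chain:
    src_chrom: str
    src_size: int
    tgt_chrom: str
    tgt_size: int
    tgt_strand: str  # relative strand of the target alignment
    blocks: list[ChainBlock] = field(default_factory=list)


class ChainMap:
    """Alignment chains between a source and a target assembly (UCSC chain
    format; the chain 't' side is the source, 'q' the target)."""

    def __init__(self, chains: Sequence[Chain], source_assembly: str = "",
                 target_assembly: str = ""):
        self.chains = list(chains)
        self.source_assembly = source_assembly
        self.target_assembly = target_assembly
        self._by_chrom: dict[str, list[Chain]] = {}
        for ch in self.chains:
            for blk in ch.blocks:
                if blk.src_end - blk.src_start <= 0:
                    raise ValueError("empty chain block")
            starts = [b.src_start for b in ch.blocks]
            if starts != sorted(starts):
                raise ValueError("chain blocks not ascending on source")
            self._by_chrom.setdefault(ch.src_chrom, []).append(ch)


def read_chain(path: str | Path, source_assembly: str = "",
               target_assembly: str = "") -> ChainMap:
    """Parse a UCSC chain file.

    Negative-strand target chains are stored with target blocks converted to
    forward-strand coordinates.
    """
    chains: list[Chain] = []
    cur: Chain | None = None
    t_pos = q_pos = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                f = line.split()
                if len(f) < 12:
                    raise ParseError(f"{path}:{lineno}: short chain header")
                (_, _score, t_name, t_size, t_strand, t_start, t_end,
                 q_name, q_size, q_strand, q_start, q_end) = f[:12]
                if t_strand != "+":
                    raise ParseError(f"{path}:{lineno}: source strand must be +")
                cur = Chain(t_name, int(t_size), q_name, int(q_size), q_strand)
                chains.append(cur)
                t_pos, q_pos = int(t_start), int(q_start)
            else:
                if cur is None:
                    raise ParseError(f"{path}:{lineno}: data before chain header")
                f = line.split()
                size = int(f[0])
                if cur.tgt_strand == "-":
                    # q coordinates run on the reverse strand; convert
                    tgt_s = cur.tgt_size - (q_pos + size)
                    tgt_e = cur.tgt_size - q_pos
                else:
                    tgt_s, tgt_e = q_pos, q_pos + size
                cur.blocks.append(ChainBlock(t_pos, t_pos + size, tgt_s, tgt_e))
                if len(f) == 3:
                    t_pos += size + int(f[1])
                    q_pos += size + int(f[2])
                elif len(f) == 1:
                    cur = None  # terminal block
                else:
                    raise ParseError(f"{path}:{lineno}: expected 1 or 3 fields")
    return ChainMap(chains, source_assembly, target_assembly)


@dataclass
class LiftoverResult:
    mapped: RegionSet
    unmapped: list[str]

    @property
    def remap_rate(self) -> float:
        total = len(self.mapped) + len(self.unmapped)
        return len(self.mapped) / total if total else float("nan")


def _map_through_chain(chain: Chain, start: int, end: int) -> tuple[int, int, str] | None:
    """Map [start, end) through one chain; None unless every base maps and
    the target image is a single contiguous interval."""
    blocks = chain.blocks
    # find blocks intersecting [start, end)
    pieces = []
    for blk in blocks:
        if blk.src_end <= start or blk.src_start >= end:
            continue
        lo = max(start, blk.src_start)
        hi = min(end, blk.src_end)
        if chain.tgt_strand == "-":
            # within a reverse chain, source offset o maps to tgt_end-1-o'
            t_hi = blk.tgt_end - (lo - blk.src_start)
            t_lo = blk.tgt_end - (hi - blk.src_start)
        else:
            t_lo = blk.tgt_start + (lo - blk.src_start)
            t_hi = blk.tgt_start + (hi - blk.src_start)
        pieces.append((lo, hi, t_lo, t_hi))
    if not pieces:
        return None
    covered = sum(hi - lo for lo, hi, _, _ in pieces)
    if covered != end - start:
        return None  # part of the interval falls in a chain gap
    # contiguity on both sides
    for (l0, h0, tl0, th0), (l1, h1, tl1, th1) in zip(pieces, pieces[1:]):
        if h0 != l1:
            return None
        if chain.tgt_strand == "-":
            if tl0 != th1:
                return None
        else:
            if th0 != tl1:
                return None
    t_lo = min(p[2] for p in pieces)
    t_hi = max(p[3] for p in pieces)
    return t_lo, t_hi, chain.tgt_strand


def liftover(regions: RegionSet, chain: ChainMap) -> LiftoverResult:
    """Remap regions to the chain's target assembly.

    An interval is successfully remapped iff every base maps through the
    blocks of a single chain onto one contiguous target interval; all other
    intervals are reported as unmapped.
    """
    if regions.assembly and chain.source_assembly \
            and regions.assembly != chain.source_assembly:
        raise ValueError(
            f"region assembly {regions.assembly!r} does not match chain "
            f"source {chain.source_assembly!r}")
    mapped = []
    unmapped = []
    for iv in regions:
        hit = None
        for ch in chain._by_chrom.get(iv.chrom, []):
            res = _map_through_chain(ch, iv.start, iv.end)
            if res is not None:
                if hit is not None and (res[0], res[1], ch.tgt_chrom) != \
                        (hit[0], hit[1], hit[3]):
                    hit = None  # ambiguous across chains
                    break
                hit = (res[0], res[1], res[2], ch.tgt_chrom)
        if hit is None:
            unmapped.append(iv.name)
        else:
            t_lo, t_hi, rel_strand, tgt_chrom = hit
            strand = iv.strand
            if rel_strand == "-" and strand in ("+", "-"):
                strand = "+" if strand == "-" else "-"
            mapped.append(GenomicInterval(tgt_chrom, t_lo, t_hi, iv.name, strand))
    return LiftoverResult(RegionSet(mapped, chain.target_assembly or "target"),
                          unmapped)


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(path: str | Path, chrom: str, start: int,
                   values: np.ndarray) -> None:
    """Write a per-base track as 4-column bedGraph, merging runs of equal
    adjacent values."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        breaks = np.flatnonzero(np.diff(values) != 0) + 1
        edges = np.concatenate(([0], breaks, [len(values)]))
        for lo, hi in zip(edges[:-1], edges[1:]):
            v = values[lo]
            if v != 0:
                fh.write(f"{chrom}\t{start + lo}\t{start + hi}\t{v:g}\n")


def read_bedgraph(path: str | Path, chrom: str, start: int, length: int) -> np.ndarray:
    """Reconstruct a per-base track over [start, start+length) from bedGraph."""
    out = np.zeros(length, dtype=float)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split("\t")
            if c != chrom:
                continue
            lo = max(0, int(s) - start)
            hi = min(length, int(e) - start)
            if hi > lo:
                out[lo:hi] = float(v)
    return out
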