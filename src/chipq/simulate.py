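"""Synthetic genome, annotations and ChIP fragment libraries.

The generator emulates the statistical structure of an estrogen-receptor
ChIP-seq experiment restricted to a small genome carrying Pol III gene
annotations:

* a random background genome with tRNA genes (each carrying internal A-box
  and B-box promoter elements at fixed offsets downstream of the start),
  snoRNA and miRNA gene sets, and two control loci — a GREB1-like canonical
  receptor target with a full estrogen response element planted 585 bp
  upstream of its start, and a BC200-like gene that is never enriched;
* fragment libraries drawn from a mixture of diffuse background coverage,
  focal Gaussian enrichment at a configurable subset of tRNA genes, focal
  enrichment at the GREB1-like control, and "decoy" receptor binding sites
  placed well away from every annotated locus (these absorb the bulk of
  the immunoprecipitated library, as canonical receptor peaks do in a real
  experiment, so that stored fragments equal the library size).

Mixture weights are calibrated so that a bound locus's *expected* raw count
in the +/-500 bp quantification window equals ``enrichment_factor`` times
the background expectation, with the overlap-counting inflation by mean
fragment length accounted for.  Everything is driven by a single seed and
is byte-reproducible.

Profile presets mirror the study's sample types: ``mcf7_like`` (about half
of the tRNA genes bound, plus the control), ``mda_like`` (an exogenous
receptor binding only the control locus, with very low diffuse background
at Pol III loci), and ``met3_like`` (every tRNA gene's enrichment factor
multiplied by a global boost).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats as _st

from .genomic_io import FragmentSet, Genome, GenomicInterval, RegionSet
from .motifs import (CONSENSUS, DEFAULT_MIN_P, IUPAC, PWM, reverse_complement,
                     scan)

__all__ = ["SimConfig", "SimTruth", "ChipProfile", "PROFILES", "make_genome",
           "simulate_chip", "make_category_table", "write_simulation"]

# gene-coordinate offsets (from the 5' end) of the internal promoter boxes
A_BOX_OFFSET = 8
B_BOX_OFFSET = 52
ERE_UPSTREAM_OFFSET = 585  # ERE start sits this far upstream of the control TSS


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment."""

    n_chromosomes: int = 2
    chromosome_length: int = 8_000_000
    n_tdna: int = 400
    n_snorna: int = 30
    n_mirna: int = 30
    enriched_fraction: float = 0.5
    enrichment_factor: float = 8.0
    control_enrichment_factor: float = 40.0
    met3_boost: float = 3.0
    library_size: int = 10_000_000
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 50.0
    min_fragment_length: int = 50
    peak_sd: float = 300.0
    locus_spacing: int = 25_000
    n_decoy: int = 1000
    decoy_exclusion: int = 11_000
    control_locus: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.enriched_fraction <= 1:
            raise ValueError("enriched_fraction must be in [0, 1]")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        for f in ("n_chromosomes", "chromosome_length", "n_tdna", "n_snorna",
                  "n_mirna", "library_size"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chromosome_length

    @property
    def mean_fragment_length(self) -> float:
        """Mean of the clipped-normal fragment length distribution."""
        # clipping at min_fragment_length barely moves the mean at the
        # default (200, 50); compute it exactly anyway
        mu, sd, lo = (self.fragment_length_mean, self.fragment_length_sd,
                      self.min_fragment_length)
        z = (lo - mu) / sd
        below = _st.norm.cdf(z)
        return float(lo * below + mu * (1 - below) + sd * _st.norm.pdf(z))


@dataclass(frozen=True)
class ChipProfile:
    """Per-sample-type mixture settings.

    ``background_fraction`` is the share of the library in diffuse
    background coverage; the profiles differ because the endogenous MCF-7
    receptor ChIP carries far more nonspecific signal at accessible Pol III
    loci than the sharply focused exogenous receptor in the MDA-like line.
    ``tdna_binding`` selects which tRNA genes are enriched: the planted
    subset, none, or all (with the met-3 boost applied).
    """

    name: str
    background_fraction: float
    tdna_binding: str  # planted | none | all_boosted


PROFILES: dict[str, ChipProfile] = {
    "mcf7_like": ChipProfile("mcf7_like", 0.015, "planted"),
    "mda_like": ChipProfile("mda_like", 0.001, "none"),
    "met3_like": ChipProfile("met3_like", 0.015, "all_boosted"),
}


@dataclass
class SimTruth:
    """Ground truth of a simulated genome and (optionally) a ChIP run."""

    config: dict
    seed: int
    loci: dict[str, dict] = field(default_factory=dict)
    planted_motifs: list[dict] = field(default_factory=list)
    bound_subset: list[str] = field(default_factory=list)
    profile: str | None = None
    chip_seed: int | None = None
    enrichment: dict[str, float] = field(default_factory=dict)
    expected_window_count: dict[str, float] = field(default_factory=dict)

    def bound(self, name: str) -> bool:
        return self.enrichment.get(name, 1.0) > 1.0 if self.enrichment \
            else name in self.bound_subset

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# genome construction


def _instantiate_iupac(consensus: str, rng: np.random.Generator) -> str:
    """Pick one concrete max-scoring word of an IUPAC consensus."""
    return "".join(IUPAC[ch][rng.integers(len(IUPAC[ch]))] for ch in consensus)


def _place_loci(config: SimConfig, rng: np.random.Generator
                ) -> list[tuple[str, int, int, str, str]]:
    """Non-overlapping locus placement with >= locus_spacing bp gaps.

    Returns (chrom, start, end, name, strand) tuples sorted by position.
    """
    entries: list[tuple[str, int]] = []
    entries += [(f"tDNA-{i + 1:04d}", int(rng.integers(70, 91)))
                for i in range(config.n_tdna)]
    entries += [(f"snoRNA-{i + 1:03d}", int(rng.integers(120, 181)))
                for i in range(config.n_snorna)]
    entries += [(f"miR-{i + 1:03d}", int(rng.integers(70, 101)))
                for i in range(config.n_mirna)]
    if config.control_locus:
        entries += [("GREB1-like", 2000), ("BC200-like", 200)]
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom = np.full(config.n_chromosomes,
                        len(entries) // config.n_chromosomes)
    per_chrom[: len(entries) % config.n_chromosomes] += 1

    placed = []
    pos = 0
    for ci, chrom in enumerate(chroms):
        n = int(per_chrom[ci])
        chunk = entries[pos:pos + n]
        pos += n
        total_len = sum(l for _, l in chunk)
        slack = config.chromosome_length - total_len \
            - (n + 1) * config.locus_spacing
        if slack < 0:
            raise ValueError(
                "loci cannot be placed with the required spacing; increase "
                "chromosome_length or reduce locus counts")
        cuts = np.sort(rng.integers(0, slack + 1, size=n))
        cursor = 0
        prev_cut = 0
        for (name, length), cut in zip(chunk, cuts):
            cursor += config.locus_spacing + (int(cut) - prev_cut)
            prev_cut = int(cut)
            strand = "+" if name in ("GREB1-like", "BC200-like") \
                else ("+" if rng.random() < 0.5 else "-")
            placed.append((chrom, cursor, cursor + length, name, strand))
            cursor += length
    return placed


def _write_motif(seq: np.ndarray, pos: int, word: str) -> None:
    seq[pos:pos + len(word)] = np.frombuffer(word.encode(), dtype=np.uint8)


def make_genome(config: SimConfig | None = None
                ) -> tuple[Genome, dict[str, RegionSet], SimTruth]:
    """Build the synthetic genome, annotation sets and ground truth.

    The background sequence is i.i.d. uniform over {A,C,G,T}; every tRNA
    gene then receives concrete A-box and B-box words at fixed offsets
    downstream of its 5' end, and the GREB1-like control (when enabled)
    receives a full ERE starting 585 bp upstream of its start.  Finally any
    chance match to the full ERE at the default scan threshold, anywhere in
    the genome outside the planted site, is destroyed by mutating two of
    its consensus positions (re-scanning until clean), so that tRNA-gene
    neighborhoods are ERE-free by construction.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    seqs: dict[str, np.ndarray] = {}
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(config.n_chromosomes):
        seqs[f"chr{i + 1}"] = alphabet[
            rng.integers(0, 4, size=config.chromosome_length)].copy()

    placed = _place_loci(config, rng)
    truth = SimTruth(config=asdict(config), seed=config.seed)
    groups: dict[str, list[GenomicInterval]] = {
        "tdna": [], "snorna": [], "mirna": [], "control": []}
    protected: list[tuple[str, int, int]] = []

    for chrom, start, end, name, strand in placed:
        iv = GenomicInterval(chrom, start, end, name, strand)
        kind = ("tdna" if name.startswith("tDNA") else
                "snorna" if name.startswith("snoRNA") else
                "mirna" if name.startswith("miR") else "control")
        groups[kind].append(iv)
        truth.loci[name] = {"chrom": chrom, "start": start, "end": end,
                            "strand": strand, "type": kind}
        if kind == "tdna":
            for motif, offset in (("A-box", A_BOX_OFFSET),
                                  ("B-box", B_BOX_OFFSET)):
                word = _instantiate_iupac(CONSENSUS[motif], rng)
                if strand == "-":
                    gpos = end - offset - len(word)
                    _write_motif(seqs[chrom], gpos, reverse_complement(word))
                else:
                    gpos = start + offset
                    _write_motif(seqs[chrom], gpos, word)
                truth.planted_motifs.append(
                    {"region": name, "motif": motif, "chrom": chrom,
                     "genomic_start": gpos, "genomic_end": gpos + len(word),
                     "offset_from_start": offset})
                protected.append((chrom, gpos, gpos + len(word)))
        elif name == "GREB1-like":
            word = _instantiate_iupac(CONSENSUS["ERE"], rng)
            gpos = start - ERE_UPSTREAM_OFFSET
            _write_motif(seqs[chrom], gpos, word)
            truth.planted_motifs.append(
                {"region": name, "motif": "ERE", "chrom": chrom,
                 "genomic_start": gpos, "genomic_end": gpos + len(word),
                 "offset_from_start": -ERE_UPSTREAM_OFFSET})
            protected.append((chrom, gpos, gpos + len(word)))

    _scrub_chance_eres(seqs, protected, rng)

    n_bound = int(round(config.enriched_fraction * config.n_tdna))
    tdna_names = [iv.name for iv in groups["tdna"]]
    bound_idx = rng.choice(config.n_tdna, size=n_bound, replace=False)
    truth.bound_subset = sorted(tdna_names[i] for i in bound_idx)

    genome = Genome({c: a.tobytes().decode("ascii") for c, a in seqs.items()})
    regionsets = {kind: RegionSet(ivs, assembly="sim1")
                  for kind, ivs in groups.items()}
    return genome, regionsets, truth


def _scrub_chance_eres(seqs: dict[str, np.ndarray],
                       protected: list[tuple[str, int, int]],
                       rng: np.random.Generator,
                       min_p: float = DEFAULT_MIN_P,
                       max_rounds: int = 20) -> None:
    """Mutate chance full-ERE matches (the motif is palindromic, so a
    plus-strand scan covers both strands)."""
    ere = PWM.from_consensus(CONSENSUS["ERE"], name="ERE")
    consensus = CONSENSUS["ERE"]
    informative = [i for i, ch in enumerate(consensus) if ch != "N"]
    prot_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in protected:
        prot_by_chrom.setdefault(chrom, []).append((s, e))

    for _ in range(max_rounds):
        dirty = False
        for chrom, arr in seqs.items():
            seq = arr.tobytes().decode("ascii")
            hits = scan(seq, ere, strands="+", min_p=min_p)
            for hit in hits:
                span = (hit.offset, hit.offset + ere.width)
                if any(s < span[1] and e > span[0]
                       for s, e in prot_by_chrom.get(chrom, [])):
                    continue  # the planted control ERE
                dirty = True
                # force >= 2 mismatches at unprotected consensus positions
                mutated = 0
                for rel in informative:
                    pos = hit.offset + rel
                    if any(s <= pos < e
                           for s, e in prot_by_chrom.get(chrom, [])):
                        continue
                    want = ord(consensus[rel])
                    choices = [b for b in b"ACGT" if b != want and b != arr[pos]]
                    arr[pos] = choices[rng.integers(len(choices))]
                    mutated += 1
                    if mutated == 2:
                        break
        if not dirty:
            return
    raise RuntimeError("ERE scrubbing did not converge")


# ---------------------------------------------------------------------------
# ChIP simulation


def _overlap_capture_probability(config: SimConfig, half_window: float) -> float:
    """P(a peak fragment overlaps [anchor-hw, anchor+hw)): midpoint is
    Gaussian(anchor, peak_sd), length an independent clipped normal."""
    ls = np.linspace(config.min_fragment_length,
                     config.fragment_length_mean + 6 * config.fragment_length_sd,
                     601)
    w = _st.norm.pdf(ls, config.fragment_length_mean, config.fragment_length_sd)
    w /= w.sum()
    cap = (_st.norm.cdf((half_window + ls / 2) / config.peak_sd)
           - _st.norm.cdf(-(half_window + ls / 2) / config.peak_sd))
    return float(np.sum(w * cap))


def simulate_chip(annotations: Mapping[str, RegionSet],
                  chrom_lengths: Mapping[str, int],
                  config: SimConfig,
                  truth: SimTruth,
                  profile: str = "mcf7_like",
                  seed: int | None = None) -> tuple[FragmentSet, SimTruth]:
    """Draw a seeded fragment library for one sample profile.

    Fragment midpoints come from the mixture described in the module
    docstring; fragment lengths are Normal(mean, sd) clipped at the minimum
    length.  Returns the library and a truth record carrying per-locus
    enrichment factors and expected +/-500 bp window counts.
    """
    if config.library_size <= 0:
        raise ValueError("library_size must be positive")
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; "
                         f"choose from {sorted(PROFILES)}")
    prof = PROFILES[profile]
    chip_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(chip_seed)
    G = float(sum(chrom_lengths.values()))
    N = config.library_size
    window = 1000.0  # the +/-500 bp quantification window
    lbar = config.mean_fragment_length
    p_capture = _overlap_capture_probability(config, window / 2)
    bg_window_rate = prof.background_fraction * (window + lbar) / G

    # per-locus enrichment factors
    factors: dict[str, float] = {}
    anchors: list[tuple[str, int, float]] = []  # (chrom, anchor, weight)
    for kind in ("tdna", "snorna", "mirna", "control"):
        for iv in annotations.get(kind, []):
            if kind == "tdna":
                base = config.enrichment_factor \
                    if iv.name in truth.bound_subset else 1.0
                if prof.tdna_binding == "none":
                    f = 1.0
                elif prof.tdna_binding == "all_boosted":
                    f = base * config.met3_boost
                else:
                    f = base
            elif iv.name == "GREB1-like":
                f = config.control_enrichment_factor
            else:
                f = 1.0
            factors[iv.name] = f
            if f > 1.0:
                w_i = (f - 1.0) * bg_window_rate / p_capture
                anchors.append((iv.chrom, iv.five_prime, w_i))

    w_bg = prof.background_fraction
    w_peaks = sum(w for _, _, w in anchors)
    w_decoy_total = 1.0 - w_bg - w_peaks
    if w_decoy_total <= 0:
        raise ValueError("mixture weights exceed 1; lower enrichment or "
                         "background_fraction")

    # decoy sites: uniform over the genome excluding +/-decoy_exclusion of
    # every annotated locus
    decoys = _sample_decoys(annotations, chrom_lengths, config, rng)
    comps: list[tuple[str, float, float, str]] = []  # chrom, centre, weight, kind
    comps.append(("*", 0.0, w_bg, "background"))
    comps += [(c, a, w, "peak") for c, a, w in anchors]
    comps += [(c, p, w_decoy_total / len(decoys), "decoy") for c, p in decoys]

    weights = np.array([w for _, _, w, _ in comps])
    counts = rng.multinomial(N, weights / weights.sum())

    chrom_names = list(chrom_lengths)
    chrom_sizes = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_probs = chrom_sizes / chrom_sizes.sum()

    all_chrom_idx: list[np.ndarray] = []
    all_mids: list[np.ndarray] = []
    name_to_idx = {c: i for i, c in enumerate(chrom_names)}
    for (chrom, centre, _w, kind), n in zip(comps, counts):
        if n == 0:
            continue
        if kind == "background":
            ci = rng.choice(len(chrom_names), size=n, p=chrom_probs)
            mids = rng.random(n) * chrom_sizes[ci]
        else:
            ci = np.full(n, name_to_idx[chrom])
            mids = rng.normal(centre, config.peak_sd, size=n)
        all_chrom_idx.append(ci)
        all_mids.append(mids)
    chrom_idx = np.concatenate(all_chrom_idx)
    mids = np.concatenate(all_mids)

    lengths = np.clip(
        np.rint(rng.normal(config.fragment_length_mean,
                           config.fragment_length_sd, size=len(mids))),
        config.min_fragment_length, None).astype(np.int64)
    starts = np.rint(mids - lengths / 2).astype(np.int64)
    sizes = chrom_sizes.astype(np.int64)[chrom_idx]
    starts = np.clip(starts, 0, sizes - lengths)
    ends = starts + lengths

    frag_map = {}
    for i, c in enumerate(chrom_names):
        mask = chrom_idx == i
        frag_map[c] = np.column_stack([starts[mask], ends[mask]])
    fragments = FragmentSet(frag_map, total_fragments=N,
                            source={"simulated": True, "profile": profile,
                                    "seed": chip_seed})

    out = SimTruth(config=asdict(config), seed=config.seed,
                   loci=truth.loci, planted_motifs=truth.planted_motifs,
                   bound_subset=truth.bound_subset, profile=profile,
                   chip_seed=chip_seed, enrichment=factors)
    for name, f in factors.items():
        out.expected_window_count[name] = N * bg_window_rate * f
    return fragments, out


def _sample_decoys(annotations: Mapping[str, RegionSet],
                   chrom_lengths: Mapping[str, int], config: SimConfig,
                   rng: np.random.Generator) -> list[tuple[str, int]]:
    allowed: list[tuple[str, int, int]] = []
    for chrom, L in chrom_lengths.items():
        blocks = sorted(
            (max(0, iv.start - config.decoy_exclusion),
             min(L, iv.end + config.decoy_exclusion))
            for rs in annotations.values() for iv in rs if iv.chrom == chrom)
        cursor = 0
        for s, e in blocks:
            if s > cursor:
                allowed.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < L:
            allowed.append((chrom, cursor, L))
    lens = np.array([e - s for _, s, e in allowed], dtype=float)
    picks = rng.choice(len(allowed), size=config.n_decoy, p=lens / lens.sum())
    out = []
    for k in picks:
        chrom, s, e = allowed[k]
        out.append((chrom, int(rng.integers(s, e))))
    return out


# ---------------------------------------------------------------------------
# convenience outputs


def make_category_table(tdna: RegionSet, seed: int = 0,
                        fractions: tuple[float, float, float] = (0.35, 0.35, 0.2)
                        ) -> "CategoryTable":
    """A synthetic proliferation/differentiation/other lookup covering a
    random ~90% of the tRNA genes (the remainder exercises the
    'unclassified' path), standing in for a published categorisation."""
    from .compare import CategoryTable

    rng = np.random.default_rng(seed)
    p_pro, p_dif, p_oth = fractions
    mapping = {}
    for name in tdna.names:
        u = rng.random()
        if u < p_pro:
            mapping[name] = "proliferation"
        elif u < p_pro + p_dif:
            mapping[name] = "differentiation"
        elif u < p_pro + p_dif + p_oth:
            mapping[name] = "other"
        # else: left out of the table
    return CategoryTable(mapping, provenance=f"synthetic(seed={seed})")


def write_simulation(outdir: str | Path, genome: Genome,
                     annotations: Mapping[str, RegionSet],
                     fragments: FragmentSet, truth: SimTruth,
                     fragment_format: str = "bed") -> dict[str, str]:
    """Write genome FASTA, BED annotation sets, the fragment library and the
    truth JSON; returns a name->path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    genome.to_fasta(outdir / "genome.fa")
    paths["genome"] = str(outdir / "genome.fa")
    for kind, rs in annotations.items():
        p = outdir / f"{kind}.bed"
        rs.to_bed(p)
        paths[kind] = str(p)
    if fragment_format == "sam":
        p = outdir / "fragments.sam"
        fragments.to_sam(p, genome.chrom_lengths)
    else:
        p = outdir / "fragments.bed"
        fragments.to_bed(p)
    paths["fragments"] = str(p)
    truth.to_json(outdir / "truth.json")
    paths["truth"] = str(outdir / "truth.json")
    return paths
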