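# Methods

This note documents the models, conventions and numerical choices behind
`chipq`, what the synthetic data generator does and does not emulate, and
the limitations a user should keep in mind.

## Coordinates and containers

All coordinates are 0-based, half-open (BED-native) internally; display
strings are 1-based inclusive. A `RegionSet` keeps intervals sorted by
(chrom, start) with unique names so downstream tables can key on the name.
A `FragmentSet` stores a sequencing library as per-chromosome start/end
arrays plus independently sorted copies, which makes counting the
fragments overlapping a window `[s, e)` two binary searches:
`#{start < e} − #{end ≤ s}`. `total_fragments` — the denominator of
reads-per-million (RPM) normalization — defaults to the stored count but
can exceed it; fragment files written by the package carry it in a header
comment (`# total_fragments=N` in BED, `@CO` in SAM) so the RPM scale
survives a round trip through disk.

## Fragment inference

Quantification counts DNA *fragments*, not reads. From SAM/BAM
input, properly paired mates are collapsed to one fragment spanning the
template (leftmost mate start + TLEN); single-end reads — and paired reads
whose mate is missing or unmapped, which are logged — are extended to a
configurable fragment length (default 200 bp, a typical ChIP fragment
size) in the 3' direction of their strand. BED intervals are taken
verbatim. Duplicates are retained. The 200 bp default is this package's
choice; single-end extension is an explicit modelling decision, since
there is no universal convention for inferring fragments from single-end
reads, and Q values from single-end data depend on it.

## Occupancy quantification (Q-values)

For each region the quantification window is
`[a − up, a + down)` with `up = down = 500` bp by default and `a` the
strand-aware 5' end of the gene (`gene_start`) or its midpoint
(`gene_centre`). For a minus-strand gene the window is mirrored so that
"upstream" always means the 5' direction. A fragment counts if it
intersects the window by ≥ 1 bp. With RPM normalization on (default),
`Q = raw × 10^6 / total_fragments`; an optional per-kilobase flag divides
further by window length / 1000. The `gene_start` anchor is interpreted as
the strand-aware 5' end because that is where TFIIIB sits at Pol III
genes; both anchors are exposed.

Ranking is by increasing Q with ties broken by (chrom, start), stable and
deterministic; `top_n` takes the n largest Q with boundary ties resolved
by (chrom, start), lowest first. The bound set uses a *strict* inequality
(Q > 0.5 by default), so a gene exactly at the threshold is excluded.

## Signal matrices, profiles and tracks

The heatmap analogue is a regions × bins matrix of RPM-normalized
fragment–bin overlap counts across ±10 kb around the gene centre, 50 bp
bins (401 columns). 50 bp resolves a peak whose footprint is ~1 kb while
keeping matrices small; matrices are raw per-bin RPM, not smoothed
densities, so every cell is an auditable count. Rows follow increasing Q when an ordering table is
supplied. With start anchoring, minus-strand rows are reversed so upstream
is always on the left; with centre anchoring orientation is off by
default, matching how centred heatmaps are conventionally displayed. Bins
that would fall off a chromosome end are kept (zero-filled) so all rows
share one bin axis, and the clipping is logged. The metagene profile is
the column mean; overlays require an identical bin axis. Coverage tracks
are exact per-base pileups (difference-array cumulative sum), written as
bedGraph with equal-valued runs merged.

## Motif model and exact p-values

Motifs are probability matrices over {A, C, G, T} with a background
distribution (uniform by default). Consensus strings in full IUPAC are
converted by giving each column equal shares over its compatible bases
plus a pseudocount of 0.25 per cell, renormalized; an `N` column equals
the background and contributes zero log-odds. Scores are summed log2
odds (bits). An `N` in the *scanned sequence* scores the column's
background-expected log-odds, so it is neutral on average.

P-values are exact tail probabilities of the score under the i.i.d.
background model. Per-column log-odds are discretized to integers on a
grid with granularity `g = (max − min) / 1000`; the null distribution of
the integer total is built by convolving per-column pmfs weighted by the
background. Crucially, *scanning uses the same discretized scores*, so a
scanned score maps onto exactly the DP cell it came from, and p-values
agree with exhaustive k-mer enumeration to within one grid step (verified
against full enumeration for widths 4–6). Queries above the achievable
maximum return 0; at or below the minimum, 1; in between the query is
rounded to the nearest grid point, clamped to the achievable maximum.

Minus-strand scanning scores the reverse complement and reports hits at
forward-strand offsets. The full ERE consensus `GGTCAnnnTGACC` is its own
reverse complement, so plus and minus hits coincide there — a property the
tests exploit.

**Detection threshold.** A hit is "found" at `p ≤ min_p` with
`min_p = 3e-4` by default. This value is set by the information content of
the least informative bundled matrix: a *perfect* A-box match
(`TRGCNNARYNNG`, five fixed bases, three two-fold degenerate positions,
four spacer N's) has exact tail probability `2048/4^12 ≈ 1.22e-4`, so any
cutoff at or below that silently makes the A-box undetectable; `3e-4`
admits perfect A-box matches with margin while keeping ERE calls to
matches within one mismatch of consensus. A corollary worth stating
plainly: a 5 bp half-site carries at most 10 bits, its best possible
p-value is `4^-5 ≈ 9.8e-4`, and therefore a half-ERE can *never* reach
significance at this threshold — presence/absence calls on very short
motifs are information-limited, and the half-ERE column of a neighborhood
report is accordingly always negative. Users who want sensitivity to
half-sites should lower the bar explicitly and accept the false-positive
rate that follows (≈ `min_p` per scanned offset and strand).

## Liftover

UCSC chain files are parsed with the `t` side as the source assembly and
`q` as the target; negative-strand target chains are converted to
forward-strand block coordinates at parse time. An interval is
"successfully remapped" iff every base maps through the blocks of a
single chain onto one contiguous target interval — intervals touching a
chain gap on either side, split across chains, or mapping ambiguously to
different targets are reported unmapped. This is the strictest
reproducible reading of "successfully remapped"; a web remapping service
may merge across chains or tolerate partial maps and will therefore report
somewhat higher rates on real data. The remap rate is
mapped / (mapped + unmapped).

## Cross-sample comparison

Occupancy distributions are compared pairwise with a two-sided
Mann–Whitney U test on per-region Q values over a shared region universe
(a mismatch is an error naming the offending regions), with Holm
adjustment across all pairs and the conventional star ladder
(0.05/0.01/0.001/0.0001). A rank test is the defensible default for
heavy-tailed occupancy scores; the comparison is unpaired — pairing by
region would be an alternative, but occupancy at the same gene in
different samples is not a matched measurement in any strong sense, and
the unpaired test is the more conservative declaration. Category tallies
match gene names case-insensitively and ignore hyphens/underscores,
because annotation sources differ in punctuation; the
proliferation/differentiation/other table is always consumed as supplied,
never re-derived.

## The synthetic study

The generator exists so that every claim the package makes is checkable
against planted truth. Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 8 Mb | two chromosomes, i.i.d. uniform background sequence |
| n_tdna | 400 | tRNA genes, 70–90 bp, random strand |
| n_snorna / n_mirna | 30 / 30 | never-enriched comparison gene sets |
| locus spacing | ≥ 25 kb | keeps ±10 kb heatmap windows clean |
| enriched_fraction | 0.5 | share of tDNAs bound in the mcf7-like profile |
| enrichment_factor | 8 | expected window-count fold excess at bound loci |
| control_enrichment_factor | 40 | GREB1-like canonical receptor peak |
| met3_boost | 3 | global multiplier on tDNA factors in met3-like |
| library_size | 1e7 | fragments per library |
| fragment length | N(200, 50), ≥ 50 | clipped normal |
| peak_sd | 300 bp | Gaussian midpoint spread of a binding site |

Every tDNA carries a concrete max-scoring instantiation of the A-box at
gene offset +8 and the B-box at +52 (reverse-complemented into the genome
for minus-strand genes). The GREB1-like control carries a full ERE
starting 585 bp upstream of its start; the BC200-like control is plain and
never enriched. Because chance near-consensus ERE matches are expected
roughly once per ±20 kb window in random sequence, the genome is scrubbed
after planting: it is rescanned with the ERE matrix at the default
threshold and every hit outside the planted site has two of its consensus
positions mutated, iterating until clean. The background is therefore
i.i.d. uniform *except* at planted and scrubbed positions.

Fragment midpoints are drawn from a mixture: a diffuse uniform background
over the genome; a Gaussian (sd 300 bp) at the 5' end of each bound locus;
and ~1000 "decoy" binding sites placed ≥ 11 kb from every annotated locus,
which absorb the rest of the library the way canonical receptor peaks
absorb most of a real IP. Decoys keep the stored fragment count equal to
the library size (files are self-contained) without flooding the Pol III
loci with background. Peak weights are calibrated so that the *expected*
raw count in a bound ±500 bp window is exactly `enrichment_factor` times
the background expectation, using the overlap-corrected closed forms

    E[background window count] = N · w_bg · (window + ℓ̄) / G
    E[peak capture] = E_ℓ[ Φ((w/2 + ℓ/2)/σ) − Φ(−(w/2 + ℓ/2)/σ) ]

where `ℓ̄` is the mean clipped fragment length: a fragment overlaps a
window iff its midpoint falls within the window dilated by half its
length. Omitting the `ℓ̄` term would bias both the background expectation
and the recovered enrichment ratio by ~20% at the defaults. The 300 bp
peak sd is chosen so the ±500 bp quantification window captures ≈ 90% of
midpoint mass (≈ 95% of overlap mass).

**Profiles.** `mcf7_like` binds the planted subset plus the control with
diffuse background fraction 0.015 of the library; `mda_like` binds only
the control, background fraction 0.001; `met3_like` multiplies every
tDNA's factor by `met3_boost` (so previously unbound genes sit at 3× and
bound ones at 24×), background as mcf7-like. The background fractions
differ per profile deliberately: they encode the different signal-to-noise
regimes of an endogenous-receptor ChIP at accessible Pol III loci versus a
sharply focused exogenous receptor, and they are what makes the two
designed contrasts simultaneously realizable on a 16 Mb genome — a
recoverable 8-fold enrichment at a 2-million-fragment library on one hand,
and an mda-like run in which no tRNA gene exceeds Q = 0.5 on the other.
(Q in RPM is invariant to library size for fixed background geometry, so
no choice of library size alone can separate those two regimes.) Both
values were fixed once from the closed-form Poisson expectations above.

**What the generator does not emulate:** read sequences and qualities,
mappability, GC or chromatin-accessibility bias, duplicate structure,
input/control libraries, and peak-shape asymmetry. Passing tests
demonstrate that the *analysis chain* is correct and calibrated on data
with known structure; they do not demonstrate robustness to the biases of
real libraries, which is why the I/O layer accepts real BAM/BED inputs
unchanged.

## Problem sizes in the test suite

The validation battery runs the study at its native size — 400 tDNAs on
16 Mb — with 5-seed batteries at library 2e6 for recovery metrics
(matching the conditions under which an 8-fold enrichment is recoverable
to within ±20% per seed) and the profile defaults elsewhere; unit tests
use a miniature genome (2 × 0.6 Mb, 12 tDNAs, 2e5 fragments) so the whole
suite stays fast. `scripts/acceptance.py` re-runs everything from one
seed in about a minute.

## Known limitations

* Single-end fragment inference is a declared stand-in (see above); Q
  values from single-end real data depend on the extension length.
* The liftover success rule is stricter than web remapping services;
  remap rates are comparable only under the same rule.
* The Mann–Whitney test is unpaired; with strongly region-matched designs
  a paired test would have more power.
* Heatmap matrices are raw binned RPM; no smoothing, no background
  subtraction (no input libraries are modelled or consumed).
* `pwm_pvalue` assumes an i.i.d. background; low-complexity or repetitive
  neighborhoods will show more chance hits than the nominal `min_p`.
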