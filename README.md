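# chipq

Windowed ChIP-seq occupancy analysis at RNA polymerase III-transcribed
gene sets: Q-value quantification, ranked heatmaps and metagene profiles,
motif interrogation with exact PWM p-values, assembly liftover, and
cross-sample comparison — with a fully seeded synthetic ChIP-seq generator
so that every stage is testable end to end without downloads.

## The problem

Estrogen receptor alpha (ERα) ChIP-seq in breast cancer cells shows focal
receptor accumulation at many tRNA genes (tDNAs), which are transcribed by
Pol III and carry internal A-box and B-box promoter elements downstream of
their transcription start. Asking whether a transcription factor occupies
hundreds of short, near-identical loci calls for a simple, transparent
occupancy score rather than conventional peak calling. The score used here
is the **Q-value** of a gene:

    Q(g) = 10^6 / N * #{ fragments overlapping [a_g - 500, a_g + 500) }

where `N` is the library size in DNA fragments, `a_g` is the strand-aware
5' end of the gene, and overlap means at least 1 bp of intersection —
i.e. fragments per million in a ±500 bp window around the gene start
(an occupancy score, *not* a multiple-testing-adjusted p-value). Genes are
ranked by increasing Q for heatmap display; a bound set is defined by
Q > 0.5; the top-bound genes feed category tallies and motif scans.

Around that score the package provides, as library functions and a
`chipq` command-line tool:

* **genomic_io** — BED6 / SAM / BAM / FASTA / UCSC-chain / bedGraph I/O,
  paired-end fragment inference (template spans; single-end reads extended
  3' to a configurable fragment length), and chain-based liftover with a
  strict "every base maps through one chain to one contiguous target
  interval" success rule.
* **occupancy** — `quantify`, `rank_regions`, `top_n`, `locus_signal`
  (e.g. the ±2 kb window upstream of a GREB1-like control locus).
* **profiles** — regions × bins RPM signal matrices around gene centres
  (±10 kb default), column-mean metagene profiles, per-base coverage
  tracks writable as bedGraph.
* **motifs** — PWMs from IUPAC consensus or MEME minimal format; bundled
  estrogen response element `GGTCAnnnTGACC` (palindromic), half-site
  `GGTCA`, A-box `TRGCNNARYNNG`, B-box `GTTCGANNC`; both-strand scanning
  with *exact* score-distribution p-values computed by dynamic programming
  on a shared discretized grid; ±20 kb neighborhood presence reports.
* **compare** — bound sets at a Q threshold, 2/3-way Venn counts,
  proliferation/differentiation/other tallies for the top-50 genes, and
  pairwise two-sided Mann–Whitney U tests with Holm adjustment and a
  significance-star ladder.
* **simulate** — the synthetic study: a 16 Mb two-chromosome genome with
  400 tDNAs (A/B boxes planted), snoRNA/miRNA gene sets, a GREB1-like
  control with a full ERE 585 bp upstream, a BC200-like unenriched
  control, and seeded fragment libraries with known per-locus enrichment
  (`mcf7_like`, `mda_like`, `met3_like` profiles).
* **pipeline** — one declarative YAML config driving the whole chain, with
  a hash-stable run manifest.

## Worked example

```python
from chipq import (SimConfig, make_genome, simulate_chip, quantify, top_n,
                   scan_neighborhood, compare_q_distributions)

cfg = SimConfig(n_tdna=40, library_size=1_000_000, seed=7)
genome, annotations, truth = make_genome(cfg)
tdna = annotations["tdna"]

mcf7, _ = simulate_chip(annotations, genome.chrom_lengths, cfg, truth,
                        "mcf7_like", seed=8)
mda, _ = simulate_chip(annotations, genome.chrom_lengths, cfg, truth,
                       "mda_like", seed=9)

q_mcf7 = quantify(mcf7, tdna)          # Q = fragments per million in +/-500 bp
q_mda = quantify(mda, tdna)
top = top_n(q_mcf7, 5, tdna)
print("top 5 by Q:",
      sorted(((n, q_mcf7.q(n)) for n in top.names), key=lambda t: -t[1]))

report = scan_neighborhood(genome, top, flank=20_000)
print(report.presence.to_string())

res = compare_q_distributions({"MCF7": q_mcf7, "MDA": q_mda})[0]
print(f"MCF7 vs MDA: U={res.statistic:.0f} p_adj={res.p_adjusted:.2e} "
      f"{res.label}")
```

prints

```
top 5 by Q: [('tDNA-0006', 15.0), ('tDNA-0005', 12.0), ('tDNA-0034', 10.0), ('tDNA-0008', 10.0), ('tDNA-0009', 10.0)]
             ERE  half-ERE  A-box  B-box
tDNA-0034  False     False   True   True
tDNA-0005  False     False   True   True
tDNA-0008  False     False   True   True
tDNA-0006  False     False   True   True
tDNA-0009  False     False   True   True
MCF7 vs MDA: U=1424 p_adj=2.43e-11 ****
```

The five most-bound tRNA genes all carry their internal A-box and B-box
promoter elements, but no full or half estrogen response element anywhere
within ±20 kb — receptor occupancy without a local consensus ERE, the
designed behaviour of the generator. The Mann–Whitney comparison confirms
that the mcf7-like occupancy distribution is strongly shifted relative to
the mda-like one, in which only the GREB1-like control locus is bound.

The same analysis from the shell:

```bash
chipq simulate --profile mcf7_like --seed 7 --out demo --n-tdna 40 \
      --library-size 1000000
chipq quantify --fragments demo/fragments.bed --regions demo/tdna.bed \
      --out demo/q.tsv
head -3 demo/q.tsv
# library_size=1000000 window_upstream=500 window_downstream=500 anchor=gene_start rpm=1 per_kb=0
# name	chrom	start	end	strand	raw_count	Q
# tDNA-0016	chr1	1241121	1241193	+	0	0.0
```

Other subcommands: `heatmap`, `profile`, `track`, `scan`, `liftover`,
`venn`, `classify`, `compare`, and `run` (full pipeline from a YAML
config).

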