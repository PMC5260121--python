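# ervpipe

Endogenous retroviruses (ERVs) are the proviral remnants of ancient
germ-line retroviral infections. A freshly integrated provirus carries two
identical long terminal repeats (LTRs) around its `gag`–`pro/pol`–`env`
coding region, flanked by a short target-site duplication (TSD) of host
sequence; over time the element decays into a solo-LTR (by homologous
recombination between its LTRs) or a truncated copy, and its two LTRs
diverge by neutral substitution. **ervpipe** turns these signatures into a
reproducible annotation pipeline for LTR-retrovirus families — written
around the GGERV10 family of the chicken genome, but parameterised for any
family with per-subfamily LTR consensuses:

- **Locus assembly & classification** — merges RepeatMasker fragments into
  loci and labels each *full-length*, *solo-LTR*, or *truncated*.
- **Flank features** — TSD detection (longest exact flanking k-mer, k = 3–8),
  the `TGTTG…CAACA` LTR terminal motifs, flank GC in 20-kb windows, gene
  density in 2-Mb windows, and intergenic/intronic/exonic context.
- **Subfamily & chimera calls** — nearest-consensus assignment of each LTR
  by end-gap-free alignment identity; a provirus whose 5′ and 3′ LTRs
  confidently match *different* consensuses is flagged as a chimeric
  recombinant (template switching). Diagnostic alignment segments that
  partition the subfamilies are recovered from the LTR MSA.
- **Dating** — Kimura 2-parameter distance between the 5′ and 3′ LTR,
  `d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`, with insertion age `t = d/(2µ)`
  (default µ = 0.19%/site/myr); subfamily age from mean divergence to the
  subfamily consensus, `t = d̄/µ`.
- **Phylogeny** — neighbor-joining over K2P distances with column-resampling
  bootstrap supports, written as newick.
- **Structure scan** — primer-binding-site motif, polypurine tract, ORF scan,
  and a gag-state call (intact / frameshifted / absent).
- **Synthetic genomes** — a generator that plants all of the above with full
  ground truth (ages, TSDs, subfamilies, chimeras, gag states), so the whole
  pipeline is testable without downloading a genome.

## Worked example

Simulate a small genome with 21 planted insertions and run the pipeline on
its RepeatMasker-style annotation:

```sh
ervpipe simulate --preset tiny --out demo --seed 42
# planted 21 events on 2 chromosomes -> demo
ervpipe run --rmsk demo/repeats.out --genome demo/genome.fa \
    --genes demo/genes.bed --consensuses demo/ltr_consensuses.fa \
    --out demo_out --bootstrap 50 --seed 42
# {"full_length": 7, "solo_ltr": 10, "truncated": 4}
```

`demo_out/summary.json` then contains (excerpt):

```
total_loci        = 21
class_counts      = {'full_length': 7, 'solo_ltr': 10, 'truncated': 4}
chimeric_loci     = ['locus_00008']
subfamily_age_myr = {'GGERV10C1': 5.1183, 'GGERV10C2': 4.7334, 'GGERV10D': 6.8146}
mean_flank_gc_pct = 41.07
gag_states        = {'absent': 0, 'frameshifted': 2, 'intact': 5}
```

All 21 planted events were recovered in their planted class; one locus is
the planted chimeric recombinant; subfamily ages estimate the mean planted
insertion ages of each subfamily's copies; flank GC matches the generator's
41% background. The per-locus table `demo_out/locus_report.tsv` holds one
row per locus:

```
locus_id     chrom start  end    strand classification subfamily  chimeric tsd_seq ... k2p_d    age_myr gc_pct genic_class
locus_00000  chr1  87344  91002  -      full_length    GGERV10C1  False    CTTTAA  ... 0.018491 4.8662  41.33  intergenic
locus_00001  chr1  163971 167300 +      truncated      NA         NA       AAATAA  ... NA       NA      41.02  intergenic
```

i.e. a minus-strand full-length GGERV10C1-like provirus with a 6-nt TSD,
inter-LTR K2P distance 0.0185 and an estimated insertion age of 4.9 myr.
`ervpipe age --ltr5 a.fa --ltr3 b.fa` dates a single element, and
`ervpipe tree --msa ltrs.afa --out tree.nwk` builds the bootstrapped NJ tree.

## Library layout

| module | contents |
| --- | --- |
| `ervpipe.io_formats` | RepeatMasker `.out` / UCSC rmsk / BED / GFF3 / FASTA readers and writers, locus report |
| `ervpipe.locus_builder` | fragment merging, classification, LTR extraction |
| `ervpipe.flank_features` | TSD, terminal motifs, GC, gene density, genic context |
| `ervpipe.subfamily` | consensus assignment, chimera calls, MSA, diagnostic segments |
| `ervpipe.dating_phylo` | K2P, ages, neighbor joining, bootstrap |
| `ervpipe.structure_scan` | pbs / PPT / ORF / gag-state heuristics |
| `ervpipe.synthetic_data` | planted-genome generator with ground truth |
| `ervpipe.pipeline`, `ervpipe.cli` | orchestration, `ervpipe` command |

See `docs/methods.md` for the models, parameter choices and limitations.
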