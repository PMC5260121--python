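# Methods

## Scope and model

ervpipe annotates insertions of an LTR-retrovirus family in an assembled
genome, starting from repeat annotation rather than raw alignment: the
RepeatMasker ID column links fragments of one interrupted element, and
repeat names of the form `<subfamily>-LTR` / `<subfamily>-int` distinguish
long terminal repeats from internal coding sequence. All internal
coordinates are 0-based half-open; the format converters in `io_formats`
are the only place the 1-based conventions of RepeatMasker `.out` and GFF3
are touched.

### Locus assembly and classification

Hits sharing a linkage id form one locus. Fragments with distinct linkage
ids are additionally merged when they lie on the same chromosome and
strand, share a subfamily stem, and are separated by at most `max_gap_bp`
(default 500 bp). The published censuses of this kind were curated by
manual inspection with unstated merge rules, so the gap rule is a
conservative, configurable automation of that step. Classification is a
total function of the component roles: LTR5 + ≥1 internal + LTR3 is
*full-length*; a lone LTR is a *solo-LTR* (the remnant of recombination
between a provirus's two LTRs); everything else — including a locus with
two LTRs but no internal hit, which is an internal deletion rather than two
independent recombination remnants, and the irregular LTR-between-internals
case — is *truncated*. Truncated loci stay in the report but are excluded
from dating, subfamily alignments and the phylogeny, because one or both
LTRs are missing. LTR sequences are extracted in element orientation
(minus-strand loci reverse-complemented); an LTR with more than 20% N is
kept but flagged and excluded from alignments.

### Flank features

*TSD*: integration duplicates a short target site, so the k-mer immediately
5′ of the locus is compared with the k-mer immediately 3′ of it for
k = `kmax`…`kmin` (8…3); the longest exact match wins. The published
record reports TSDs without stating a length or matching rule; exact
matching over 3–8 nt is the package's choice and is configurable.
*Terminal motifs*: the family-specific LTR ends `TGTTG`/`CAACA` (mutual
reverse complements) are simple prefix/suffix tests.
*GC*: percentage over `window_bp/2` (default 10 kb) on each flank, element
excluded, N excluded from the denominator, windows clipped at chromosome
ends with the actual length used.
*Gene density*: genes overlapping the 1-Mb flank on either side (element
excluded) divided by the nominal 2-Mb window. The source protocols are
ambiguous between 2 Mb total and 2 Mb per side; 2 Mb total ("centered") is
the default and the window is a parameter. Any overlap counts — the
simplest defensible rule, also configurable.
*Genic context*: exonic if the locus overlaps any exon feature, else
intronic if it overlaps a gene span, else intergenic; the precedence is
total and order-independent.

### Subfamily assignment and chimera detection

Each LTR is scored against every subfamily consensus with an end-gap-free
global alignment (match +1, mismatch −1, gap open −5, extend −2); the
distance is 1 − identity over aligned columns between the first and last
doubly-aligned position. Stiff gap costs matter: under free end gaps,
unrelated sequences otherwise optimise to a tiny high-identity overlap, so
an aligned span shorter than half the shorter sequence is treated as
maximally distant, and a best distance above 0.5 is *unassigned*. Identity
distance (not K2P) is used here deliberately — it is robust to the length
variation at LTR edges, while K2P is reserved for dating.

A full-length locus is *chimeric* when its two LTRs' best consensuses
differ and each call's margin (runner-up minus best) is at least
`margin_min` = 0.02. With consensuses ≥5% diverged and copies a few myr
old, genuine calls have margins several times this threshold; discordance
below it is resolved toward the 5′ LTR and flagged rather than called.

Diagnostic segments are found on a per-subfamily-labelled MSA: a column is
informative when every subfamily's rows agree at ≥80% on a majority state
(gap is a state) and those states split the subfamilies into ≥2 groups;
maximal runs ≥ `min_len` (default 10) of columns with the same partition
become segments. `present_in` is the union of non-gap groups when a group's
state is gap (an insertion private to those subfamilies), otherwise the
smallest group. Rows are de-duplicated within a subfamily first, making the
result invariant to row order and duplication. The 80% agreement level
tolerates within-subfamily noise without erasing real regions and is
configurable. Multiple alignment itself is delegated to mafft (progressive,
pairwise-distance guide tree); sequences more than 50 bp shorter than the
subfamily median are excluded beforehand, because heavily deleted copies
cannot be aligned reliably.

### Dating

For aligned sequences, transitions P and transversions Q are counted over
columns free of gaps and N (pairwise deletion, the common default in
dating software), and

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q).

Saturation (non-positive log argument) is an error, not a number. A
provirus's two LTRs are identical at integration and diverge independently,
so its age is `d/(2µ)`. The default rate µ = 0.0019/site/myr follows the
value used for this family's published age; the literature also quotes
0.20–0.26%/myr, and µ is a parameter everywhere.

Subfamily age uses a mean-divergence proxy for rho-statistic network
dating (whose median-joining procedure is not reproducible from its
description): build the column-majority consensus of the subfamily's LTRs,
average the K2P distance of each LTR to it, and divide by µ (not 2µ — each
copy diverges from the shared ancestral sequence along a single lineage).
Whether the published 3.70-myr figure divided by µ or 2µ is not stated;
the single-lineage reading is the package default and the divisor follows
from the stated estimand.

### Phylogeny

Neighbor joining (Saitou–Nei) over the K2P matrix of aligned LTRs, with
negative branch lengths clamped to zero and the deficit shifted to the
sister branch so path lengths are preserved; on additive matrices the
reconstruction is exact to 1e-9 and matches an independent NJ
implementation. Bootstrap supports resample alignment columns with
replacement, rebuild the tree, and report for each internal bipartition of
the reference tree the percentage of replicates containing it; the RNG is
seeded and the seed echoed in the summary. Saturated pairs inside a
bootstrap replicate are assigned twice the largest finite distance in that
matrix — they carry no reliable signal but must not abort clustering.

### Structure scan

Deliberately simplified, alignment-free surrogates for retroviral-motif
chain reconstruction, applied to the internal region in element
orientation: the pbs is the best ≤1-mismatch match of a user-supplied motif
list within 30 bp of the 5′ LTR (the bundled 18-mer is a synthetic default,
not a tRNA database); the PPT is a ≥10-nt window with ≥90% purines within
30 bp of the 3′ LTR; ORFs are maximal stop-free codon runs ≥100 codons in
all six frames (no start codon required). The gag call is *intact* if a
forward ORF ≥400 codons starts in the 5′ third of the internal region,
*frameshifted* if two sub-threshold forward ORFs in different frames
jointly cover ≥1200 nt from the 5′ third with ≤30 nt gap, else *absent*.
These thresholds are package choices, exposed in `StructureParams`; they
are validated against the generator's planted states, not against any
published per-locus table.

## The synthetic-data generator

The generator is the package's test bed and defines its study conditions.
Background sequence is i.i.d. at 41% GC (the AT-rich environment the family
inhabits). Five LTR consensuses are derived from one ancestor at staggered
substitution rates (pairwise substitution divergence 5–15%), resized to the
family's mean subfamily LTR lengths (295, 382, 329, 336, 332 nt), all
framed by `TGTTG…CAACA`, with one consensus carrying a private tandem 24-nt
duplication as a planted diagnostic segment. The 3-kb internal consensus
carries a pbs motif at offset 3, a 450-codon open reading frame starting at
position 240, and a 13-purine PPT just before the 3′ LTR. (A real internal
region is ~7–8 kb; 3 kb preserves every scanned feature at a fraction of
the genome cost.)

The default event mix is the reference census: 47 regular full-length + 2
chimeric proviruses, 483 solo-LTRs and 61 truncated copies, with
per-subfamily counts matching the published table, and gag/pbs states
allocated 31 intact / 15 frameshifted / 3 pbs-deficient across the 49
proviruses. Default subfamily mean ages are staggered at 6.0 / 3.7 / 5.0 /
4.5 / 5.5 myr (the B-like subfamily youngest, at its published age); each
element's age is drawn uniformly within ±50% of its subfamily mean. Each
LTR receives Poisson(µ·age·L) substitutions with a 2:1
transition:transversion bias, so expected pair divergence is 2µ·age.
Evolution is substitution-only by default, keeping the dating model exact;
an optional indel mode (geometric lengths, mean 8 nt) exercises the
deletion filters.

Placement draws non-overlapping positions with ≥1 kb spacing (safely above
the assembler's 500-bp merge gap, so planted events are unambiguous) and an
edge margin of min(1.001 Mb, chrom_len/5), which keeps the 2-Mb environment
windows fully on-genome at the default chromosome size. Each insertion
duplicates its target site (4–6 nt); sites whose flanks would admit a
longer accidental exact repeat are shifted a few bases so the planted TSD
is the unique longest match. Planted diagnostic features are protected
from mutation: substitutions that would create a stop in a planted-intact
gag are resampled, and the pbs/PPT windows and engineered
frameshifted/degraded gag regions are held fixed — the generator guarantees
that its recorded truth is still true at any age, at the cost of slightly
unrealistic conservation of those few dozen bases. Engineered states are
verified against the structure scanner and re-drawn in the rare pathological
case. Genes are placed as Poisson events at 3.8/Mb with uniform 5–30 kb
lengths, independent of elements; with these defaults ~6–7% of loci fall
inside a gene span, consistent with the observed intergenic fraction.

What the generator does *not* emulate: nested insertions, segmental
duplications, sequence context preferences at integration sites, selection,
indel-dominated decay, or assembly artefacts. Tests passing on this
generator therefore demonstrate the correctness of the pipeline's logic and
estimators under the stated model, not its robustness to every failure mode
of real annotation.

## Numerical and statistical choices

- Consensus ties resolve alphabetically; bipartitions are canonicalised to
  the smaller (then lexicographically smaller) leaf set.
- All randomness flows from explicit seeds; a fixed config reproduces
  byte-identical outputs (the summary echoes every parameter and seed).
- Study sizes used by the test suite and acceptance script: the census runs
  on 4 × 10 Mb chromosomes; environment statistics on 4 × 40 Mb (300 loci);
  TSD recovery on 500 planted events; chimera calling on 400 + 100
  proviruses; dating accuracy on batches of 50 LTR pairs at 1.0 and
  3.7 myr. A single 50-pair batch at 1.0 myr carries only ~73 expected
  substitutions (Monte-Carlo error ~12% of truth), so accuracy assertions
  average over ten replicate batches; the tolerance itself (15%) is
  unchanged. Bias of the K2P age at d ≤ 0.05 is checked at 250 pairs
  (<5%).

## Known limitations

- The merge-gap rule stands in for manual curation; on real annotation,
  adjacent independent insertions of one subfamily closer than the gap
  would be merged.
- The structure scan is heuristic; its categories agree with planted truth
  by construction but have no claim to RetroTector-level accuracy on real
  proviruses.
- Subfamily age is a consensus-based proxy for network rho dating; the two
  can differ when the true genealogy is star-like only approximately.
- Transcription-factor-site scanning, PCR design and population genotyping
  are out of scope.
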