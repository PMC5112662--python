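# Methods

This note documents the models, estimators and numerical choices behind
pairedrec, and what the simulated validation does and does not show
about real data.

## Substitution counting (NG86)

Pairwise dN/dS uses the unweighted pathway-counting method of Nei &
Gojobori (1986) on a gap-edited codon alignment.

* **Sites.** For each codon position, the synonymous fraction among the
  non-stop single-base changes is that position's synonymous-site
  contribution; stop-creating changes are removed from the denominator.
  Per codon S + N = 3 exactly. Totals are averaged over the two
  sequences.
* **Differences.** For a codon pair differing at k positions, all k!
  orderings of single-base steps are enumerated and (Sd, Nd) averaged
  with equal weights. Pathways through stop codons are excluded; in the
  degenerate case where every pathway crosses a stop, all pathways are
  re-admitted with stop-involving steps counted as nonsynonymous.
  Sd + Nd equals the nucleotide Hamming distance of the pair.
* **Correction.** ps = Sd/S and pn = Nd/N are corrected with the
  one-parameter Jukes–Cantor formula −(3/4)·ln(1 − 4p/3). p ≥ 3/4 is
  reported as a "saturated" flag (NaN), not an exception; dS = 0 makes
  the ratio "undefined", and downstream ranking places undefined ratios
  last rather than treating them as infinite — this avoids spurious top
  ranks for nearly identical pairs.
* **Editing rule.** The published analyses removed alignment gaps by
  hand; here every codon column containing a gap, ambiguity symbol or
  stop codon in either sequence is dropped automatically and counted.
  Automated editing is reproducible; it can differ from manual editing
  by a few columns, which motivates the ±0.15 tolerance used when
  comparing dN/dS values computed from published sequences.
* Only the standard genetic code is supported. TSV output rounds to 4
  decimals; internal arithmetic is full precision.

## Conversion-tract detection

Gene conversion homogenises a donor/acceptor tract, so synonymous
substitutions — which accumulate clock-like — are locally absent. The
detector formalises the visual criterion "flat synonymous curve":

* A candidate tract is a maximal run of codon columns with zero
  (fractional) synonymous difference, of length ≥ `min_len`
  (default 15 codons).
* Significance: codon columns are exchangeable under uniform
  divergence, so the null distribution of the longest zero-synonymous
  run is obtained by permuting columns (default 999 permutations,
  seeded). P-values use the add-one rule (b+1)/(B+1) and are therefore
  in (0, 1]; tracts with p ≤ α (default 0.05) are reported. Alignments
  with no synonymous difference at all are "not assessable".
* Multiple tracts in one pair are each compared against the same null
  of the longest run (conservative for secondary tracts); no correction
  is applied within a pair, while Benjamini–Hochberg is applied across
  pairs at report level.
* Exon-boundary concordance: a tract is "exon-restricted" when both
  genomic limits fall within a slack (default 10 nt) of the exon limits
  extended by the 2-nt splice dinucleotides.
* Percent-identity tracks: matches / aligned non-gap columns per
  sliding window (default 100 nt window, 25 nt step — the original
  percent-identity-plot settings are not published); windows with <50 %
  comparable columns are flagged.
* Region contrast: mean per-codon nonsynonymous count inside a named
  set of codon intervals (e.g. the CC′C″FG β-strands) versus the
  remainder, with a one-sided permutation p for enrichment.

## Annotation rules

* **Distinct N exons** are single-linkage clusters at ≤1 % divergence,
  where divergence = 1 − identity over non-gap columns of a global
  nucleotide alignment (match +1, mismatch −1, gap open −5, extend −1).
  The threshold is the published convention; the metric is ours.
* **Gene merging**: consecutive N exons with no non-N exon between them
  belong to one gene; an N exon following a non-N exon (or a leader
  exon) starts a new gene.
* **Pseudogenes**: an in-frame stop inside an N exon, or a flanking
  intron lacking the canonical GT donor / AG acceptor (strand-aware;
  GC donors acceptable behind a config flag, off by default).
* **Motifs** (regular-expression consensi, configurable):
  ITIM `[ILVS]xYxx[ILV]`, ITSM `TxYxx[VI]`,
  ITAM `Yxx[LI]x{6,12}Yxx[LI]`; "ITAM-like" is two Yxx[ILV] modules at
  non-canonical spacing (3–5 or 13–20) or a lone Yxx[ILV] module in an
  ITIM-free tail. Precedence ITAM > ITAM-like > ITIM/ITSM per
  overlapping site. Gene classes: inhibitory (ITIM, no ITAM),
  activating (ITAM/ITAM-like), ambiguous (both; excluded from pairing),
  none.

## Distance trees and orthology

Protein distances are computed on global pairwise alignments (BLOSUM62,
gap open −11, extend −1): p = mismatches/compared columns, Poisson
correction −ln(1−p), saturated at 10 substitutions/site when p = 1.
This replaces the published maximum-likelihood trees with a
self-contained, testable distance approach; for the deep subgroup
splits and ortholog pairs analysed here the grouping is robust to that
substitution.

* **Neighbor joining** with deterministic tie-breaking by label order;
  negative branch lengths are clamped to zero with the deficit moved to
  the sister branch. Validated against (i) exact recovery on additive
  matrices, (ii) an exhaustive ordinary-least-squares topology search
  (all 15 five-taxon topologies; agreement ≥95 % under 5 % multiplicative
  noise — at materially larger noise NJ genuinely departs from the OLS
  optimum, as expected of an agglomerative approximation), and
  (iii) scikit-bio's independent implementation.
* **Bootstrap**: column resampling with replacement, support = % of
  replicate NJ trees containing each bipartition of the full tree.
* **Subgroups**: the NJ tree is cut at its longest internal edge; if no
  internal edge reaches `min_split_edge` (default 0.1
  substitutions/site) the input is flagged "no split". Within- and
  between-group identity ranges are reported.
* **Orthology**: reciprocal best hits across species. In an
  allotetraploid the L and S locus gene sets are compared with the
  diploid relative *separately* (each homeologous locus carries its own
  orthologs), and homeologs are reciprocal best hits across the L/S
  tags within the allotetraploid. A non-reciprocal gene joins an
  ortholog group as a co-ortholog only when its within-group nearest
  neighbour is the reciprocal partner itself and their distance is
  smaller than both cross-species distances (duplication more recent
  than speciation). Paralog pairs are within-species mutual nearest
  neighbours closer to each other than to any cross-species sequence;
  cross-tag (L vs S) pairs are reported as homeologs, never paralogs.
  Ties are broken by label order and flagged.

## Paired receptors, ranking, locus comparison

A paired-receptor pair requires opposing motif classes, N-domain
amino-acid identity ≥80 % (the lower edge of the identity range
observed for such pairs; configurable) and opposite transcriptional
orientation on the same chromosome and subgroup. Genomic distance is
reported but not filtered on. Selection ranking orders ortholog and
homeolog pairs by descending dN/dS with undefined ratios last and ties
broken by pair label; pairs whose activating member carries a detected
conversion tract are tabulated but excluded from the ranking, because a
converted N exon carries the donor's substitution history rather than
its own. Locus comparison assigns every gene of the reference locus
exactly one fate (retained with homeolog / lost), reports gained genes,
the loss fraction (loss + retention = 1), per-subgroup and
per-motif-class breakdowns, and whether a complete paired-receptor pair
survives at each locus.

## The simulator

The generator emulates the inferred history of a two-subgroup paired-
receptor cluster; its defaults are the study conditions.

* **Gene template**: leader (20 codons), N (107), IgC (90), TM (40),
  cytoplasmic (32) exons; introns of 250/300/280/220 nt with enforced
  GT…AG ends; ~700 nt spacers. All exons phase 0.
* **Substitution process**: single-nucleotide proposals at the
  synonymous rate (uniform base kernel; an HKY-style κ knob exists,
  default 1), synonymous changes always accepted, nonsynonymous
  accepted with probability ω of the codon, stop-creating proposals
  rejected. Validated: at ω = 1 the estimated dN/dS is centred on 1.
  Introns and intergenic DNA evolve neutrally at 1.5× the synonymous
  rate (splice dinucleotides frozen, mimicking their purifying
  selection), reproducing the exon/intron conservation contrast used to
  diagnose exon-restricted conversion.
* **Rates and times**: synonymous rate 0.0033 per synonymous site per
  My — chosen so the 120 My separating the two species gives ortholog
  dS ≈ 0.4, squarely in the range where both dN/dS and conversion
  tracts are informative. Speciation 60 My ago and allotetraploid
  duplication 40 My ago are the published divergence times for the two
  frog species. The duplication giving rise to each
  inhibitory/activating pair is placed 200 My ago with older tandem
  duplications laddered at 8 My steps, so paralogs are markedly more
  diverged than orthologs (within-subgroup identity ~40–95 %); the
  second subgroup root derives from the first by a long branch
  (1 substitution/synonymous site, ω 0.8), giving between-subgroup
  identities far below within-subgroup ones.
* **Selection profile**: ω = 0.2 background; ω = 2.0 in five β-strand
  windows of the N domain (codons 32–41, 44–52, 55–63, 78–88, 91–101 —
  the CC′C″FG face) on inhibitory-receptor lineages only. Cytoplasmic
  exons evolve at ω = 0 from a tyrosine-free ancestral tail, so a
  gene's motif content is exactly its inserted cassette (ITIM+ITSM or
  ITAM peptide blocks) — signaling class is a controlled truth, not
  mutational noise.
* **Conversion**: each event copies the donor's present-day N-exon
  tract (default codons 25–103, which covers all selected windows) into
  the acceptor and then lets the acceptor tract drift for twice the
  event age. This end-state construction gives the same pairwise
  divergence as a mid-branch exchange while keeping the truth tract
  exact; what it does not model is three-way correlation structure
  among donor, acceptor and third genes at intermediate times.
* **Demography**: species A keeps one locus (with one recent
  post-speciation duplication of an activating gene); species B carries
  homeologous L and S loci, with 34 of 38 genes (≈89 %) deleted from S.
  The retained S genes are the group-2 inhibitory receptor, two
  GPI-anchored group-2 genes and one motif-less group-1 gene — no
  complete paired-receptor pair survives on S. Two species-A genes are
  pseudogenized (internal stop; corrupted splice donor). Activating
  genes sit on the minus strand, giving paired receptors opposite
  transcriptional orientation.
* **Truth tables** record every gene copy, event, relation and the ω
  profile. Cross-species orthology of conversion acceptors is marked
  *not recoverable*: overwriting the N exon erases the phylogenetic
  signal the caller uses, and such genes legitimately surface as
  within-species paralog groups instead (as converted paired receptors
  do in real trees). Truth-recovery checks therefore require every
  recoverable relation to be called and forbid spurious calls among
  non-acceptor genes.

## What the validation shows — and does not

Passing tests show the estimators are correct against enumeration and
least-squares oracles, calibrated under their own nulls (false tract
calls ≤ α; permutation p-values exact by construction), powered under
the simulated selection regime, and that the integrated pipeline
recovers a known cluster history exactly. The simulator omits indels
inside exons (gap editing is exercised on constructed fixtures, not by
the generator), alignment error (simulated exons are directly
alignable), transition bias and codon-usage bias (uniform kernel by
default), recurrent conversion, and lineage-specific rate variation.
Results on real clusters additionally depend on assembly and alignment
quality, which these tests cannot certify.

## Problem sizes and defaults

Validation sizes: NG86 enumeration over all 61 sense codons and 61×61
codon pairs; 50 neutral replicates of 10,000 codons; 100 + 100 NJ
matrices; 100 conversion-recovery and 200 null replicates (999
permutations each); 100 region-contrast replicates; one full scenario
run (81 gene copies across three loci). Pipeline defaults: identity
threshold 80 %, min tract 15 codons, α 0.05, 999 permutations, 1 %
N-exon divergence threshold, 0.1 subgroup split edge. All thresholds
actually applied are echoed into the run report.
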