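# Methods

`famdiverge` re-traces a comparative analysis of the insect trehalase
(*treh*) and acid-trehalase (*ath*) gene families as a deterministic,
fully testable pipeline.  This note documents the models and procedures,
the parameters that matter, what the synthetic generator does and does not
emulate, and the design decisions taken where the analysis recipe was
genuinely open.

## Anchor domains and alignment trimming

Trehalase proteins carry seven short conserved domains: VIVPGGR,
QWDYPNAWPP, DSKTFVDM, RSQPPL, PRPESYREDY, ELKAA and the glycine-rich
GGGEYE.  Each domain is located per sequence in the degapped row by a
degenerate scan (fewest mismatches wins, ties leftmost; default mismatch
budget 1 per anchor, configurable) and mapped back through the gaps to
alignment columns.  Per-sequence column intervals are reduced to one
alignment-level interval by a modal vote — the most frequent
``(start, end)`` pair, ties to the leftmost — which makes the anchor
coordinates robust to a minority of divergent rows.  An anchor located in
fewer than half of the rows gets no alignment-level interval.  The
alignment is trimmed to the columns between the start of the leftmost and
the end of the rightmost located anchor, both anchor spans included.
Sequences whose anchors cannot be located are flagged but retained, so
divergent paralogs stay in the downstream tree.  All seven domains are
scored for conservation; only the outermost located pair defines the trim
boundaries (whether the glycine-rich domain itself ever bounds the trim is
thus decided by its position, not by fiat).

## Conservation

The consensus is majority rule per column over non-gap residues
(lexicographic tie-break; all-gap columns give `-`).  Conservation per
sequence and domain is the p-distance — the proportion of differing
columns — between the sequence and the consensus over the domain's
columns.  Comparisons use pairwise deletion and treat `X` as
non-information; a domain with no comparable columns yields a missing
value rather than an extreme one.  A per-clade consensus is not used: the
reference is always the global consensus of the trimmed alignment.

## Degenerate motifs

Motif syntax is the compact field notation: literal residues, `X` for any
residue, `[G/A]` for alternatives.  Patterns compile to explicit
position-wise allowed-residue sets (no regex), so the scanner can be — and
is — checked position by position against a brute-force oracle.  The
acid-trehalase panel comprises six motifs in fixed order: the
transmembrane span LFFFFFFFLCFSFTTSML, the cAMP-dependent phosphorylation
site RRXS, the EF-hand-like Ca²⁺-binding motif DTXGDXQITIXD, trehalase
signature motifs PGGRFXEXYXWDXY and QWDXPX[G/A]W[P/A/S]P, and the GPI
anchor motif CRTNYGYSAA.  Presence is reported at budget 0 by default
(the biological claim of interest is the *absence* of canonical domains);
note that the trehalase anchor QWDYPNAWPP is itself a legal instance of
signature motif 2, so that one motif is expected in *treh* proteins too.

The glycine-rich extent measure is this package's own construction (no
published rule exists): locate GGGEYE with budget 1, then grow the region
one residue at a time; a candidate boundary residue is accepted while the
window of up to five residues extending outward from the current edge
(candidate included) is at least 40% glycine.  An inward-facing window
test would creep across glycine-free flanks, so the outward version is
used.  The number is comparable across sequences, nothing more.

## Physicochemistry and topology

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da); `X` contributes the mean residue mass.  Average rather than
monoisotopic masses match the 60–75 kDa scale of full-length trehalases.
Isoelectric point comes from bisection of the Henderson–Hasselbalch net
charge on pH 0–14, iterated to interval convergence; the pKa set is
EMBOSS by default with the Expasy/Bjellqvist set selectable.

The topology predictors are deliberately simple, *documented stand-ins*,
not reimplementations of the published neural/HMM tools: a
transmembrane-like segment is a maximal run of positions in which every
19-residue window has mean Kyte–Doolittle hydropathy ≥ 1.6 (threshold
configurable); runs whose residue spans overlap are merged.  A segment
starting within the first 5 residues and ending before residue 45 of a
protein of ≥ 30 residues is reported as the signal peptide.  An isoform
is *membrane-bound* iff it has at least one transmembrane segment outside
the signal region, else *soluble*.  Calls from external predictors can be
imported from TSV and substituted per protein, restoring tool-faithful
workflows without changing any downstream code.

## Isoform diversity

Isoforms *sensu stricto* are distinct complete protein sequences;
isoforms *sensu lato* are distinct concatenations of the conserved-domain
substrings only (missing domains contribute a placeholder token), so
changes confined to the termini collapse.  The domain set is the seven
anchors for *treh* and the six ATH motifs for *ath*.  When an alignment is
available the sensu-lato signature is read at the modal anchor columns,
which is robust to individual-row scan failures; the per-protein scanning
path exists for unaligned input.  Census ratios (transcripts per gene,
genes per species, isoforms per species) are carried as exact integer
quotients and formatted with `.` decimal separator and nine decimals only
at output time, permitting digit-level comparison with printed tables.
Soluble/membrane percentages are computed over isoforms sensu stricto.

## Micro-synteny and colinearity

A neighborhood is the ordered, stranded list of orthogroup labels of up to
k genes (default k = 5, recorded in output) on each side of a focal gene;
orthogroup labels are an input column — the package never infers
orthology.  Synteny between two neighborhoods is the size of the label-set
intersection.  Colinearity is the longest common *subsequence* of the
label orders (insertions interrupt conserved order without destroying
it), taking the better of the second neighborhood as given and reversed
with strands flipped; on run-length ties the orientation with the higher
strand agreement wins, which makes the score invariant under
reversal-with-flip of either input.  Orientation agreement is the fraction
of matched pairs with consistent relative strand.  The species-pair matrix
reports, per pair, the maximum shared count over neighborhood pairs; a
separate statistic counts orthogroups present in every species'
neighborhoods, since "shared by N species" admits both readings.

## Distance phylogeny

Pairwise p-distances on the trimmed alignment feed canonical
neighbor-joining (Saitou–Nei Q criterion).  NJ is exact on additive
matrices and keeps the pipeline self-contained and deterministic — ties in
Q break by sorted label pair, negative branch-length estimates are clamped
to zero and counted.  The tree is rooted on the distant outgroup sequence
by splitting its subtending edge evenly.  A seeded column-resampling
bootstrap (NJ path only) and a nearest-reference-leaf subfamily labeler
(explicitly heuristic) are provided.  An externally computed
maximum-likelihood Newick tree can be annotated instead of the NJ tree.

## Synthetic data generator

The generator produces complete inputs with the statistical structure the
analysis assumes; its defaults define the package's study conditions.

* **Species tree**: five orders on an ultrametric tree of depth 1.0
  (order stems 0.5, within-order ladders of depth 0.5).  The default
  preset has 3 species per order (15 species); the `insect-like` preset
  uses the published census's species counts per order (40 species).
* **Gene birth–death**: one ancestral gene evolves along the tree;
  within each order's subtree, duplications arrive as a birth process
  with rate 2·ln(m) + loss (so the expected tip count per species is the
  configured m; default m = 4, `insect-like` uses the census's
  genes-per-species per order).  Loss rate defaults to 0.
* **Proteins**: fixed 207-residue architecture — an immutable initiator
  Met, a 21-residue signal zone, the seven anchor instances separated by
  12-residue spacers, a 25-residue transmembrane zone, hydrophilic
  background elsewhere.  Per-site substitution probabilities over an edge
  of length t are 1−exp(−r·t), with per-domain rates (defaults ascending
  0.01…0.08 per unit length, giving a conservation gradient across
  domains) and background rate 0.30; substitutions are uniform over the
  19 alternatives.  The generator logs, per domain, sites, realized
  substitutions and the first two moments of the per-site probabilities,
  so binomial recovery checks need no re-simulation.
* **Plants**: per gene, a signal peptide (probability 0.4) and/or a
  transmembrane segment (0.35) is written into its zone as a hydrophobic
  run at the tips.  Because the background alphabet is hydrophilic, at
  zero topology noise the hydropathy classifier's calls equal the planted
  labels by construction; a noise parameter admixes arbitrary residues to
  degrade this.
* **Transcripts**: 1–4 variants per gene (probabilities .45/.30/.15/.10,
  mean 1.9, matching the 1.2–2.9 transcripts-per-gene range of the
  census), differing only by N-/C-terminal trims of up to 8 residues that
  never touch the domains (signal-bearing genes vary the C terminus
  only, so the signal is preserved in every variant).
* **Genome**: each variant's CDS (fixed codon per residue + stop) is
  split into 2–3 exons with random introns; variants are laid out in
  disjoint segments of the gene span (the generator emulates variant
  *products*, not shared-exon structure), on a random strand, with the
  minus strand stored as the reverse complement.  *ath* genes are
  intronless, single-isoform, and carry all six ATH motifs planted at
  recorded offsets.
* **Neighborhoods**: each order has a conserved block of 5 orthogroups
  shared around every focal gene of its species, padded with
  species-unique fillers to the 2k window; per neighborhood one
  inversion (p = .3), insertion (p = .3) and/or translocation (p = .2)
  may be applied and logged.
* **Alignment**: evolution is substitution-only (no indels), so the
  per-gene representative proteins plus a deeply diverged outgroup copy
  constitute a ready gapless alignment whose coordinates equal the
  planted domain coordinates.  This stands in for the externally computed
  alignment the real workflow consumes.

All randomness flows through one seeded numpy generator; a fixed seed
reproduces every output byte for byte.

**What passing tests do and do not show.**  The generator has no indels,
no rate heterogeneity within domains, no codon structure or selection,
no shared exons between variants, and proteins about one third the
length of real trehalases (hence e.g. mean synthetic MW ≈ 24 kDa versus
60–75 kDa for the real family).  Recovery results on it demonstrate the
pipeline's internal correctness — that each stage computes what it claims
on data satisfying its assumptions — not robustness to real alignment
error, annotation noise or orthology mistakes.

## Packaged census fixture

`famdiverge/data/table2_counts.tsv` carries the published order-level
census of the family (Hemiptera 7/54/93, Lepidoptera 3/9/11, Hymenoptera
15/32/93, Coleoptera 4/29/51, Diptera 11/36/49 species/genes/transcripts;
160 genes, 40 species in total).  The published per-species list does not
sum to those order totals for every order, so the fixture's per-species
rows are a *synthetic allocation* (largest-remainder scaling of the
per-species list, each species keeping ≥ 1 gene and transcripts ≥ genes);
Coleoptera sums exactly and is preserved verbatim, including the 11 genes
of *Aethina tumida*.  Only order totals (and Coleoptera rows) should be
read as data.  The discrepancy is recorded here rather than silently
resolved.

## Numerical choices and degenerate inputs

* Coordinates: files are 1-based inclusive (GFF3 convention); all internal
  arithmetic is 0-based half-open; the io layer is the only crossing point.
* ORF calling searches the three forward frames only (exon assembly has
  already oriented the sequence); longest ATG..stop wins, ties by smaller
  frame then leftmost start; no minimum length.  The reported span
  excludes the stop codon.  Annotated-CDS passthrough is available when
  the ORF call is not wanted.
* Unknown residues map to `X`/`N`, never dropped; `X` never matches a
  literal motif position and never enters p-distance comparisons.
* Empty scan results, empty neighbor lists, all-gap columns, zero-gene
  orders and anchor-missing sequences all produce missing values or empty
  sets, not zeros, so absence is distinguishable from measurement.
* Problem sizes: the default simulation (15 species, ≈ 160 genes,
  ≈ 19 000 domain site-events) keeps a full pipeline run under a few
  seconds while leaving the binomial recovery aggregate comfortably above
  10⁴ sites.

## Known limitations

The topology stand-ins are hydropathy heuristics and will not reproduce
published SignalP/TMHMM calls on real proteins (import real calls via TSV
for that).  NJ replaces the original maximum-likelihood inference;
topologies on real, non-additive distance data will differ in detail.
Subfamily labels are a nearest-reference heuristic, not clade calls.  The
sensu-lato count depends on the anchor set and scan budget, both
configurable and recorded in the run manifest.
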