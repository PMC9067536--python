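# Methods

This note documents the models and algorithms in `rnascout`, the choices
made where the design was genuinely open, and what validation on synthetic
data does and does not establish.

## Scope and stand-ins

The pipeline mirrors a large-scale comparative-genomics workflow for
discovering structured RNAs near Cas operons: homology search, clustering,
structural alignment, covariation assessment, and model-based re-search.
At desk scale, several industrial tools are replaced by explicit,
self-contained stand-ins that preserve the *decision semantics* of each
stage (what passes, what fails, and why) rather than the original
algorithms:

| stage | production tool family | stand-in here |
|---|---|---|
| homology | nucleotide BLAST | seeded banded Smith-Waterman |
| clustering | single-linkage overclustering | union-find over hit graph |
| structural alignment | covariance-model EM (CMfinder-like) | anchor stacking + column-model EM |
| structure score | phylogenetic likelihood (RNAphylo-like) | count-based support score |
| covariation | R-scape | compensatory covariance + permutation E |
| search | covariance-model scan (Infernal-like) | ungapped profile+pair scan |

The numeric gates: contigs > 3 kb, 500 bp flanks,
hit filters (identity < 100%, length ≥ 30, bit ≥ 20), structure score ≥ 10,
covariation E < 0.05, search E < 10⁻⁶ at ≥ 3 distinct regions, antirepeat
E < 0.05.

## Homology

Sequences are compared by seed-and-extend: exact shared words nucleate an
ungapped Kadane extension in a fixed window; segments whose best
≥ 30-column run scores ≥ 15 are re-aligned by banded gapped Smith-Waterman
(match +2, mismatch −3, gap of length k costs 5 + 2k) with full three-state
traceback, so every reported hit's raw score equals the score of its
reported alignment. Karlin-Altschul parameters are fixed (λ = 0.625,
K = 0.41); E-values use the two regions' lengths as the search space
(E-values are informational here — the retention filter is the bit score).

**Seed word length (default 7).** The classic nucleotide-BLAST word of 11
needs ~90% identity before two ~60-nt homologs are likely to share an exact
word. The divergence regime this pipeline targets (per-site substitution
rate θ = 0.2 ⇒ ~65-70% pairwise identity) yields an expected
(L−10)(1−p)p¹¹ ≈ 0.16 shared 11-mers per true pair — an 11-mer-seeded
aligner would miss most true homologies outright. A 7-mer gives about one
shared word per true pair at this identity. Word length is configurable.

Self-comparisons run too (internal repeats are legitimate homology
evidence); only the trivial full-length identity diagonal is suppressed,
and symmetric duplicates collapse to one canonical orientation.

## Clustering

Hit endpoints overlapping by ≥ 1 bp merge into nodes; hits are edges;
clusters are connected components (single linkage: any edge merges two
groups). A maximum-raw-score spanning forest orients members (flipping
across minus-strand edges) and assigns each member a column offset implied
by its strongest linking alignment — these offsets are what make the
anchor-based alignment below possible. Member sequences are extracted with
12 bp of flanking context, because local alignments at moderate divergence
systematically stop short of the true homology boundary and would
otherwise clip motif edges (helices near instance ends lose their pairing
columns to the coverage rule).

## Motif stage

**Units.** One cluster can harbor more than one alignable motif. Clusters
with both orientation blocks of ≥ 3 members emit the whole cluster plus
each block as separate units — this is how a tracrRNA motif (linked to
repeats only through its antirepeat, on the minus strand) can separate
from the repeat family itself. Composition-coherent subgroups (guide-tree
cut at cosine 0.7 over 4-mer profiles) are also split out.

**Alignment.** For same-scale members, sequences are stacked at their
hit-implied offsets (exact for indel-free homologs) after a shift-only
re-registration pass; heterogeneous units (e.g. array-spanning nodes mixed
with single repeats) fall back to progressive profile alignment under an
average-linkage 4-mer guide tree (match +1, mismatch −1, gap −2, free end
gaps). Rows that disagree with the others' consensus at most columns
(members pulled in by spurious hits) are pruned: such rows deviate jointly
across columns and would otherwise manufacture covariation. The alignment
is then polished by one EM-style loop: a column model over the
information-trimmed match columns, each member re-placed at its best
ungapped register (overhangs allowed, partial coverage allowed), repeated
twice. Exact duplicate rows (within-array repeat copies) are collapsed —
they carry no independent evolutionary information and would otherwise
inflate both signal and null. A gap-based realignment polish is
deliberately *not* applied: at 60-70% identity it slides whole rows off
register, and jointly shifted rows fake covariation.

**Folding.** Nussinov-style maximization of total pair support
`B(i,j) = c_ij − (n_ij − c_ij)` over nested structures with loop ≥ 3,
where `c` counts rows forming canonical pairs (AT/TA/GC/CG/GT/TG on DNA)
and `n` rows with both columns non-gap; pairs are admissible when
n ≥ N/2 and B > 0. Traceback prefers pairing, then leaving i, then j, then
the smallest bifurcation split, making structures deterministic.

**Structure score.** `Σ_pairs [0.5·c − 1.0·(n−c) + 2·v]` with `v` the
number of distinct canonical pair types beyond the first; motifs pass at
≥ 10. This is a deliberately simple surrogate for a phylogenetic
structure-support score; the gate's numeric threshold transfers in spirit
only.

**Covariation.** The tested statistic is a compensatory covariance in the
RNAalifold tradition: for a column pair, each pair of rows whose canonical
pair types differ on *both* sides contributes 1 (normalized by all row
pairs); rows breaking canonical pairing subtract their fraction. One-sided
(wobble-type) transitions are excluded — a single substitution that
happens to preserve pairing arises readily in unstructured conserved
sequence, whereas a two-sided pairing-preserving change is the specific
signature of a maintained helix. Mutual information with average-product
correction (MIp) is computed alongside and reported per pair.

Significance comes from a column-permutation null: each replicate permutes
every column's non-gap residues among its non-gap rows; a pair's E-value
is the expected number of null values per replicate at or above its
observed statistic (pooled over the structure's pairs). Because the fold
*selected* its pairs on the same data, a pair-level test alone passes
coincidences at a measurable excess; a motif is therefore significant only
if additionally the *number* of positive-covariance structure pairs beats
its permutation null (the "ladder" test — a real helix covaries along its
ladder, a lucky decoy pair stands alone). An optional selection-aware null
(each replicate tests its own best-supported disjoint pairs) is stricter
still; it controls false positives near-perfectly but at a substantial
power cost at these sample sizes, and is off by default.

**Refinement.** Motifs passing the gate are refolded with pair support
`B' = B + max(MIp,0)·N`; the structure with more significant pairs (ties:
higher structure score) is kept, so refinement never loses significant
pairs.

Units with fewer than 4 rows cannot pass the covariation gate: with three
row pairs, any single coincidence dominates the statistic.

## Search

Models are per-column log-odds `log2((count+1)/(N+4)/bg)` over match
columns (< 50% gaps) plus per-pair log-odds for consensus pairs, refit once
against the cluster members (ungapped best-window re-estimation, adopted
only if it does not degrade the fit). Every window on both strands of
every region is scored; ambiguous bases contribute the background
expectation (zero). The null is dinucleotide-preserving shuffles
(Altschul-Erikson) of all regions; E(s) = M·P(S ≥ s) with M the real
search's window count and a survival function that is empirical within the
null sample and switches to a Gumbel tail (ML fit on the top 1%) beyond
the 99th percentile — so E at the median null score is M/2 by
construction, and extreme scores extrapolate smoothly. Models whose
significant windows (E < 10⁻⁶, merged per region to the peak window)
cover ≥ 3 distinct regions become candidates; dedup is greedy by model
width (ties by id), and candidates overlapping known-structure intervals
are subtracted.

The scan is ungapped and fixed-width: indel-tolerant covariance-model
search is a tool in its own right, and the synthetic data is generated
without indels; this is a documented limitation for real data.

## Classification

Category priority: `direct_repeat` if > 50% of instances overlap array
repeat intervals; else `tracrRNA_like` if the candidate has an antirepeat
link (below) and > 50% of instances lie within 100 bp upstream of a cas9
start (or over it); else `coding_overlap` if > 50% overlap genes; else
`intergenic`. Palindromicity is the match fraction of a free-end-gap
alignment of the candidate consensus against its own reverse complement
(lexicographically maximizing score, then matches, so the value is well
defined among co-optimal alignments); ≥ 0.7 flags a candidate palindromic.
Antirepeat assignment aligns each array's consensus repeat against all
regions, discards hits with E ≥ 0.05 or overlapping any array
(self matches), and links arrays to candidates whose instances the
surviving hits intersect; an assigned array inherits the modal subtype of
the operons its candidate occurs in.

## The synthetic generator

Contigs are iid background (configurable GC) carrying labeled Cas operons
(one per contig, subtype-consistent gene lists; II-C operons contain cas9),
CRISPR arrays downstream of II-C/I-C operons, structured RNA families,
unstructured conserved decoys, and a tracrRNA upstream of each II-C cas9.
Structured families follow a star phylogeny: instances derive independently
from a consensus by iid per-site substitution (θ, default 0.2); a
substitution at a paired site is, with probability ρ (default 0.9), a
compensatory event replacing both partners with a different canonical pair.
Pair events are owned by the 5′ partner and always change both sides, so
stem and loop positions realize the same per-site substitution rate —
structured and decoy families share one identity distribution and differ
only in whether pairing is preserved (a property the tests check
directly). Default family lengths are 32-109 nt with 1-2 helices of
4-8 bp and loops ≥ 3.

Within an array, repeats are exact copies; across arrays of one subtype,
repeats derive from a shared structured consensus (one hairpin) at
divergence 0.08 — low enough that repeat-antirepeat homology remains
detectable at E < 0.05, which the array-assignment stage requires. Repeat
lengths default to 30-40 nt because the pipeline's own ≥ 30-column filter
makes shorter repeats undiscoverable. The tracrRNA is the reverse
complement of its operon's array repeat (divergence µ = 0.10) plus a
conserved stem-loop tail, placed 5-25 bp upstream of cas9.

What the generator does *not* emulate: indels, tree-structured phylogeny,
Markovian background composition, realistic protein-coding sequence,
taxonomic structure, or the scale of real metagenomic surveys. Passing
tests on this data demonstrates the machinery recovers planted signal
under its stated model, not field performance.

## Operating characteristics and limitations

`scripts/acceptance.py` computes the pipeline's operating characteristics
on the standard scenario at run time; the points below summarize what
drives them.

* **Power is capped by the hit filters at the scenario's divergence.** At
  θ = 0.2, a ~60 nt homolog pair aligns at ~65% identity, where the
  expected raw score barely clears the bit ≥ 20 threshold; short families
  often cannot produce any retainable hit, and longer ones fragment into
  partial windows. Clusters therefore under-sample their families, and
  motif units inherit reduced depth. This is a property of the published
  filter cascade, not of the implementation.
* **Pair-level covariation at depth ~10 is coincidence-prone.** The fold
  chooses pairs on the data it is then tested on; the ladder test removes
  most of the resulting excess, and the optional selection-aware null
  removes essentially all of it at a large cost in power. The default
  configuration favors power while keeping decoy acceptance low.
* **Repeat families carry thin covariation evidence by construction.** A
  subtype has 3-5 arrays whose repeats must stay ≥ ~75% identical for the
  antirepeat homology search to work, leaving roughly one compensatory
  event per stem pair across the whole family; direct-repeat candidates
  therefore pass the covariation gate only in a fraction of runs. The
  original large-scale setting had thousands of arrays per repeat model.
  The same applies to the tracrRNA's 5-copy tail.
* **Determinism.** All stochastic stages draw named substreams from the
  single root seed; identical inputs, config and seed give byte-identical
  outputs, which the tests assert.

Numerical conventions: coordinates are 0-based half-open throughout
(BED convention); DNA is stored internally with T, rendered as U only in
Stockholm output; N matches nothing anywhere; all tie-breaks (alignment
traceback, fold traceback, dedup ordering, modal subtype) are
deterministic and documented at their definition sites.
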