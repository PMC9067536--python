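# rnascout

Comparative-genomics discovery of candidate structured RNAs in CRISPR-Cas
loci, with a synthetic locus generator for end-to-end validation.

## The problem

CRISPR-Cas systems are steeped in structured noncoding RNA — crRNA direct
repeats, tracrRNAs, scoutRNAs — and more such elements likely remain
unannotated. Given a collection of contigs with predicted Cas operons and
CRISPR arrays, `rnascout` searches the surrounding sequence for conserved
elements whose substitution pattern shows the hallmark of maintained base
pairing: compensatory (covarying) substitutions.

The pipeline is a staged funnel:

1. **Region extraction** — Cas operon and CRISPR array loci (contigs > 3 kb)
   are extended by 500 bp on each side, merged, and extracted.
2. **All-vs-all homology** — a seeded local aligner (seed-and-extend, banded
   gapped Smith-Waterman) compares every pair of regions on both strands.
   Raw scores *S* convert to bit scores and E-values by Karlin-Altschul
   statistics, `bits = (λS − ln K)/ln 2`, `E = K·m·n·e^(−λS)` with the
   standard λ = 0.625, K = 0.41 for the +2/−3 (5,2) system. Hits are kept
   when identity < 100%, alignment length ≥ 30, and bit score ≥ 20.
3. **Single-linkage clustering** — overlapping hit endpoints merge into
   nodes; hits are edges; clusters are connected components, orientation-
   and register-normalized along a maximum-score spanning tree.
4. **Motif analysis** — per cluster: alignment (hit-anchored stacking with
   an EM polish, or progressive profile alignment), Nussinov-style
   consensus folding maximizing pair support `B(i,j) = c − (n − c)`, a
   structure-support score gate (≥ 10), and a covariation gate: each
   consensus pair's compensatory covariance is tested against a
   column-permutation null (E < 0.05, plus a motif-level ladder test).
5. **Search** — each surviving motif becomes a log-odds profile+pair model,
   scanned over all regions; E-values are calibrated on dinucleotide-
   preserving shuffles; models that hit ≥ 3 distinct regions at
   E < 10⁻⁶ become candidates. Overlapping candidates deduplicate
   longest-first, and candidates overlapping known structures are removed.
6. **Classification** — candidates are binned into `direct_repeat`,
   `tracrRNA_like`, `coding_overlap`, or `intergenic`; array repeats are
   aligned to all regions to find antirepeats (E < 0.05, self matches
   excluded), linking CRISPR arrays to candidates and assigning subtypes.

A bundled generator (`rnascout simulate`) plants Cas operons, CRISPR arrays,
covarying RNA families, unstructured conserved decoys, and a tracrRNA with
an antirepeat into synthetic contigs, and records everything in a truth
manifest — so every stage can be validated against known ground truth.

## Worked example

```bash
rnascout simulate --seed 11 --out sim/
# wrote 20 contigs, 33 genes, 8 arrays, 234 truth records to sim/

rnascout run --contigs sim/contigs.fasta --genes sim/genes.tsv \
             --arrays sim/arrays.tsv --seed 11 --out run/
# funnel: regions=10 hits=878 clusters=13 aligned=13 score=13 covary=4
#         searchable=4 dedup=4 final=4
```

Ten extracted regions produced 878 filtered hits and 13 clusters; 4 passed
the structure and covariation gates and re-detected enough regions to be
retained. `run/candidates.bed` lists every candidate instance with
`-log10 E` as the score:

```
contig002   14474   14535   cluster0000   13.64   +
contig004   3446    3507    cluster0000   13.0    +
contig005   8849    8910    cluster0000   14.43   +
```

`run/categories.tsv` carries the category call and palindromicity per
candidate, `run/assignments.tsv` the antirepeat-based array assignments,
`run/candidates/*.sto` the final Stockholm alignments with `#=GC SS_cons`
and the significant covarying pairs, and `run/report.json` the funnel.

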