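# Methods

`panveil` re-implements, as a tested pipeline, the comparative pan-genome
analysis applied to small within-species bacterial strain panels (the
motivating case is a nine-strain *Veillonella atypica* panel): ortholog
clustering of all proteins, core/accessory/specific partitioning,
gene-accumulation curves with an openness verdict, two strain phylogenies,
partition-stratified functional summaries, and CRISPR-array detection.
Because the original panel's inputs (NCBI assemblies, versioned annotation
databases) are not reproducible at the desk, a synthetic strain-set
generator with exact ground truth stands in for them; every stage is
validated by recovery of planted structure, plus replays of the published
panel's printed arithmetic.

## Synthetic strain sets

`simulate.SimulationConfig` fixes the study conditions. Defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `n_strains` | 9 | panel size, matching the real nine-strain panel |
| `n_core` / `n_accessory` / `n_specific` | 150 / 60 / 5 | family counts; ~70% core preserves the real panel's ~73% core fraction at ~1/10 scale |
| `mean_protein_length` | 300 aa | typical bacterial protein length (Poisson per family, min 30) |
| `divergence` | 0.05 | expected substitutions per site per unit branch length; with a height-1.0 tree this gives ≥~90% identity between the most distant strains — within-species protein divergence |
| `paralog_rate` | 0.02 | probability a present strain gains one extra in-paralog copy (core/accessory families) |
| `specific_copies` | 2 | gene copies of a strain-specific family (the real panel's specific families were all multi-copy); configurable, interpreting the ambiguous "more than two" as ≥2 |
| `genome_length` / `gc_content` | 100 kb / 0.39 | nucleotide genome scale (GC matches the real panel's ~39%) |
| `array_specs` | 4 heterogeneous arrays, one truncated | planted CRISPR arrays, repeats 23–55 bp |

The strain tree is a random binary rooted ultrametric tree: uniform random
joins at sorted-uniform heights rescaled so the root sits at exactly 1.0.
Sequence evolution is i.i.d. substitution only — each site is replaced,
with probability `divergence × branch_length`, by a draw from a fixed
embedded amino-acid background frequency vector (the draw may equal the
original residue, which models coincident/back substitution). There are no
indels: this keeps alignment-stage expectations exact (a substitution-only
family must align gap-free at the ancestral length). In-paralog copies
diverge from their strain's leaf sequence at one tenth of the configured
divergence, so duplicates are always closer to each other than to
orthologs in other strains — the property the OrthoMCL edge rules rely on.
Strain-specific families default to two identical-origin copies so they
form clusters rather than singletons.

What the generator deliberately does **not** emulate: indels, rate
heterogeneity across sites, codon/operon structure, horizontal transfer,
fragmented assemblies, and annotation errors. Recovery results on this
model therefore certify the algorithmic chain (search → graph → MCL →
partition → trees), not robustness to real-data artefacts such as split
genes or contaminated proteomes.

CRISPR truth: each planted array is `n_units` exact repeat copies
interleaved with random spacers; an optionally truncated terminal repeat
keeps its first ⌈R/2⌉ bases. Arrays are placed ≥100 bp from sequence ends
and ≥100 bp apart, coordinates recorded 0-based half-open.

Annotation truth: each true cluster draws, per namespace (CAZy-style
family tokens, COG category letters, opaque GO terms), a label with
probability `label_rate`; the label propagates to every member protein, so
cluster-level recovery has an exact expected answer.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; fixed seed ⇒ byte-identical outputs.

## Similarity search

Every protein pair is scored by optimal Smith–Waterman local alignment
(Biopython's C aligner) with BLOSUM62 and affine gaps 11/1 — the de facto
protein-search defaults — modified so X scores 0 against everything.
E-values use the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the gapped
BLOSUM62 constants K=0.041, λ=0.267, `m` the query length and `n` the
total residue count of the database; hits with E < 1e-5 (the panel's
ortholog-search threshold) are retained, in both directions per pair.
E-values are floored at 1e-300 so `−log10 E` edge weights stay finite;
close homologs therefore saturate at weight 300, as they do in real
BLAST-based OrthoMCL runs. Only ordering and thresholding matter
downstream, not absolute E-value calibration.

A shared-k-mer prefilter (k=5) skips pairs with no exact 5-mer in common.
For within-species homologs at ≤10% divergence, runs of ≥5 conserved
residues are essentially certain, so the prefilter is conservative at the
default cutoff; its equivalence to exhaustive search is property-tested on
simulated proteomes rather than assumed.

## Ortholog graph and Markov Clustering

Pair weight = average of `−log10 E` over both directions (one-directional
pairs are dropped). Edges follow the OrthoMCL scheme — the original tool
names only its two parameters, so the internals are design choices made to
match the published algorithm:

* **ortholog**: inter-strain reciprocal best hits; all partners within
  1e-3 of the best weight count as best (float-safe ties);
* **in-paralog**: intra-strain pairs whose weight reaches both members'
  best inter-strain weight (0 for genes with no inter-strain hit, so
  strain-specific duplicates always qualify);
* **co-ortholog**: inter-strain pairs with a direct hit connected through
  an ortholog edge between the two in-paralog groups.

Weights are rescaled by the class mean — per strain pair for orthologs,
globally for in-/co-ortholog classes. MCL then iterates expansion (matrix
squaring), inflation (entrywise power, default 1.5 as in the panel study,
column renormalisation) and pruning (<1e-5), to a 1e-6 fixed-point
tolerance with a 100-iteration cap; it runs dense per connected component
(components are family-sized, and MCL cannot merge disconnected
subgraphs). Clusters are connected components of the converged nonzero
structure; single-member components are reported as singletons and
excluded from the pan-genome cluster count, mirroring the published
panel's multi-gene specific families.

## Partition, curves, openness

Core = present in all strains; specific = present in exactly one strain
(regardless of copy number); accessory = the rest (≥2 but not all);
single-copy core = exactly one copy everywhere. Accumulation curves use
random strain orderings (exhaustive when N ≤ 7, else 1,000 seeded
permutations); `pan(k)`/`core(k)` are cumulative union/intersection
presence counts. Openness is judged Tettelin-style because the source
analysis gives only a visual plateau judgment: the median new-cluster
count `n_new(k)` for k ≥ 2 is fitted as `κ·k^(−α)` by log–log least
squares (zero medians excluded; all-zero ⇒ closed with γ=0 and a tiny
positive κ sentinel), and the pan-genome is **open** iff α < 1
(γ = 1 − α > 0).

## Phylogenies

**Single-copy-core tree.** Each single-copy-core family is aligned by
progressive profile alignment: pairwise global-alignment identity
distances feed a UPGMA guide tree, profiles merge child-first with
affine-gap Needleman–Wunsch (Gotoh) over expected BLOSUM62 column scores
(numba kernel). Columns with gap fraction > 0.2 or modal-residue frequency
< 0.5 are removed (a two-threshold stand-in for Gblocks' intent of
dropping divergent/gappy regions). Families are concatenated in fixed
order; pairwise distances are p-distances over mutually ungapped columns,
Poisson-corrected (−ln(1−p), capped at 23 for saturated pairs); the tree
is neighbor joining (negative branches clamped to 0 with a warning).
Distance methods replace the original maximum-likelihood step
deliberately: the quantity of interest here is topology recovery on
simulated panels, for which NJ on corrected distances is consistent and
orders of magnitude cheaper; the trade-off is the loss of ML branch-length
estimates and model flexibility, which nothing downstream consumes.

**Pan-genome tree.** Manhattan distance between strain presence profiles
(binarised by default — the source analysis is stated on absence/presence;
raw copy numbers behind a flag), then UPGMA (merge height = half the
average inter-cluster distance, so the output is ultrametric by
construction). All tie-breaks in UPGMA/NJ are lexicographic on the
smallest contained leaf label, making every builder deterministic.

**Support and comparison.** Bootstrap resamples alignment columns (or
cluster columns for the pan-genome tree) with replacement, 100 replicates
by default, and reports percent support on internal edges of the point
tree. Tree comparison uses the Robinson–Foulds distance over canonicalised
non-trivial splits.

The tree-recovery experiment uses 40 single-copy families of mean length
250 aa (~10,000 concatenated columns) over 20 seeded panels — about 1/10
of the real panel's 1,468-family concatenation, chosen to keep a full
20-panel replication fast while retaining several expected substitutions
on even the shortest internal branches.

## Annotation summaries

Database scans (dbCAN, COG BLASTP, eggnog-mapper) are out of scope; the
module ingests their tabular outputs. The best-hit filter drops hits with
E > 1e-4 and keeps the single top-bit-score row per protein (ties: lower
E, then lexicographic label) — the COG assignment rule of the source
analysis; the filter is idempotent. Cluster lifting defaults to the
majority rule (> 50% of annotated members; exact ties report all tied
labels flagged ambiguous), which tolerates one mislabeled paralog; `any`
gives union-style reporting. Stratified outputs are cluster counts per
(label × partition stratum) and gene copies per (strain × label); when all
core clusters are single-copy, core-derived label counts are identical
across strains by construction. CAZy labels must match the family grammar
(GT/GH/CE/PL/CBM/AA/SLH + number), COG labels are single letters, GO terms
are opaque (no ontology traversal — the source figures are flat category
bars).

## CRISPR detection

CRT/CRISPRCasFinder-style: exact 8-mer seeds recurring within the period
window anchor a candidate repeat pair; the pair is extended to the maximal
exact match; unit length must fall in 23–55 bp and the implied spacer in
0.5–2.5× the repeat; the detector then walks outward collecting units
whose identity to the first unit is ≥ 0.8, searching a spacer-bounded
window each step. Terminal boundary columns not conserved across **all**
units are trimmed (the pairwise extension can overshoot when flanking
bases match by chance — with only two units that overshoot is
information-theoretically unresolvable, so reported coordinates may be
fuzzy by 1–2 bp in that case). A terminal partial unit of ≥ ⌊R/2⌋ bases
matching the consensus prefix/suffix is kept and flagged truncated; it
must clear a stricter identity bar (0.9) because a partial unit carries
fewer informative bases — at 0.8, a maximised search over a ~75-position ×
~20-length window accepts chance matches in background sequence. Arrays
need ≥3 units (2 behind a permissive flag); the consensus is the
columnwise modal base; overlapping candidates resolve greedily by unit
count then leftmost start; up to 100-bp flanks are attached (the flank
convention of the source study). Scanning is forward-strand only: an
exact-repeat array is the same object on either strand, so
reverse-complement scanning is redundant (toggle documented in code).
Coordinates are 0-based half-open internally; GFF3 export is 1-based.

## Numerical and degenerate-input choices

* MCL columns renormalise to sum 1 after every inflation; a column emptied
  by pruning is revived as its own attractor.
* Saturated protein distances (p → 1) cap at 23 substitutions/site.
* Empty presence matrices partition to an empty partition; clusters
  present in no strain are rejected.
* `local_align` returns the empty alignment (0, 0, 0.0) when all scores
  are non-positive (the Smith–Waterman floor).
* All validation errors are `ValueError`s naming the offending parameter;
  the workflow CLI maps configuration errors to exit code 2 and missing
  stage inputs to exit code 3.

## Known limitations

* No indel simulation means the aligner's gap handling is exercised only
  by unequal-length and constructed cases, not by the recovery
  experiments.
* E-value saturation at 1e-300 flattens weight differences among close
  homologs; cluster boundaries then rest on graph topology rather than
  weight contrast (as in real capped-E pipelines).
* The openness verdict on a closed simulated panel correctly comes out
  "closed" (α ≥ 1): a fixed family pool is exhausted by few strains. An
  open verdict on real data reflects new-family discovery that this
  generator does not model.
* CRISPR boundary coordinates can be off by 1–2 bp for two-unit evidence
  (see above); unit counts and truncation flags are unaffected.
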