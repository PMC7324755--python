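# panveil

Comparative pan-genome analysis for small within-species bacterial strain
panels — the analysis chain applied to panels like the nine sequenced
*Veillonella atypica* strains — with a ground-truthed synthetic strain-set
generator so every stage is testable without downloading assemblies or
annotation databases.

The pipeline: all-vs-all protein similarity search → OrthoMCL-style
ortholog graph → Markov Clustering → core/accessory/specific partition →
gene-accumulation curves and Heaps-law openness → single-copy-core and
presence/absence phylogenies → partition-stratified functional summaries →
CRISPR repeat–spacer array detection.

## Who this is for

Microbial comparative genomicists who want a small, fully inspectable,
deterministic implementation of the standard pan-genome workflow — for
teaching, for method checking, or as a harness for testing how well the
classic algorithm chain recovers known structure.

## The models and statistics at the core

* **Ortholog clustering.** Proteins are nodes; pair weights are the
  average of −log₁₀ E over both directions of a Smith–Waterman search
  (BLOSUM62, affine gaps 11/1, Karlin–Altschul E = K·m·n·e^(−λS),
  E < 10⁻⁵). Edges are classified as orthologs (inter-strain reciprocal
  best hits), in-paralogs (intra-strain pairs tighter than either member's
  best inter-strain hit) and co-orthologs, normalised per class, and
  clustered by Markov Clustering — expansion M←M², inflation
  (entrywise power 1.5, column renormalisation), pruning — to a fixed
  point. Clusters are the pan-genome's unit of accounting.
* **Partition.** For presence matrix X (strains × clusters, copy
  numbers): core ⇔ present in all N strains, specific ⇔ present in
  exactly one, accessory otherwise; single-copy core ⇔ xᵢc = 1 ∀i.
* **Openness.** Over random strain orderings, the median number of new
  clusters contributed by the k-th genome is fitted as n_new(k) = κ·k^(−α)
  (log–log least squares); α < 1 ⇒ open pan-genome (Heaps' law,
  γ = 1 − α).
* **Phylogenies.** (a) Single-copy-core families aligned (progressive
  profile NW), filtered (gap fraction > 0.2 or modal residue < 0.5
  dropped), concatenated; Poisson-corrected p-distances
  d = −ln(1 − p); neighbor joining with 100 column-bootstrap replicates.
  (b) Manhattan distance d(i,j) = Σc |xᵢc − xⱼc| on binarised presence
  profiles, UPGMA (ultrametric by construction).
* **CRISPR arrays.** CRT-style detection: exact k-mer seeding, maximal
  pair extension, repeat length 23–55 bp, spacers 0.5–2.5× the repeat,
  ≥ 3 units at ≥ 0.8 identity to the consensus, truncated terminal
  repeats (≥ half length, stricter 0.9 identity) kept and flagged,
  100-bp flanks attached.

See `docs/methods.md` for assumptions, parameter rationale and
limitations.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
nine-strain panel (150 core / 60 accessory / 5 specific families,
divergence 0.05, seed 11) and narrate what they find:

```bash
python analysis/01_simulate_panel.py --seed 11
python analysis/02_cluster_orthologs.py --seed 11
python analysis/03_partition_pangenome.py --seed 11
python analysis/04_build_trees.py --seed 11
python analysis/05_summarize_annotations.py --seed 11
python analysis/06_detect_crispr_arrays.py --seed 11
```

Output of steps 02–04 (verbatim):

```
215 clusters (+9 singletons) from 1712 proteins
adjusted Rand index vs planted families: 0.9936

simulated panel: 215 clusters — 150 core / 60 accessory / 5 specific; 136 single-copy core
Heaps fit: alpha=2.22, gamma=-1.22 -> closed pan-genome
published-panel replay: core 73.22% of 2065 clusters; 16948 proteins in total

single-copy-core tree: 136 families, 40639 filtered alignment columns
Robinson–Foulds distance to the generating strain tree: 2
```

Reading this: the clustering stage recovers the 215 planted families
nearly perfectly (ARI 0.99; the 9 singletons are in-paralog copies split
from their family), and the partition reproduces the planted 150/60/5
split exactly. The single-copy-core tree matches the generating strain
tree except for one split (RF 2 of a possible 12) sitting on an internal
edge of length ~1e-4 with 94% bootstrap support — at this panel's
divergence that edge carries almost no substitutions, and the dedicated
recovery experiment (`scripts/acceptance.py`) shows RF = 0 on 20/20
paralog-free panels. The *closed* verdict is correct for a simulated
panel: its family pool is fixed, so new-cluster discovery decays faster
than any open pan-genome — unlike the real panel, whose printed counts
(1,512 core of 2,065 clusters = 73.22%, 16,948 proteins) the same summary
functions replay exactly. The same pipeline is available as a single
entry point (`panveil --seed 11 --outdir results/run`) or as the library
call `panveil.run_pipeline(RunConfig(...))`.

To analyse real data instead, point the pipeline at per-strain protein
FASTA files (`<strain>.faa`, ids `strain|gene`), optional genome FASTA for
the CRISPR stage, and externally produced annotation tables (TSV:
protein_id, namespace, label) — the stages read and write plain
BLAST-tabular, groups-file, TSV and Newick formats throughout.

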