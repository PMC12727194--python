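# cognate

**Co**nserved **g**ene **n**eighborhoods **a**round a **t**arget gene family,
**e**valuated per phylogenetic clade.

Genes that must act together — a target enzyme and its maturation factors
(chaperones, endopeptidases, metal-insertion proteins) — tend to stay
physically close on prokaryotic genomes. `cognate` turns that signal into a
concrete report: for every phylogenetic clade of a target gene's homologs,
which gene families are conserved in its genomic neighborhood?

## What it computes

1. **Homolog harvest.** Query protein(s) are searched against all
   protein-coding genes of the input genomes (Smith–Waterman, BLOSUM62,
   Karlin–Altschul E-values; defaults E ≤ 10⁻⁵, aligned coverage ≥ 70%).
2. **Neighborhoods.** Each hit is taken with the 10 genes around it (five
   upstream, five downstream in gene order; truncated at contig ends).
3. **Gene clusters.** All neighborhood proteins are compared all-against-all;
   the similarity graph (edge weight −log₁₀ E) is partitioned by Markov
   clustering (inflation 1.2). Clusters get integer IDs ranked by size,
   0 = largest — cluster 0 is normally the target family itself.
4. **Target tree.** The target cluster's sequences are aligned (built-in
   progressive aligner, or supply your own MSA), pairwise distances are
   Poisson-corrected, *d* = −ln(1 − *p*), with pairwise deletion of gaps,
   and a neighbor-joining tree is built and midpoint-rooted.
5. **Clade cutting.** Leaves are partitioned into clades under a distance
   threshold. Five methods: `avg_clade` (default, threshold 0.5),
   `leaf_dist_max`, `leaf_dist_min`, `root_dist`, `single_linkage`; the
   partition is the exact minimum-cardinality one for the constraint, with
   singleton clades labeled −1 (unclassified). A k-means partition of the
   distance matrix is available for comparison.
6. **Conservation scoring.** Per clade, the member genes of its anchors'
   neighborhoods are pooled (deduplicated), counted per cluster ID, and each
   count is divided by the number of strains in the clade — the *criteria
   score*. Cluster IDs with score > 1.0 (configurable, e.g. > 0.9) form the
   clade's **gene cluster list (GCL)**, printed as `0|1|2|…`.
7. **Evaluation.** Given an external reference classification of the target
   homologs (e.g. a curated enzyme class table), clade quality is scored in
   both directions: distinct classes per clade and distinct clades per
   class, each total divided by the clade count (1.0 = perfect 1:1).

## Worked example

The package ships a seeded pangenome simulator so the whole workflow can be
exercised without downloads. Eight strains, two planted clades, and one
companion gene family planted next to the target in each clade:

```sh
cognate simulate --out demo/fixture --n-strains 8 --seed 11
cognate run --genomes demo/fixture --query demo/fixture/query.faa --out demo/run
cat demo/run/gcl_summary.tsv
```

```
clade_label	gcl_string
1	0|1
2	0|2
```

Reading this: the target homolog tree was cut into two clades (8 leaves
each). Both clades conserve cluster 0 — the target family itself — and each
clade additionally conserves exactly one companion family (clusters 1 and 2),
which is precisely what was planted. The per-cluster detail in
`demo/run/gcl.tsv` shows the underlying arithmetic, e.g. for clade 1:

```
clade_label  n_anchors  n_strains  cluster_id  count  score  conserved
          1          8          4           0      8    2.0       True
          1          8          4           1      8    2.0       True
```

8 cluster-0 genes pooled over 4 strains gives a criteria score of 2.0 > 1.0,
so cluster 0 enters the GCL. Other outputs of the run: `hits.tsv`,
`neighborhoods.tsv`, `clusters.tsv`, `cluster_summary.tsv`, `distances.tsv`,
`tree.nwk`, `clades.tsv`, `sweep.tsv` (clade counts over thresholds
0.05–1.0), `legend.tsv` + `annotated.nwk` (clade-labeled tree), and
`evaluation.tsv` when a reference class table is supplied. Re-running the
same command skips completed stages via `manifest.json`; changing a
parameter reruns only the stages downstream of it.

Real genomes go in the same way: a directory of GenBank flat files or
GFF3 + protein-FASTA pairs, plus a query FASTA. Externally computed
similarity tables (12-column tabular hits) and alignments can substitute for
the built-in search/aligner stages.

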