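# podmat

Pod-maturation transcriptome inference toolkit: a tested, reusable
implementation of a fold-change-based pipeline for identifying maturation
genes from staged bulk RNA-seq designs, exercised end-to-end on a synthetic
data generator with a ground-truth manifest.

The pipeline covers:

- **Replicate QC** — hierarchical clustering (Chebyshev distance, UPGMA) of
  the common top-expressed genes; replicates that cluster away from their
  (genotype, stage) group are flagged and dropped.
- **DEG calling** — a gene is up-/down-regulated for a genotype when its
  signed fold change on stage-mean FPKM exceeds the threshold (default 2,
  strict) in *every* (mature stage, immature stage) pair.
- **Cross-genotype intersection** — shared, genotype-exclusive and
  direction-conflicting DEG sets.
- **Cross-species concordance** — shared DEGs kept only when a reference
  homolog supports the same direction; the concordant union is the final
  maturation gene set.
- **Promoter motif scanning** — strand-aware promoter extraction (TSS − 500
  bp to TSS + 100 bp), log-odds PWM scoring, exact p-values by dynamic
  programming over discretized score distributions, and evidence-class
  filtering (motif / motif_CE / FunTFBS).
- **Enrichment** — hypergeometric / one-sided Fisher tests, BH adjustment,
  term over-representation, and per-TF binding-site enrichment with target
  assignment.
- **Ordination** — correspondence analysis of sample × gene tables, plus a
  ddCt qPCR utility.
- **Synthetic data** — a seeded generator emulating the 2-genotype ×
  5-stage × 3-replicate design with planted up/down genes, genotype-
  exclusive DEGs, a discordant replicate, homolog maps with concordant and
  discordant reference directions, annotation terms and promoters with
  planted motif sites; every planted signal is recorded in a JSON manifest.

## Command line

Every stage is exposed as a `podmat` subcommand; `podmat synth` writes a
complete fixture bundle in plain-text formats (TSV, GFF3, FASTA, MEME
minimal, JSON manifest) to drive the rest:

```sh
podmat synth --seed 1 --n-genes 2000 --out fixture/
podmat qc   --matrix fixture/counts_PMB0225.tsv --matrix fixture/counts_PHA1037.tsv \
            --design fixture/design.tsv --models fixture/genes.gff3 \
            --top 100 --out qc/
podmat deg  --matrix fixture/counts_PMB0225.tsv --matrix fixture/counts_PHA1037.tsv \
            --design fixture/design.tsv --models fixture/genes.gff3 \
            --threshold 2 --pseudocount 0.01 \
            --drop PMB0225_ANT45_R2 --out deg/
podmat ortho --intersection deg/intersection.tsv --map fixture/homolog_map.tsv \
             --reference fixture/reference_lists.tsv --out final.tsv
podmat extract-promoters --genome fixture/genome.fa --models fixture/genes.gff3 \
             --out promoters.fa
podmat scan  --pwm fixture/motifs.meme --promoters promoters.fa --p 1e-5 \
             --out sites.tsv
podmat enrich --genes up_genes.txt --annotation fixture/annotation.tsv \
             --universe universe.txt --out ora.tsv
podmat tfbs-enrich --genes final_genes.txt --sites sites.tsv \
             --universe universe.txt --out tfbs
podmat ca    --matrix fixture/counts_PMB0225.tsv --matrix fixture/counts_PHA1037.tsv \
             --design fixture/design.tsv --models fixture/genes.gff3 --out ca/
```

## Package layout

| module | contents |
| --- | --- |
| `podmat.datamodel_io` | `ExpressionMatrix`, `SampleDesign`, `GeneModel`; TSV/GFF3/BED/FASTA readers and writers; FPKM and log1p transforms |
| `podmat.synth` | `SynthParams`, `generate_dataset`, `write_fixture_bundle`, `FixtureManifest` |
| `podmat.qc` | top-gene selection, Chebyshev distances, UPGMA (`ClusterTree`), discordant-replicate flagging |
| `podmat.deg` | stage means, signed fold changes, DEG calls, cross-genotype intersection |
| `podmat.ortho` | homolog maps, direction-concordant selection, final maturation set |
| `podmat.motif` | `PWM`, MEME minimal I/O, promoter extraction, scanning, DP p-values, evidence filters |
| `podmat.enrich` | hypergeometric upper tail, BH adjustment, ORA, TFBS enrichment |
| `podmat.ordination` | correspondence analysis, ddCt |
| `podmat.pipeline` | end-to-end orchestration used by the CLI and tests |
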