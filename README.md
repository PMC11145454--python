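# hashdemux

Demultiplexing for cell-hashing single-cell experiments, with an optional
hybrid mode that reconciles hashing calls with SNP-based genotype clusters.

In a cell-hashing experiment each sample's cells are stained with a
barcoded hashtag antibody (HTO) before pooling, and sequencing yields a
cells × hashtags UMI count matrix. Per hashtag, the normalized counts are
bimodal: a background mode (cells from other samples) and a positive mode
(the hashtag's own sample). `hashdemux` calls a cutoff between the two
modes per hashtag and labels each cell **singlet** (one hashtag positive),
**Doublet** (several) or **Negative** (none). When the pool mixes donors
with distinct genotypes, SNP-based tools (e.g. souporcell) independently
cluster cells by donor but cannot name the donors; the hybrid mode combines
both channels to name the clusters, rescue false doublets/negatives, and
flag disagreements.

It is aimed at people processing pooled single-cell RNA-seq with hashtag
libraries — especially pools with many hashtags, imbalanced sample sizes,
or patchy staining, where simple global thresholds fail.

## Method

Per hashtag with count vector *W* across cells:

1. **Normalize**: CLR, `clr(w_i) = log((w_i + p) / g(w + p))` with geometric
   mean *g* and pseudocount *p* = 1, or log, `log(w_i + 1)` (natural logs).
2. **Reshape** (only for pools of *N* > 4 hashtags, where true positives are
   ~1/*N* of cells and the background peak swamps the fit): values below an
   empirical bound *c* (1.5 CLR / 3 log) are sorted ascending and thinned to
   every `θ = floor(N/2)`-th value; values ≥ *c* are all kept.
3. **Fit** a two-component Gaussian mixture `N(μ₁, σ₁²)`, `N(μ₂, σ₂²)`
   (μ₁ < μ₂) by deterministic EM.
4. **Cutoff**:

       cutoff = μ₁ + ( σ₁^(1/n) / (σ₁^(1/n) + σ₂^(1/n)) ) · (μ₂ − μ₁)

   with rank *n* = 2 by default. A cutoff below the empirical bound is
   replaced by the minimum of the linearly interpolated signal density
   between μ₁ and μ₂.

Hybrid mode joins the hashing labels with a genotype table (souporcell
`clusters.tsv` dialect) on barcodes, pairs each genotype singlet cluster
with the hashing singlet group it shares the most cells with, and computes
the **convergence score** `C = N1/(N1+N2)` over cells called singlet by
both channels (N1 agree under the pairing, N2 disagree). If `C ≥ 0.7` the
final labels are resolved per cell: consistent singlets keep their label;
hashing Doublet/Negative with a genotype singlet is **rescued** with the
cluster's sample label (case 1); a hashing singlet with genotype
doublet/unassigned becomes `Unassigned` (case 2), as does an identity
conflict between two singlet calls (case 3). If `C < 0.7` the hashing
labels are kept unchanged and a quality warning is emitted.

Evaluation treats singlets as the positive class (TP requires the correct
sample identity by default) and reports accuracy, recall, precision and
F1 = 2TP/(2TP+FP+FN), plus the singlet rate.

## Worked example

`examples/02_hybrid_integration.py` runs the hybrid integrator on the
bundled reference table — hashing labels crossed with souporcell clusters
for 12 884 hashtagged PBMC carrier cells from an eight-donor pool:

```
$ python examples/02_hybrid_integration.py
genotype cluster -> sample pairing:
  Singlet0 -> S397
  Singlet1 -> S344
  ...
convergence score C = 0.99 (N1 = 10597 consistent, N2 = 72 inconsistent both-singlet cells)
case-1 rescues: 166 hashing-Negative and 715 hashing-Doublet cells recovered as singlets
final singlets 11478/12884 (89.1%) vs hashing alone 10821/12884 (84.0%)
```

Reading: the pairing names each anonymous genotype cluster after the
hashing group it overlaps most; C = 0.99 means the two independent channels
agree on 99% of the cells both call singlets, so the 881 cells hashing had
discarded as Doublet/Negative but genotyping resolves to a single donor are
rescued, lifting the usable singlet yield by five points.

The other examples demultiplex a simulated eight-hashtag pool from raw
counts (`01`) and show the hybrid rescue of a sample whose hashtag staining
failed (`03`).

A command-line interface mirrors the library:

```bash
hashdemux simulate --n-samples 8 --seed 0 --out-dir sim/
hashdemux demux --counts sim/counts.tsv --out-dir demux/
hashdemux hybrid --hashing-labels demux/hashing_assignments.tsv \
                 --genotype-clusters sim/clusters.tsv --out-dir hybrid/
hashdemux evaluate --pred hybrid_labels.tsv --truth sim/truth.tsv --out metrics.tsv
```

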