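# far-expand

Statistical toolkit for asking whether a gene-family expansion is associated
with transposable elements (TEs), and for linking the expanded family to its
biochemical output. It was built around the analysis of the fatty acyl-CoA
reductase (FAR) family in bumble bees — where the FAR-A ortholog group
expanded massively and its members biosynthesise the fatty alcohols of the
male marking pheromone (MMP) — but every stage operates on standard file
formats and applies to any focal gene set.

The package is for genomicists and chemical ecologists who have: a gene
annotation with a focal gene group, a TE annotation, RNA-seq counts from a
secretory tissue and a reference tissue, and/or GC quantifications of fatty
alcohols and fatty acyls.

## What it computes

**Flank TE density and the permutation null.** For each gene, the TE density
is the fraction of bases in the 10 kb windows upstream and downstream of the
gene body (clipped at scaffold ends, gene body excluded) covered by the union
of TE annotations:

    density(g) = |union(TEs) ∩ flanks(g)| / |flanks(g)|

The mean density of a focal gene set is compared with a null distribution of
means over `n_perm` random gene sets of the same size drawn without
replacement from the full gene pool; the one-sided empirical p-value is
`(n_ge + 1) / (n_perm + 1)`. Densities are also computed per TE class
(I: LINE, LTR, LARD, DIRS; II: DNA, TIR, MITE, TRIM, Maverick, Helitron) and
per family, and focal vs non-focal groups are compared with a two-sided
Mann-Whitney U test (exact when n1·n2 ≤ 400 without ties, otherwise
tie-corrected normal).

**RPKM and candidate selection.** Raw counts become
`RPKM = count · 10⁹ / (length_bp · total_reads)`, displayed as
`log2(RPKM + 1)`. Candidate pheromone-biosynthetic transcripts are those in
the top-100 most abundant labial-gland (LG) transcripts, at least 4-fold more
abundant in LG than fat body (FB), with all catalytically critical protein
domains present. qPCR Cp values are normalised to two reference genes:
`rel_expr = 2^−(Cp_target − mean(Cp_ref1, Cp_ref2))`.

**Fatty-alcohol ratio.** For a fatty chain structure X,

    ratio(X) = 100 · n(alcohol X) / (n(alcohol X) + n(acyl X))  [%]

with amounts in moles and all transesterifiable acyls of the same chain
pooled in the denominator — the apparent degree of acyl-to-alcohol
conversion, i.e. the in-vivo readout of FAR specificity. Chain descriptors
use the compact field notation (`Z9,Z12-18:OH`, `16:COOH`, `22:1`).

**Synthetic data.** `far_expand.synthetic_data` generates annotation bundles,
LG/FB count matrices and lipid tables with known ground truth, at the study's
default contrast (focal flank coverage 0.5 vs background 0.1, 20 focal genes
in a pool of 500), so calibration, power and recovery are testable end to end.

## Worked example

```
far-expand demo --seed 42 --n-perm 1000 --out demo_out
```

prints (abridged):

```
mean flank TE density FAR-A: 0.4808 (n=20)
mean flank TE density non-FAR-A: 0.0966 (n=13)
permutation FAR-A / all: observed 0.4808 vs null 0.1094, p = 0.000999 (ENRICHED)
permutation non-FAR-A / all: observed 0.0966 vs null 0.1110, p = 0.6663 (not significant)
Mann-Whitney FAR-A vs non-FAR-A: U = 260.0 (n1=20, n2=13), p = 3.489e-09 [exact]

planted LG-biased transcripts: 10; selected candidates: 10 (top_k=100, min_fold=4.0)
planted transcripts recovered: 10/10

           16:: mean ratio  63.55 % (sd  2.40, true  60.00)
       Z15-20:: mean ratio  95.56 % (sd  0.14, true  95.24)
```

Reading: the focal group's flanks are ~48% TE-covered against a ~10%
genome-wide background, no random gene set of the same size reaches that mean
(p = 1/(1000+1)), while the non-focal group is indistinguishable from
background; the expression filter recovers exactly the planted LG-biased
transcripts; and the measured alcohol ratios track the generator's true
conversion rates within replicate noise.

On real data, the same stages run from files:

```
far-expand te-enrich --genes genes.bed --groups groups.tsv --tes tes.bed \
    --scaffolds genome.fai --scaffold-format fai --window 10000 \
    --n-perm 10000 --seed 42 --category all --category I --category II \
    --out results/
far-expand rpkm --counts counts.tsv --totals totals.tsv --out rpkm.tsv
far-expand candidates --counts counts.tsv --totals totals.tsv --flags flags.tsv --out cand.tsv
far-expand lipid-ratio --input lipids.csv --out ratios.tsv
```

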