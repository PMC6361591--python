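# Methods

## Flank TE density

A gene's TE density is the covered fraction of its two flanking windows
`[max(0, start − w), start)` and `[end, min(L, end + w))` with `w = 10,000 bp`
by default. Three choices matter:

* **The gene body is excluded** and the denominator is the *clipped* flank
  length, not `2w`. Genes near scaffold ends — common when a repeat-rich
  region breaks the assembly into short scaffolds, which is exactly the
  situation around an expanding gene family — would otherwise have their
  densities deflated. A gene spanning a whole scaffold has no flank bases and
  is excluded from the analysis (the API raises a dedicated error rather than
  returning 0/0).
* **Strand is read but ignored**: upstream and downstream windows are
  symmetric for a density, so the two flanks are treated identically.
* **Overlapping TE records are unioned** within a category, so a base counts
  at most once per category. Per-family densities are computed independently
  per family: a base covered by records of two families counts once in each
  family's density and once in `all`. Raw records are never deduplicated at
  parse time, because the per-family view needs them.

Coordinates are normalised at the parsing boundary to 0-based half-open;
BED is taken verbatim, GFF3 and RepeatMasker `.out` are shifted on read.

## Permutation null

The observed mean density of the focal set (size k) is compared with means of
`n_perm` sets of k genes sampled uniformly without replacement from the gene
pool, replicates independent, all driven by one seeded generator. The
one-sided upper-tail p-value uses the add-one estimator
`(n_ge + 1)/(n_perm + 1)`, which never reports 0 and is consistent with
reporting "p < 1/n_perm" at the resolution run. Per-gene densities are
computed once and cached; replicates only resample cached values, so a
10,000-replicate null costs no additional coverage computation.

By default the pool is the full gene set *including* the focal genes (the
conservative choice when the published sampling frame is the full annotation);
`exclude_focal` removes them. Means are taken over sorted values so the
result is bit-for-bit reproducible and invariant to the input order of pool
genes, and so the exchangeability identity (focal = pool ⇒ p = 1) holds
exactly in floating point.

## Mann-Whitney comparison

`U = Σ_{i,j} [x_i > y_j] + ½[x_i = y_j]`, computed from midranks and reported
for the first sample (`U₁ + U₂ = n₁n₂`). The p-value is two-sided: exact
enumeration when `n₁·n₂ ≤ 400` and there are no ties, otherwise the normal
approximation with midrank tie correction and no continuity correction.
The p-value computation is delegated to `scipy.stats.mannwhitneyu` under
exactly these settings; the U statistic itself is computed in-package and is
cross-checked in the test suite against an O(n₁n₂) pair-count oracle.

## Expression

RPKM is `count · 10⁹ / (length_bp · total_reads)` with library-wide mapped
totals (totals need not equal the column sums of the listed transcripts).
The candidate filter has three explicit parameters:

* `top_k = 100` — membership in the most abundant LG transcripts; ranking
  ties are broken by transcript id so the selection is deterministic.
* `min_fold = 4` — the LG/FB abundance ratio, computed as
  `rpkm_LG / (rpkm_FB + 10⁻⁶)`; the epsilon guards division when a transcript
  is absent from FB. "Substantially more abundant" is not a quantity with a
  field-wide convention, so the threshold is an explicit, echoed parameter
  rather than a hidden constant; 4 is the default because a secretory-tissue
  bias below ~4-fold is within the range that library-composition effects
  alone can produce in two-library designs. The published 10-candidate list
  cannot be re-derived from counts alone because the original threshold is
  unknown; the filter makes whatever choice is used auditable.
* domain completeness — a per-transcript boolean (active site, NAD(P)⁺
  binding site, substrate binding site all present), supplied externally.

Cp normalisation uses the arithmetic mean of the two reference-gene Cp values
(equivalent to the geometric mean of the linear quantities) and a fixed
amplification efficiency of 2; per-primer efficiency calibration is out of
scope.

## Lipids

Chain descriptors parse into (carbons, double-bond count, optional
position/configuration list). A bare count (`22:1`) marks the positions as
unresolved; pairing then falls back from exact positional matching to
(carbons, bond count) and sums over isomers, mirroring how co-eluting isomer
peaks are reported. All acyl moieties — free acid, methyl-ester-detected
esters, CoA thioesters, or an already-pooled total — are summed into the
ratio denominator, because base-catalysed transesterification converts all of
them into the measured FAMEs.

A compound below detection is treated as *missing*, not zero, and excluded
from replicate means; zeroing censored values would bias ratios toward the
extremes. Because it is ambiguous whether a published per-tissue ratio is a
mean of per-replicate ratios or a ratio of mean amounts, the profile reports
both. Mass-mode input converts µg to nmol from the formula implied by the
descriptor (alcohol CnH(2n+2−2d)O, FAME C(n+1)H(2n+2−2d)O₂, acid
CnH(2n−2d)O₂).

## Synthetic data

The generators emulate the statistical structure the analyses rely on, not
the underlying biology:

* **Genome**: genes sit in disjoint territories (gene body + both flanks +
  500 bp pad, jittered), so flank coverages are independent across genes.
  Each gene draws a coverage target from a Beta distribution with its group's
  mean (focal 0.5, background 0.1 — the enrichment contrast at its
  published magnitude) and concentration 50, then its flanks are filled to
  that target *exactly* by a stars-and-bars construction: covered bases are
  split into ~target/800 bp fragments and the uncovered bases into random
  gaps, with families drawn from a weight table (52% Class I). The
  concentration value balances two needs: per-group achieved coverage must
  sit within ±0.05 of its target (sd of a 20-gene group mean ≈ 0.016), and
  the per-gene spread must be non-degenerate — a constant coverage would
  collapse the permutation null to a point mass and make calibration
  meaningless. The exact-fill construction replaces an intensity-based
  placement with rejection adjustment: it is simpler, exactly on target, and
  still randomises fragment counts, lengths and positions. What it does *not*
  emulate: nested/fragmented insertions, coverage correlation between
  neighbouring genes (clustered paralogs sharing a TE-rich region), and
  sequence content. Passing calibration/power tests therefore demonstrates
  the statistics under independence, not robustness to spatial correlation.
* **Counts**: per-transcript log-normal baselines (σ = 1), a planted subset
  (10 of 1000) multiplied by `lg_fold = 50` in LG only, negative-binomial
  counts (dispersion 0.05; Poisson at 0), lengths uniform on 900–2100 bp,
  5 M reads per library. Planted transcripts always have complete domains;
  others are flagged complete with probability ½.
* **Lipids**: log-normal amounts around configured alcohol/acyl means with
  cv = 0.2 over 3 replicates, the acyl pool split across free-acid and
  methyl-ester moieties to exercise pooled matching; true ratios are recorded
  in a sidecar table.

All generators are deterministic under the config seed (sub-generators use
seed, seed+1, seed+2).

## Numerical and scale choices

* Empirical p-values live on the grid `{1/(n+1), …, 1}`; calibration checks
  use `n_perm = 199` so the α = 0.05 rejection region is exactly attainable.
* Calibration runs 500 null genomes of 120 genes (rejection rate 0.05 ± 0.02,
  binomial sd ≈ 0.01); power runs 100 genomes at the full 500-gene,
  20-focal contrast with 1000 permutations. These sizes keep the whole
  acceptance computation around half a minute while leaving the Monte-Carlo
  error well inside the stated tolerances.
* The demo report contains no timestamps, so a fixed seed reproduces it
  byte-identically; run manifests record input SHA256 digests, parameters and
  seeds.

## Known limitations

* The permutation null treats genes as exchangeable units; it does not model
  flank overlap between clustered genes (each gene's flank is counted
  independently, including any shared bases) or match gene length/GC.
* The Mann-Whitney exact path refuses ties rather than enumerating the
  tie-permuted null.
* No multiple-testing correction is applied across TE categories; per-category
  p-values are reported raw.
* RepeatMasker parsing covers the standard 15-column `.out` body; exotic
  dialects (e.g. with extra ID columns removed) are not auto-detected.
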