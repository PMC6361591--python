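"""Synthetic inputs with the statistical structure the analyses assume.

Three generators emulate the three data types of the study design:

* a multi-scaffold genome annotation in which the flanks of a focal gene
  group carry elevated TE coverage (the enrichment contrast of roughly 50%
  focal vs 10% genome-wide background flank coverage),
* paired labial-gland / fat-body RNA-seq count matrices with a planted
  LG-biased transcript subset,
* replicate lipid tables with known true alcohol/acyl ratios per chain.

Everything is driven by one :class:`SimulationConfig` and a single seed, and
is bit-for-bit reproducible.  Per-flank TE coverage is generated exactly: a
gene's coverage target is drawn from a Beta distribution around the group
mean, and TE fragments are laid down by a stars-and-bars construction that
hits the target to the base pair.  The spread of the Beta draw
(``cov_concentration``) is what gives the permutation null a non-degenerate
distribution; a constant per-gene coverage would collapse it to a point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from far_expand.expression import CountMatrix
from far_expand.io_annotations import (
    CLASS_OF_FAMILY,
    GROUP_BACKGROUND,
    GROUP_FOCAL,
    GROUP_NONFOCAL,
    GeneRecord,
    GenomicInterval,
    ScaffoldIndex,
    TERecord,
    write_genes_bed,
    write_groups_tsv,
    write_scaffold_index,
    write_tes_bed,
)
from far_expand.lipids import LipidMeasurement, fatty_alcohol_ratio, parse_chain

DEFAULT_FAMILY_WEIGHTS = {
    "LINE": 0.20,
    "LTR": 0.25,
    "LARD": 0.05,
    "DIRS": 0.02,
    "DNA": 0.18,
    "TIR": 0.10,
    "MITE": 0.08,
    "TRIM": 0.04,
    "Maverick": 0.03,
    "Helitron": 0.05,
}


@dataclass(frozen=True)
class LipidChainSpec:
    """Simulation target for one fatty chain."""

    descriptor: str
    alcohol_mean_nmol: float
    acyl_mean_nmol: float
    cv: float = 0.2


@dataclass
class SimulationConfig:
    """All knobs of the synthetic generators.

    Genome defaults mirror the enrichment study conditions at desk scale:
    a pool of 500 genes, a focal group of 20 with mean flank TE coverage
    0.5 against a background of 0.1, and 10 kb flank windows.
    """

    seed: int = 0
    # genome
    n_scaffolds: int = 10
    scaffold_len_bp: int | None = None  # derived from the gene layout if None
    n_genes: int = 500
    gene_len_bp: int = 2_000
    n_focal: int = 20
    n_nonfocal: int = 13
    flank_w: int = 10_000
    te_cov_focal: float = 0.5
    te_cov_nonfocal: float = 0.1
    te_cov_background: float = 0.1
    cov_concentration: float = 50.0
    te_len_mean: float = 800.0
    family_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_WEIGHTS)
    )
    # expression
    n_transcripts: int = 1_000
    n_planted_lg_biased: int = 10
    lg_fold: float = 50.0
    count_dispersion: float = 0.05
    baseline_log_sigma: float = 1.0
    library_totals: tuple[int, int] = (5_000_000, 5_000_000)  # (LG, FB)
    # lipids
    n_lipid_replicates: int = 3
    lipid_chains: tuple[LipidChainSpec, ...] = (
        LipidChainSpec("16:OH", 60.0, 40.0, 0.2),
        LipidChainSpec("Z9-16:OH", 5.0, 45.0, 0.2),
        LipidChainSpec("18:OH", 30.0, 20.0, 0.2),
        LipidChainSpec("Z9,Z12-18:OH", 12.0, 36.0, 0.2),
        LipidChainSpec("Z15-20:OH", 40.0, 2.0, 0.2),
        LipidChainSpec("22:1:OH", 25.0, 5.0, 0.2),
    )

    def __post_init__(self) -> None:
        total = sum(self.family_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"family weights must sum to 1, got {total}")
        unknown = set(self.family_weights) - set(CLASS_OF_FAMILY)
        if unknown:
            raise ValueError(f"unknown TE families in weights: {sorted(unknown)}")
        for name in ("te_cov_focal", "te_cov_nonfocal", "te_cov_background"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_focal + self.n_nonfocal > self.n_genes:
            raise ValueError("n_focal + n_nonfocal exceeds n_genes")
        if min(self.n_scaffolds, self.n_genes, self.gene_len_bp, self.flank_w) < 1:
            raise ValueError("all sizes must be >= 1")


@dataclass
class SyntheticGenome:
    """A generated annotation bundle."""

    index: ScaffoldIndex
    genes: list[GeneRecord]
    tes: list[TERecord]

    @property
    def focal(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.group == GROUP_FOCAL]

    @property
    def nonfocal(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.group == GROUP_NONFOCAL]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genes.bed, tes.bed, scaffolds.tsv and groups.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.bed",
            "tes": outdir / "tes.bed",
            "scaffolds": outdir / "scaffolds.tsv",
            "groups": outdir / "groups.tsv",
        }
        write_genes_bed(self.genes, paths["genes"])
        write_tes_bed(self.tes, paths["tes"])
        write_scaffold_index(self.index, paths["scaffolds"])
        write_groups_tsv(self.genes, paths["groups"])
        return paths


def _beta_target(rng: np.random.Generator, mean: float, kappa: float) -> float:
    if mean <= 0.0:
        return 0.0
    if mean >= 1.0:
        return 1.0
    return float(rng.beta(mean * kappa, (1.0 - mean) * kappa))


def _fill_window_to_coverage(
    rng: np.random.Generator,
    scaffold: str,
    win_start: int,
    win_end: int,
    coverage: float,
    te_len_mean: float,
    families: Sequence[str],
    family_p: np.ndarray,
) -> list[TERecord]:
    """Place non-overlapping TE fragments covering exactly round(c * len) bp.

    The covered bases are split into k fragments (k roughly target/te_len_mean)
    and the uncovered bases into k+1 gaps by uniform random composition, so
    fragment positions and lengths vary while the union coverage is exact.
    """
    window_len = win_end - win_start
    target = int(round(coverage * window_len))
    if target <= 0:
        return []
    if target >= window_len:
        fam = str(rng.choice(families, p=family_p))
        return [
            TERecord(GenomicInterval(scaffold, win_start, win_end), CLASS_OF_FAMILY[fam], fam)
        ]
    k = 1 + int(rng.poisson(max(target / te_len_mean - 1.0, 0.0)))
    k = min(k, target)  # every fragment needs >= 1 bp
    if k > 1:
        cuts = np.sort(rng.choice(target - 1, size=k - 1, replace=False)) + 1
        seg_lens = np.diff(np.concatenate([[0], cuts, [target]]))
    else:
        seg_lens = np.array([target])
    gap_total = window_len - target
    gap_cuts = np.sort(rng.integers(0, gap_total + 1, size=k))
    gaps = np.diff(np.concatenate([[0], gap_cuts, [gap_total]]))
    records = []
    pos = win_start
    for seg_len, gap in zip(seg_lens, gaps[:-1]):
        pos += int(gap)
        fam = str(rng.choice(families, p=family_p))
        records.append(
            TERecord(
                GenomicInterval(scaffold, pos, pos + int(seg_len)),
                CLASS_OF_FAMILY[fam],
                fam,
            )
        )
        pos += int(seg_len)
    return records


def simulate_genome_with_tes(config: SimulationConfig) -> SyntheticGenome:
    """Generate a scaffold index, gene set and TE annotation.

    Genes are laid out in disjoint per-gene territories (gene body plus both
    flank windows plus padding), so one gene's flank coverage is independent
    of its neighbours'.  Each gene draws a flank-coverage target from a Beta
    distribution with the mean of its group, and its two flank windows are
    filled to that target exactly.
    """
    rng = np.random.default_rng(config.seed)
    w = config.flank_w
    pad = 500
    block = config.gene_len_bp + 2 * w + 2 * pad
    genes_per_scaffold = math.ceil(config.n_genes / config.n_scaffolds)
    needed_len = genes_per_scaffold * block
    scaffold_len = config.scaffold_len_bp or needed_len
    if scaffold_len < needed_len:
        raise ValueError(
            f"scaffold_len_bp={scaffold_len} cannot fit {genes_per_scaffold} gene "
            f"territories of {block} bp; need >= {needed_len}"
        )

    index = ScaffoldIndex(
        {f"scaf{i + 1}": scaffold_len for i in range(config.n_scaffolds)}
    )

    # group labels: focal / nonfocal gene indices drawn without replacement
    labels = np.array([GROUP_BACKGROUND] * config.n_genes, dtype=object)
    special = rng.choice(
        config.n_genes, size=config.n_focal + config.n_nonfocal, replace=False
    )
    labels[special[: config.n_focal]] = GROUP_FOCAL
    labels[special[config.n_focal:]] = GROUP_NONFOCAL
    cov_mean = {
        GROUP_FOCAL: config.te_cov_focal,
        GROUP_NONFOCAL: config.te_cov_nonfocal,
        GROUP_BACKGROUND: config.te_cov_background,
    }

    families = list(config.family_weights)
    family_p = np.array([config.family_weights[f] for f in families])
    family_p = family_p / family_p.sum()

    genes: list[GeneRecord] = []
    tes: list[TERecord] = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        scaffold = f"scaf{i // genes_per_scaffold + 1}"
        block_start = (i % genes_per_scaffold) * block
        jitter = int(rng.integers(0, 2 * pad + 1))
        gene_start = block_start + w + jitter
        gene_end = gene_start + config.gene_len_bp
        group = str(labels[i])
        gene = GeneRecord(
            f"g{i + 1:0{width}d}",
            GenomicInterval(scaffold, gene_start, gene_end, "+"),
            group,
        )
        genes.append(gene)
        target = _beta_target(rng, cov_mean[group], config.cov_concentration)
        for win_start, win_end in ((gene_start - w, gene_start), (gene_end, gene_end + w)):
            tes.extend(
                _fill_window_to_coverage(
                    rng,
                    scaffold,
                    win_start,
                    win_end,
                    target,
                    config.te_len_mean,
                    families,
                    family_p,
                )
            )
    return SyntheticGenome(index, genes, tes)


@dataclass
class SyntheticCounts:
    """LG/FB count matrix with the planted ground truth."""

    matrix: CountMatrix
    planted: list[str]
    domain_flags: dict[str, bool]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "totals": outdir / "library_totals.tsv",
            "truth": outdir / "counts_truth.tsv",
        }
        table = self.matrix.counts.astype(int).copy()
        table.insert(0, "length_bp", self.matrix.lengths.astype(int))
        table.rename_axis("transcript_id").reset_index().to_csv(
            paths["counts"], sep="\t", index=False
        )
        self.matrix.totals.astype(int).to_csv(paths["totals"], sep="\t", header=False)
        truth = pd.DataFrame(
            {
                "transcript_id": list(self.domain_flags),
                "planted": [t in set(self.planted) for t in self.domain_flags],
                "domain_complete": [self.domain_flags[t] for t in self.domain_flags],
            }
        )
        truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_count_matrix(config: SimulationConfig) -> SyntheticCounts:
    """Generate paired LG/FB count matrices with a planted LG-biased subset.

    Baseline expression is log-normal across transcripts; the planted subset
    is multiplied by ``lg_fold`` in LG only; counts are negative-binomial
    around the library-scaled expectations (Poisson when the dispersion is 0).
    Transcript lengths are uniform on 900-2100 bp.  Planted transcripts carry
    complete catalytic domains; the rest have a 50% chance of truncation.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_transcripts
    width = len(str(n))
    ids = [f"t{i + 1:0{width}d}" for i in range(n)]
    baseline = rng.lognormal(mean=math.log(100.0), sigma=config.baseline_log_sigma, size=n)
    planted_idx = rng.choice(n, size=config.n_planted_lg_biased, replace=False)
    planted = sorted(ids[i] for i in planted_idx)

    lg_weight = baseline.copy()
    lg_weight[planted_idx] *= config.lg_fold
    fb_weight = baseline

    lengths = rng.integers(900, 2101, size=n)
    counts = {}
    for library, weight, total in (
        ("LG", lg_weight, config.library_totals[0]),
        ("FB", fb_weight, config.library_totals[1]),
    ):
        # expectation scales with expression weight and transcript length
        mu = weight * lengths / (weight * lengths).sum() * total
        if config.count_dispersion <= 1e-9:
            counts[library] = rng.poisson(mu)
        else:
            r = 1.0 / config.count_dispersion
            counts[library] = rng.negative_binomial(r, r / (r + mu))
    matrix = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(ids, name="transcript_id")),
        pd.Series(lengths, index=ids, name="length_bp"),
        pd.Series(
            {"LG": config.library_totals[0], "FB": config.library_totals[1]},
            name="total_reads",
        ),
    )
    flags = {
        t: True if t in set(planted) else bool(rng.random() < 0.5) for t in ids
    }
    return SyntheticCounts(matrix, planted, flags)


@dataclass
class SyntheticLipids:
    """Replicate lipid measurements with the per-chain true ratios."""

    measurements: list[LipidMeasurement]
    sample_ids: list[str]
    truth: pd.DataFrame  # chain, true_ratio_percent

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"lipids": outdir / "lipids.csv", "truth": outdir / "lipids_truth.tsv"}
        rows = [
            {
                "sample_id": m.sample_id,
                "tissue": m.tissue,
                "descriptor": m.chain.format(m.moiety if m.moiety != "acyl_total" else ""),
                "amount_nmol": m.amount_nmol,
            }
            for m in self.measurements
        ]
        pd.DataFrame(rows).to_csv(paths["lipids"], index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_lipid_table(config: SimulationConfig) -> SyntheticLipids:
    """Generate replicate alcohol/acyl amounts with known true ratios.

    Amounts are log-normal with the configured means and coefficient of
    variation (``cv=0`` reproduces the means exactly); the acyl pool of each
    chain is split across the free-acid and methyl-ester moieties to exercise
    the pooled-denominator matching.
    """
    rng = np.random.default_rng(config.seed + 2)
    sample_ids = [f"LG_r{i + 1}" for i in range(config.n_lipid_replicates)]
    measurements: list[LipidMeasurement] = []
    truth_rows = []
    for spec in config.lipid_chains:
        chain, moiety = parse_chain(spec.descriptor, default_moiety="OH")
        truth_rows.append(
            {
                "chain": chain.format(),
                "true_ratio_percent": fatty_alcohol_ratio(
                    spec.alcohol_mean_nmol, spec.acyl_mean_nmol
                ),
            }
        )
        for sid in sample_ids:
            for mo, mean in ((moiety, spec.alcohol_mean_nmol),):
                measurements.append(
                    LipidMeasurement(chain, mo, _lognormal_amount(rng, mean, spec.cv), sid, "LG")
                )
            acyl = _lognormal_amount(rng, spec.acyl_mean_nmol, spec.cv)
            split = float(rng.uniform(0.3, 0.7))
            for mo, amount in (("COOH", acyl * split), ("Me", acyl * (1.0 - split))):
                measurements.append(LipidMeasurement(chain, mo, amount, sid, "LG"))
    return SyntheticLipids(measurements, sample_ids, pd.DataFrame(truth_rows))


def _lognormal_amount(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean <= 0.0:
        return 0.0
    if cv <= 0.0:
        return float(mean)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(math.log(mean) - sigma * sigma / 2.0, sigma))


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The same conditions with the focal enrichment switched off."""
    return replace(
        config,
        te_cov_focal=config.te_cov_background,
        te_cov_nonfocal=config.te_cov_background,
    )
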