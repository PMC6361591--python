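"""RPKM normalisation, the labial-gland candidate filter and qPCR normalisation.

RPKM (reads per kilobase of transcript per million mapped reads) is computed
from raw mapped-read counts, the transcript coding-region length and the
library-wide total of mapped reads.  For display and downstream comparison a
constant 1 is added before log2 transformation.

The candidate filter formalises the selection of putative pheromone-
biosynthetic transcripts: a transcript qualifies if it is (1) among the
``top_k`` most abundant transcripts in the pheromone-producing labial gland
(LG), (2) at least ``min_fold``-fold more abundant in LG than in the fat-body
(FB) reference tissue, and (3) carries all catalytically critical protein
domains.  "Substantially more abundant" is not a fixed convention, so the
fold threshold is an explicit, reported parameter (default 4).

qPCR crossing-point (Cp) values are normalised to the mean of two reference
genes (phospholipase A2 and elongation factor 1-alpha) with amplification
efficiency fixed at 2: ``rel_expr = 2**-(cp_target - mean(cp_refs))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FOLD_EPSILON = 1e-6  # guards the LG/FB division when FB expression is zero


@dataclass
class CountMatrix:
    """Raw mapped-read counts with transcript lengths and library totals.

    ``counts`` is indexed by transcript id with one column per library;
    ``lengths`` (bp) is indexed by transcript id; ``totals`` (library-wide
    mapped reads) is indexed by library id.  Totals are library-wide, so they
    need not equal the column sums of the listed transcripts.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.lengths = self.lengths.reindex(self.counts.index)
        self.totals = self.totals.reindex(self.counts.columns)
        if self.lengths.isna().any():
            missing = list(self.lengths.index[self.lengths.isna()])[:5]
            raise ValueError(f"missing transcript lengths, e.g. {missing}")
        if self.totals.isna().any():
            missing = list(self.totals.index[self.totals.isna()])[:5]
            raise ValueError(f"missing library totals, e.g. {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.lengths <= 0).any():
            raise ValueError("transcript lengths must be > 0")
        if (self.totals <= 0).any():
            raise ValueError("library totals must be > 0 (zero total reads)")


def compute_rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Tidy per-(transcript, library) expression table.

    ``rpkm = count * 1e9 / (length_bp * total_reads)``; the returned frame has
    columns ``transcript_id, library_id, count, rpkm, log2_rpkm_plus1``.
    """
    rpkm = counts.counts.mul(1e9).div(counts.lengths, axis=0).div(counts.totals, axis=1)
    tidy = (
        rpkm.rename_axis(index="transcript_id", columns="library_id")
        .stack()
        .rename("rpkm")
        .reset_index()
    )
    tidy["count"] = counts.counts.stack().to_numpy()
    tidy["log2_rpkm_plus1"] = np.log2(tidy["rpkm"] + 1.0)
    return tidy[["transcript_id", "library_id", "count", "rpkm", "log2_rpkm_plus1"]]


def rpkm_series(counts: CountMatrix, library_id: str) -> pd.Series:
    """RPKM values of one library, indexed by transcript id."""
    if library_id not in counts.counts.columns:
        raise KeyError(f"library {library_id!r} not in count matrix")
    col = counts.counts[library_id]
    return col * 1e9 / (counts.lengths * counts.totals[library_id])


@dataclass
class CandidateSelection:
    """Result of the LG-candidate filter with its parameters echoed."""

    candidates: list[str]
    table: pd.DataFrame
    top_k: int
    min_fold: float


def select_mmp_candidates(
    lg: pd.Series,
    fb: pd.Series,
    domain_flags: dict[str, bool] | pd.Series,
    top_k: int = 100,
    min_fold: float = 4.0,
) -> CandidateSelection:
    """Select candidate pheromone-biosynthetic transcripts.

    *lg* and *fb* are RPKM series indexed by a shared set of transcript ids.
    Transcripts are ranked by LG abundance (ties broken by lexicographic id
    for determinism); the ``top_k`` of them survive if
    ``rpkm_LG / (rpkm_FB + eps) >= min_fold`` and their domain flag is true.
    The returned list preserves LG-rank order.
    """
    lg = pd.Series(lg, dtype=float)
    fb = pd.Series(fb, dtype=float).reindex(lg.index)
    if fb.isna().any():
        raise ValueError("lg and fb must share transcript ids")
    flags = pd.Series(domain_flags)

    order = sorted(lg.index, key=lambda t: (-lg[t], t))
    ranked = pd.DataFrame(
        {
            "transcript_id": order,
            "rank_lg": np.arange(1, len(order) + 1),
            "rpkm_lg": lg.loc[order].to_numpy(),
            "rpkm_fb": fb.loc[order].to_numpy(),
        }
    )
    ranked["fold_lg_fb"] = ranked["rpkm_lg"] / (ranked["rpkm_fb"] + FOLD_EPSILON)
    ranked["in_top_k"] = ranked["rank_lg"] <= top_k
    ranked["passes_fold"] = ranked["fold_lg_fb"] >= min_fold

    surviving = ranked[ranked["in_top_k"] & ranked["passes_fold"]]
    missing = [t for t in surviving["transcript_id"] if t not in flags.index]
    if missing:
        raise ValueError(f"missing domain flags for candidate transcripts: {missing[:5]}")
    ranked["domain_complete"] = [
        bool(flags.get(t, False)) for t in ranked["transcript_id"]
    ]
    ranked["candidate"] = ranked["in_top_k"] & ranked["passes_fold"] & ranked["domain_complete"]
    candidates = list(ranked.loc[ranked["candidate"], "transcript_id"])
    return CandidateSelection(candidates, ranked, top_k=top_k, min_fold=min_fold)


@dataclass(frozen=True)
class QpcrRecord:
    """One normalised qPCR measurement."""

    target_id: str
    tissue: str
    replicate: int
    cp_target: float
    cp_ref1: float
    cp_ref2: float
    delta_cp: float
    rel_expr: float


def qpcr_relative_expression(
    cp_target: float,
    cp_ref1: float,
    cp_ref2: float,
    target_id: str = "",
    tissue: str = "",
    replicate: int = 0,
) -> QpcrRecord:
    """Delta-Cp normalisation against the mean of two reference genes.

    ``delta_cp = cp_target - (cp_ref1 + cp_ref2) / 2`` and
    ``rel_expr = 2 ** -delta_cp`` (amplification efficiency fixed at 2).
    """
    for name, value in (("cp_target", cp_target), ("cp_ref1", cp_ref1), ("cp_ref2", cp_ref2)):
        if not np.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value}")
    delta = cp_target - (cp_ref1 + cp_ref2) / 2.0
    return QpcrRecord(
        target_id=target_id,
        tissue=tissue,
        replicate=replicate,
        cp_target=float(cp_target),
        cp_ref1=float(cp_ref1),
        cp_ref2=float(cp_ref2),
        delta_cp=float(delta),
        rel_expr=float(2.0 ** (-delta)),
    )


def normalize_cp_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the delta-Cp normalisation to a Cp table.

    Expects columns ``target_id, tissue, replicate, cp_target, cp_ref1,
    cp_ref2``; returns the table with ``delta_cp`` and ``rel_expr`` appended.
    """
    required = {"target_id", "tissue", "replicate", "cp_target", "cp_ref1", "cp_ref2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Cp table missing columns: {sorted(missing)}")
    out = table.copy()
    out["delta_cp"] = out["cp_target"] - (out["cp_ref1"] + out["cp_ref2"]) / 2.0
    out["rel_expr"] = 2.0 ** (-out["delta_cp"])
    return out


def read_counts(counts_path: str | Path, totals_path: str | Path) -> CountMatrix:
    """Read a counts TSV plus a companion library-totals TSV.

    The counts table has columns ``transcript_id, length_bp`` followed by one
    column per library; totals is a two-column ``library_id<TAB>total_reads``.
    """
    table = pd.read_csv(counts_path, sep="\t")
    if "transcript_id" not in table.columns or "length_bp" not in table.columns:
        raise ValueError("counts TSV needs 'transcript_id' and 'length_bp' columns")
    table = table.set_index("transcript_id")
    lengths = table.pop("length_bp")
    totals_table = pd.read_csv(
        totals_path, sep="\t", header=None, names=["library_id", "total_reads"]
    )
    totals = totals_table.set_index("library_id")["total_reads"]
    return CountMatrix(table, lengths, totals)
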