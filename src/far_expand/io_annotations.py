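"""Readers and writers for the genomic annotation inputs.

All coordinates are normalised at the parsing boundary to a single internal
convention: 0-based, half-open ``[start, end)`` intervals.  BED input is taken
verbatim; GFF3 and RepeatMasker ``.out`` coordinates (1-based, inclusive) are
shifted on read.  Every reader transparently accepts gzip-compressed files.

TE classification follows the two-class system used for bee genome repeat
annotations: Class I (retroid) families LINE, LTR, LARD, DIRS and Class II
(DNA) families DNA, TIR, MITE, TRIM, Maverick, Helitron.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: Fixed family -> class table (Class I: retroid elements, Class II: DNA elements).
CLASS_OF_FAMILY: dict[str, str] = {
    "LINE": "I",
    "LTR": "I",
    "LARD": "I",
    "DIRS": "I",
    "DNA": "II",
    "TIR": "II",
    "MITE": "II",
    "TRIM": "II",
    "Maverick": "II",
    "Helitron": "II",
}

TE_CLASSES = ("I", "II", "unknown")
TE_FAMILIES = tuple(CLASS_OF_FAMILY) + ("other",)

GROUP_FOCAL = "FAR-A"
GROUP_NONFOCAL = "non-FAR-A"
GROUP_BACKGROUND = "background"


class AnnotationParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named scaffold."""

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its genomic interval and analysis group label."""

    gene_id: str
    interval: GenomicInterval
    group: str = GROUP_BACKGROUND


@dataclass(frozen=True)
class TERecord:
    """A transposable-element annotation with class/family labels.

    Records with the same genomic span but different families are kept
    distinct; de-duplication happens only when coverage is computed, so that
    per-family densities see the raw annotation.
    """

    interval: GenomicInterval
    te_class: str = "unknown"
    te_family: str = "other"

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")
        if self.te_family not in TE_FAMILIES:
            raise ValueError(f"unknown TE family {self.te_family!r}")
        expected = CLASS_OF_FAMILY.get(self.te_family)
        if expected is not None and self.te_class != expected:
            raise ValueError(
                f"family {self.te_family} implies class {expected}, got {self.te_class}"
            )


@dataclass
class ScaffoldIndex:
    """Mapping scaffold id -> length in bp."""

    lengths: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, scaffold: str) -> int:
        try:
            return self.lengths[scaffold]
        except KeyError:
            raise KeyError(f"scaffold {scaffold!r} absent from index") from None

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)

    def validate(self, interval: GenomicInterval) -> None:
        """Check that *interval* fits on its scaffold."""
        length = self[interval.scaffold]
        if interval.end > length:
            raise ValueError(
                f"interval end {interval.end} exceeds length {length} "
                f"of scaffold {interval.scaffold}"
            )


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_data_lines(handle: Iterable[str]) -> Iterator[tuple[int, str]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        yield lineno, line


def classify_family(label: str) -> tuple[str, str]:
    """Resolve a class/family label string to ``(te_class, te_family)``.

    Accepts ``"I/LINE"``-style prefixed labels, bare family names (class
    inferred from the fixed table) and bare class labels ``"I"``/``"II"``.
    Unrecognised labels fall back to ``("unknown", "other")``.
    """
    label = label.strip()
    if "/" in label:
        cls, fam = label.split("/", 1)
        cls, fam = cls.strip(), fam.strip()
        if fam in CLASS_OF_FAMILY and cls in ("I", "II"):
            if CLASS_OF_FAMILY[fam] != cls:
                return CLASS_OF_FAMILY[fam], fam
            return cls, fam
        if fam in CLASS_OF_FAMILY:
            return CLASS_OF_FAMILY[fam], fam
        if cls in ("I", "II"):
            return cls, "other"
        return "unknown", "other"
    if label in CLASS_OF_FAMILY:
        return CLASS_OF_FAMILY[label], label
    if label in ("I", "II"):
        return label, "other"
    return "unknown", "other"


def read_genes(
    path: str | Path,
    format: str = "bed",
    group_map: Mapping[str, str] | None = None,
) -> list[GeneRecord]:
    """Read gene annotations from BED6 or GFF3 into :class:`GeneRecord` s.

    Genes without an entry in *group_map* are labelled ``background``.
    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; only features of type ``gene`` are used.
    """
    group_map = dict(group_map or {})
    if format == "bed":
        records = list(_read_genes_bed(path, group_map))
    elif format == "gff3":
        records = list(_read_genes_gff3(path, group_map))
    else:
        raise ValueError(f"unsupported gene format {format!r}")
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise AnnotationParseError(f"duplicate gene_id {rec.gene_id!r} in {path}")
        seen.add(rec.gene_id)
    if not records:
        logger.warning("no gene records read from %s", path)
    return records


def _read_genes_bed(path: str | Path, group_map: Mapping[str, str]) -> Iterator[GeneRecord]:
    with _open_text(path) as handle:
        for lineno, line in _iter_data_lines(handle):
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED gene line needs >= 4 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from None
            strand = fields[5] if len(fields) > 5 else "."
            gene_id = fields[3]
            try:
                interval = GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from None
            yield GeneRecord(gene_id, interval, group_map.get(gene_id, GROUP_BACKGROUND))


def _read_genes_gff3(path: str | Path, group_map: Mapping[str, str]) -> Iterator[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        yield GeneRecord(gene_id, interval, group_map.get(gene_id, GROUP_BACKGROUND))


def write_genes_bed(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write genes as BED6 (score column written as ``.``)."""
    with open(path, "wt") as handle:
        for gene in genes:
            iv = gene.interval
            handle.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{gene.gene_id}\t.\t{iv.strand}\n"
            )


def write_groups_tsv(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write a two-column ``gene_id<TAB>group`` table."""
    with open(path, "wt") as handle:
        for gene in genes:
            handle.write(f"{gene.gene_id}\t{gene.group}\n")


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column ``gene_id<TAB>group`` table into a mapping."""
    mapping: dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, line in _iter_data_lines(handle):
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationParseError(
                    f"{path}:{lineno}: group line needs 2 columns"
                )
            mapping[fields[0]] = fields[1]
    return mapping


def read_tes(path: str | Path, format: str = "bed") -> list[TERecord]:
    """Read TE annotations from BED or RepeatMasker ``.out``.

    The BED name column encodes ``class/family`` (e.g. ``I/LTR``); a bare
    family name is resolved through the fixed class table.  Unparseable
    labels are kept with family ``other`` and counted in a warning.
    """
    if format == "bed":
        records = list(_read_tes_bed(path))
    elif format == "repeatmasker_out":
        records = list(_read_tes_repeatmasker(path))
    else:
        raise ValueError(f"unsupported TE format {format!r}")
    n_other = sum(1 for rec in records if rec.te_family == "other")
    if n_other:
        logger.warning(
            "%d of %d TE records in %s had unrecognised family labels (kept as 'other')",
            n_other,
            len(records),
            path,
        )
    return records


def _read_tes_bed(path: str | Path) -> Iterator[TERecord]:
    with _open_text(path) as handle:
        for lineno, line in _iter_data_lines(handle):
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED TE line needs >= 3 columns"
                )
            try:
                interval = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from None
            label = fields[3] if len(fields) > 3 else ""
            te_class, te_family = classify_family(label)
            yield TERecord(interval, te_class, te_family)


def _read_tes_repeatmasker(path: str | Path) -> Iterator[TERecord]:
    # RepeatMasker .out: 3 header lines, then whitespace-separated body rows:
    # score div del ins query qbegin qend qleft strand repeat class/family ...
    with _open_text(path) as handle:
        lines = handle.readlines()
    body = lines[3:] if len(lines) >= 3 else []
    for lineno, raw in enumerate(body, start=4):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 11:
            raise AnnotationParseError(
                f"{path}:{lineno}: RepeatMasker row needs >= 11 columns, got {len(fields)}"
            )
        scaffold = fields[4]
        try:
            begin, end = int(fields[5]), int(fields[6])
        except ValueError as exc:
            raise AnnotationParseError(f"{path}:{lineno}: {exc}") from None
        te_class, te_family = classify_family(fields[10])
        try:
            interval = GenomicInterval(scaffold, begin - 1, end)
        except ValueError as exc:
            raise AnnotationParseError(f"{path}:{lineno}: {exc}") from None
        yield TERecord(interval, te_class, te_family)


def write_tes_bed(tes: Iterable[TERecord], path: str | Path) -> None:
    """Write TE records as BED4 with ``class/family`` in the name column."""
    with open(path, "wt") as handle:
        for te in tes:
            iv = te.interval
            handle.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{te.te_class}/{te.te_family}\n")


def read_scaffold_index(path: str | Path, format: str = "tsv") -> ScaffoldIndex:
    """Read scaffold lengths from a two-column TSV or a FASTA ``.fai`` index."""
    if format not in ("tsv", "fai"):
        raise ValueError(f"unsupported scaffold index format {format!r}")
    lengths: dict[str, int] = {}
    with _open_text(path) as handle:
        for lineno, line in _iter_data_lines(handle):
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationParseError(
                    f"{path}:{lineno}: scaffold index line needs >= 2 columns"
                )
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer scaffold length {fields[1]!r}"
                ) from None
            if length <= 0:
                raise AnnotationParseError(f"{path}:{lineno}: scaffold length must be > 0")
            if name in lengths:
                raise AnnotationParseError(f"{path}:{lineno}: duplicate scaffold {name!r}")
            lengths[name] = length
    return ScaffoldIndex(lengths)


def write_scaffold_index(index: ScaffoldIndex, path: str | Path) -> None:
    with open(path, "wt") as handle:
        for name, length in index.lengths.items():
            handle.write(f"{name}\t{length}\n")
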