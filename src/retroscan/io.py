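"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are kept 0-based half-open internally (BED convention).
RepeatMasker ``.out`` rows, which are 1-based inclusive, are converted on
read. Chromosome names are matched by exact string equality; no ``chr``
prefix normalization is attempted.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DataError, FormatError, ParseError

#: Retroelement classes kept by default: the retrotransposon classes
#: (LINE, SINE, LTR and SVA/Retroposon). DNA transposons are excluded.
DEFAULT_RE_CLASSES = frozenset({"LINE", "SINE", "LTR", "SVA", "Retroposon"})

GENE_CLASSES = ("protein_coding", "miRNA", "lncRNA", "other")

_VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored at its reference TSS."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    gene_class: str = "protein_coding"

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError(f"negative tss: {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


class GeneSetCollection(Mapping):
    """Named gene sets (pathways or annotation terms) as read from GMT.

    Member order is preserved; duplicates within a set are dropped at
    construction. Empty sets are rejected.
    """

    def __init__(self, sets: Mapping[str, Iterable[str]], descriptions: Mapping[str, str] | None = None):
        self._sets: dict[str, tuple[str, ...]] = {}
        self._descriptions: dict[str, str] = {}
        for name, members in sets.items():
            deduped = tuple(dict.fromkeys(members))
            if not deduped:
                raise DataError(f"gene set {name!r} is empty")
            self._sets[name] = deduped
            self._descriptions[name] = (descriptions or {}).get(name, "")

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def description(self, name: str) -> str:
        return self._descriptions[name]

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with *universe*, dropping sets that empty out."""
        uni = set(universe)
        kept = {
            name: [g for g in members if g in uni]
            for name, members in self._sets.items()
        }
        kept = {name: m for name, m in kept.items() if m}
        return GeneSetCollection(kept, self._descriptions)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; columns beyond 6 are ignored."""
    intervals: list[GenomicInterval] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand, name))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval] | pd.DataFrame, path: str | Path) -> None:
    """Write intervals as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        if isinstance(intervals, pd.DataFrame):
            df = intervals
            names = df["name"] if "name" in df else [""] * len(df)
            strands = df["strand"] if "strand" in df else ["."] * len(df)
            for chrom, start, end, name, strand in zip(
                df["chrom"], df["start"], df["end"], names, strands
            ):
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")
        else:
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# RepeatMasker


def _re_class_matches(repeat_class: str, keep: frozenset[str] | set[str]) -> bool:
    if repeat_class in keep:
        return True
    return any(part in keep for part in repeat_class.split("/"))


def _looks_like_out(first_line: str) -> bool:
    tokens = first_line.split()
    return bool(tokens) and tokens[0].lower() in ("sw", "score")


def read_repeatmasker(
    path: str | Path,
    keep_classes: Iterable[str] = DEFAULT_RE_CLASSES,
) -> list[GenomicInterval]:
    """Read a RepeatMasker ``.out`` file or a BED with the repeat class in
    the name column, keeping only retroelement classes in *keep_classes*.

    ``.out`` coordinates (1-based inclusive) are converted to 0-based
    half-open. Returned interval names carry the repeat class/family string
    so the filter is reproducible after a BED round trip.
    """
    keep = frozenset(keep_classes)
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    first_data = next((ln for ln in lines if ln.strip()), "")
    if _looks_like_out(first_data):
        return _read_rm_out(path, lines, keep)
    if "\t" in first_data:
        bed = read_bed(path)
        return [iv for iv in bed if _re_class_matches(iv.name, keep)]
    raise FormatError(f"{path}: neither RepeatMasker .out nor BED dialect")


def _read_rm_out(path: Path, lines: list[str], keep: frozenset[str]) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    header_seen = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if header_seen < 2 and _looks_like_out(line):
            header_seen += 1
            continue
        parts = line.split()
        if len(parts) < 11:
            raise ParseError(f"{path}:{lineno}: expected >=11 whitespace-separated columns")
        chrom, begin, end = parts[4], parts[5], parts[6]
        strand = "+" if parts[8] == "+" else "-"
        repeat_class = parts[10]
        try:
            start0, end0 = int(begin) - 1, int(end)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if not _re_class_matches(repeat_class, keep):
            continue
        try:
            intervals.append(GenomicInterval(chrom, start0, end0, strand, repeat_class))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


# ---------------------------------------------------------------------------
# Gene tables

GENE_TABLE_COLUMNS = ("chrom", "txStart", "txEnd", "strand", "gene_id", "gene_class")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a refGene-like TSV and collapse transcripts to one row per gene.

    The reference TSS is ``txStart`` for + genes and ``txEnd - 1`` for -
    genes (txStart/txEnd are 0-based half-open). When a gene has several
    transcripts the 5'-most TSS is kept: the minimum over + transcripts,
    the maximum over - transcripts.

    Returns a frame with columns gene_id, chrom, tss, strand, gene_class.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str, "gene_class": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ParseError(f"{path}: invalid strand value {df.loc[bad_strand, 'strand'].iloc[0]!r}")
    if (df["txEnd"] <= df["txStart"]).any():
        raise ParseError(f"{path}: txEnd <= txStart on some rows")
    if (df["txStart"] < 0).any():
        raise ParseError(f"{path}: negative txStart")

    df = df.copy()
    df["tss"] = df["txStart"].where(df["strand"] == "+", df["txEnd"] - 1)

    records = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        if grp["chrom"].nunique() > 1:
            raise DataError(f"gene {gene_id!r} annotated on multiple chromosomes")
        if grp["strand"].nunique() > 1:
            raise DataError(f"gene {gene_id!r} annotated on both strands")
        strand = grp["strand"].iloc[0]
        tss = int(grp["tss"].min() if strand == "+" else grp["tss"].max())
        records.append(
            {
                "gene_id": gene_id,
                "chrom": grp["chrom"].iloc[0],
                "tss": tss,
                "strand": strand,
                "gene_class": grp["gene_class"].iloc[0],
            }
        )
    return pd.DataFrame.from_records(records, columns=["gene_id", "chrom", "tss", "strand", "gene_class"])


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a gene table TSV in the refGene-like input layout."""
    missing = set(GENE_TABLE_COLUMNS) - set(genes.columns)
    if missing:
        raise DataError(f"gene table to write is missing columns {sorted(missing)}")
    genes.loc[:, list(GENE_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False)


def gene_records(genes: pd.DataFrame) -> list[GeneRecord]:
    """Materialize GeneRecord objects from a collapsed gene table frame."""
    return [
        GeneRecord(r.gene_id, r.chrom, int(r.tss), r.strand, r.gene_class)
        for r in genes.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line a set name, a description, then gene ids."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected name, description and >=1 gene id")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
            descriptions[name] = fields[1]
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            members = "\t".join(collection[name])
            fh.write(f"{name}\t{collection.description(name)}\t{members}\n")
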