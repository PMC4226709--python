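"""Readers and writers for the tabular and genomic formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals
(BED convention); the GTF serializer converts to 1-based closed on write and
back on read. Readers validate and raise rather than silently coercing
malformed input; every writer round-trips through its paired reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BIOTYPES = ("mRNA", "lncRNA")
TISSUES = ("N", "T")
SIZES = ("S", "L", "NA")


class FormatError(ValueError):
    """Malformed input file: wrong schema, bad value, or broken invariant."""


class ContractError(ValueError):
    """A call violated an operation's precondition."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript interval with strand, biotype, and optional exon structure.

    Coordinates are 0-based half-open. Exons, when present, are sorted,
    non-overlapping, and contained in [start, end).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"{self.id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.id}: unknown strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise FormatError(f"{self.id}: biotype must be one of {BIOTYPES}")
        prev_end = self.start
        for (es, ee) in self.exons:
            if es < prev_end or ee > self.end or es >= ee:
                raise FormatError(
                    f"{self.id}: exon ({es},{ee}) out of order or outside transcript"
                )
            prev_end = ee

    @property
    def tss(self) -> int:
        """Transcription start: `start` on +, `end` on - (half-open aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        if len(self.exons) < 2:
            return ()
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass
class ExpressionMatrix:
    """log2 expression values (features x samples) plus sample metadata.

    ``samples`` is indexed by sample id with columns ``patient``, ``tissue``
    (N/T) and ``size`` (S/L/NA); ``biotype`` maps each feature to mRNA or
    lncRNA.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    biotype: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if v.columns.has_duplicates:
            raise FormatError("duplicate sample ids in expression matrix")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            bad = np.argwhere(~np.isfinite(v.to_numpy(dtype=float)))[0]
            raise FormatError(
                f"non-finite value at feature {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        missing = set(v.columns) - set(self.samples.index)
        if missing:
            raise FormatError(f"samples absent from sample sheet: {sorted(missing)}")
        if self.biotype is None:
            self.biotype = pd.Series("mRNA", index=v.index)
        self.biotype = self.biotype.reindex(v.index)
        if self.biotype.isna().any():
            raise FormatError("biotype missing for some features")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_biotype(self, biotype: str) -> pd.DataFrame:
        return self.values.loc[self.biotype == biotype]


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, ordered unique member ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


# ---------------------------------------------------------------------------
# Expression matrix + sample sheet TSV
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, sample_sheet_path: str | Path) -> ExpressionMatrix:
    """Read a feature x sample TSV and join its sample sheet.

    The TSV's first column holds feature ids; the header row holds sample ids.
    The sheet must cover every sample. Non-numeric or missing cells and
    duplicate ids are rejected.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicated feature id(s): {dups}")
    biotype = None
    # biotype may ride along as a reserved column in the expression TSV
    if "biotype" in raw.columns:
        biotype = raw["biotype"]
        raw = raw.drop(columns=["biotype"])
    try:
        values = raw.apply(pd.to_numeric).astype(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in expression matrix: {exc}") from exc
    if values.isna().any().any():
        r, c = next(zip(*np.where(values.isna().to_numpy())))
        raise FormatError(
            f"NaN cell at feature {values.index[r]!r}, sample {values.columns[c]!r}"
        )
    sheet = read_sample_sheet(sample_sheet_path)
    return ExpressionMatrix(values=values, samples=sheet, biotype=biotype)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     sample_sheet_path: str | Path | None = None) -> None:
    out = matrix.values.copy()
    out["biotype"] = matrix.biotype
    out.index.name = "feature"
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")
    if sample_sheet_path is not None:
        write_sample_sheet(matrix.samples, sample_sheet_path)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    # keep_default_na: the size class "NA" (normal tissue) is a value, not missing
    sheet = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample", "patient", "tissue", "size"}
    if not required.issubset(sheet.columns):
        raise FormatError(
            f"sample sheet must have columns {sorted(required)}, got {list(sheet.columns)}"
        )
    if sheet["sample"].duplicated().any():
        raise FormatError("duplicate sample ids in sample sheet")
    bad_tissue = set(sheet["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise FormatError(f"unknown tissue value(s): {sorted(bad_tissue)}")
    bad_size = set(sheet["size"]) - set(SIZES)
    if bad_size:
        raise FormatError(f"unknown size value(s): {sorted(bad_size)}")
    return sheet.set_index("sample")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    out = sheet.reset_index()
    if "sample" not in out.columns:
        out = out.rename(columns={"index": "sample"})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Annotation: BED12 and GTF
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, dialect: str) -> list[TranscriptRecord]:
    """Read transcripts from BED12 or GTF into internal 0-based half-open form."""
    if dialect == "BED12":
        return _read_bed12(path)
    if dialect == "GTF":
        return _read_gtf(path)
    raise ContractError(f"unknown annotation dialect {dialect!r}")


def write_annotation(records: Sequence[TranscriptRecord], path: str | Path,
                     dialect: str) -> None:
    if dialect == "BED12":
        _write_bed12(records, path)
    elif dialect == "GTF":
        _write_gtf(records, path)
    else:
        raise ContractError(f"unknown annotation dialect {dialect!r}")


def _parse_bed_biotype(extra: str) -> str:
    for part in extra.split(";"):
        if part.startswith("biotype="):
            return part.split("=", 1)[1]
    raise FormatError("BED record lacks biotype=... tag in column 13")


def _read_bed12(path: str | Path) -> list[TranscriptRecord]:
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 13:
            raise FormatError(f"line {lineno}: expected 13 BED fields, got {len(f)}")
        chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")] if n_blocks else []
        starts = [int(x) for x in f[11].rstrip(",").split(",")] if n_blocks else []
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise FormatError(f"line {lineno}: blockCount disagrees with block lists")
        exons = tuple((start + s, start + s + z) for s, z in zip(starts, sizes))
        records.append(TranscriptRecord(
            id=name, chrom=chrom, start=start, end=end, strand=strand,
            biotype=_parse_bed_biotype(f[12]), exons=exons,
        ))
    return records


def _write_bed12(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    lines = []
    for r in records:
        exons = r.exons or ((r.start, r.end),)
        sizes = ",".join(str(e - s) for s, e in exons) + ","
        starts = ",".join(str(s - r.start) for s, e in exons) + ","
        lines.append("\t".join([
            r.chrom, str(r.start), str(r.end), r.id, "0", r.strand,
            str(r.start), str(r.end), "0", str(len(exons)), sizes, starts,
            f"biotype={r.biotype}",
        ]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def _read_gtf(path: str | Path) -> list[TranscriptRecord]:
    transcripts: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise FormatError(f"line {lineno}: expected 9 GTF fields, got {len(f)}")
        chrom, _src, feature, start1, end1, _score, strand, _frame, attr_text = f
        if strand not in ("+", "-"):
            raise FormatError(f"line {lineno}: unknown strand {strand!r}")
        # GTF is 1-based closed; internal form is 0-based half-open
        start, end = int(start1) - 1, int(end1)
        if start >= end:
            raise FormatError(f"line {lineno}: empty interval")
        attrs = _parse_gtf_attrs(attr_text)
        tid = attrs.get("transcript_id")
        if tid is None:
            raise FormatError(f"line {lineno}: missing transcript_id")
        if feature == "transcript":
            transcripts[tid] = dict(
                chrom=chrom, start=start, end=end, strand=strand,
                biotype=attrs.get("biotype", "mRNA"),
            )
        elif feature == "exon":
            exons.setdefault(tid, []).append((start, end))
    records = []
    for tid, t in transcripts.items():
        ex = tuple(sorted(exons.get(tid, [])))
        records.append(TranscriptRecord(id=tid, exons=ex, **t))
    return records


def _write_gtf(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    lines = []
    for r in records:
        attrs = f'gene_id "{r.id}"; transcript_id "{r.id}"; biotype "{r.biotype}";'
        lines.append("\t".join([
            r.chrom, "lncomat", "transcript", str(r.start + 1), str(r.end),
            ".", r.strand, ".", attrs,
        ]))
        for (es, ee) in r.exons:
            lines.append("\t".join([
                r.chrom, "lncomat", "exon", str(es + 1), str(ee),
                ".", r.strand, ".", attrs,
            ]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read tab-separated GMT (name, description, members...); dedups members."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise FormatError(f"line {lineno}: GMT line needs >= 3 fields")
        name, desc = f[0], f[1]
        if name in sets:
            raise FormatError(f"line {lineno}: duplicate gene set name {name!r}")
        members = tuple(dict.fromkeys(m for m in f[2:] if m))
        sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, desc, *members])
        for name, (desc, members) in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# JSON truth manifest (defined in synthio; (de)serialized here)
# ---------------------------------------------------------------------------

def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
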