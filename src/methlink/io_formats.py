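"""Readers and writers for every external format the pipeline touches.

Coordinate conventions
----------------------
All *internal* interval coordinates are 0-based half-open (BED-style).
GTF input (1-based inclusive) is converted on read; cytosine positions are
kept 1-based as read from the Bismark report and converted once, at the
interval-overlap boundary (see :func:`methlink.integration.interval_distance`
and region assignment in :mod:`methlink.methylation`).

Strand is carried through but ignored by all distance and overlap
computations.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GZIP_MAGIC = b"\x1f\x8b"

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CytosineTable:
    """Per-sample CpG methylation counts.

    ``data`` columns: chrom, pos (1-based), strand, meth, unmeth.
    """

    sample_id: str
    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CYTOSINE_COLUMNS))

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if list(self.data.columns) != CYTOSINE_COLUMNS:
            raise ValueError(f"CytosineTable columns must be {CYTOSINE_COLUMNS}")
        if len(self.data):
            if (self.data["meth"] < 0).any() or (self.data["unmeth"] < 0).any():
                raise ValueError("negative methylation counts")
            if (self.data["pos"] < 1).any():
                raise ValueError("cytosine positions must be >= 1")
            if self.data.duplicated(subset=["chrom", "pos"]).any():
                raise ValueError("duplicate (chrom, pos) in cytosine table")

    @property
    def coverage(self) -> pd.Series:
        return self.data["meth"] + self.data["unmeth"]

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One annotated transcript; coordinates 0-based half-open."""

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str  # "lncRNA", "protein_coding" or "other"
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.transcript_id}: start must be < end "
                f"({self.start} >= {self.end})"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class CountMatrix:
    """Transcript x sample integer read counts plus a case/control label per sample."""

    counts: pd.DataFrame  # transcripts (rows) x samples (columns)
    groups: pd.Series  # sample id -> "case" | "control"

    def __post_init__(self) -> None:
        if self.counts.isna().any().any():
            raise ValueError("count matrix contains missing cells")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(
                "samples present in count matrix but absent from sample sheet: "
                + ", ".join(missing)
            )
        self.groups = self.groups.loc[list(self.counts.columns)]
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in ("case", "control"):
            if (self.groups == g).sum() < 2:
                raise ValueError(f"need >=2 samples in group {g!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def _open_text(path: str | Path):
    """Open plain or gzip-compressed text, sniffing gzip by magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


# ---------------------------------------------------------------------------
# Bismark cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | Path, sample_id: str | None = None) -> CytosineTable:
    """Read a Bismark-style per-cytosine report, keeping CpG-context rows only.

    Expected columns (tab-separated): chrom, position (1-based), strand,
    count-methylated, count-unmethylated, context, trinucleotide context.
    The file may be gzip-compressed (detected by magic bytes).
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    records: list[tuple] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: position must be >= 1, got {pos}")
            if context != "CG":
                continue
            records.append((chrom, pos, strand, meth, unmeth))
    if not records:
        warnings.warn(f"{path}: no CpG records found, returning empty table")
        return CytosineTable(sample_id=sample_id)
    data = pd.DataFrame(records, columns=CYTOSINE_COLUMNS)
    return CytosineTable(sample_id=sample_id, data=data)


def write_cytosine_report(
    table: CytosineTable,
    path: str | Path,
    tri_context: str = "CGG",
    compress: bool | None = None,
) -> None:
    """Write a CytosineTable as a 7-column Bismark-style CpG report.

    Gzip output (deterministic: mtime fixed to 0) when ``compress`` is true
    or the filename ends in ``.gz``.
    """
    path = Path(path)
    if compress is None:
        compress = path.suffix == ".gz"
    lines = [
        f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.meth}\t{r.unmeth}\tCG\t{tri_context}\n"
        for r in table.data.itertuples(index=False)
    ]
    payload = "".join(lines).encode("utf-8")
    if compress:
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                gz.write(payload)
    else:
        with open(path, "wb") as fh:
            fh.write(payload)


# ---------------------------------------------------------------------------
# Transcript annotation (GTF / BED6+biotype)
# ---------------------------------------------------------------------------

_BIOTYPE_KEYS = ("transcript_type", "transcript_biotype", "biotype", "gene_type")


def _normalize_biotype(raw: str) -> str:
    if raw in ("lncRNA", "protein_coding"):
        return raw
    return "other"


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_annotation(path: str | Path) -> list[TranscriptAnnotation]:
    """Read transcript annotation from GTF (1-based inclusive) or BED6+biotype.

    All coordinates are normalized to 0-based half-open. Biotypes outside
    {lncRNA, protein_coding} are retained but flagged "other".
    """
    path = Path(path)
    suffixes = [s.lower() for s in path.suffixes]
    if ".gtf" in suffixes:
        return _read_gtf(path)
    if ".bed" in suffixes:
        return _read_bed_annotation(path)
    raise ParseError(
        f"{path}: unknown annotation format (expected .gtf or .bed, "
        f"optionally gzip-compressed)"
    )


def _read_gtf(path: Path) -> list[TranscriptAnnotation]:
    records: list[TranscriptAnnotation] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature != "transcript":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end < start ({end1} < {start1})")
            attrs = _parse_gtf_attributes(attr)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(f"{path}:{lineno}: transcript without transcript_id")
            biotype = "other"
            for key in _BIOTYPE_KEYS:
                if key in attrs:
                    biotype = _normalize_biotype(attrs[key])
                    break
            records.append(
                TranscriptAnnotation(
                    transcript_id=tid,
                    gene_id=attrs.get("gene_id", tid),
                    gene_name=attrs.get("gene_name", attrs.get("gene_id", tid)),
                    biotype=biotype,
                    chrom=chrom,
                    start=start1 - 1,  # 1-based inclusive -> 0-based half-open
                    end=end1,
                    strand=strand,
                )
            )
    _check_unique_transcripts(records, path)
    return records


def _read_bed_annotation(path: Path) -> list[TranscriptAnnotation]:
    """BED6 plus columns: 7=biotype, optional 8=gene_id, 9=gene_name."""
    records: list[TranscriptAnnotation] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(
                    f"{path}:{lineno}: need >=7 columns (BED6 + biotype)"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            records.append(
                TranscriptAnnotation(
                    transcript_id=name,
                    gene_id=fields[7] if len(fields) > 7 else name,
                    gene_name=fields[8] if len(fields) > 8 else name,
                    biotype=_normalize_biotype(fields[6]),
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    _check_unique_transcripts(records, path)
    return records


def _check_unique_transcripts(records: Sequence[TranscriptAnnotation], path: Path) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.transcript_id in seen:
            raise ParseError(f"{path}: duplicate transcript_id {rec.transcript_id!r}")
        seen.add(rec.transcript_id)


def write_gtf(records: Iterable[TranscriptAnnotation], path: str | Path) -> None:
    """Write transcripts as GTF (converting back to 1-based inclusive)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for rec in records:
            attrs = (
                f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}"; '
                f'gene_name "{rec.gene_name}"; transcript_type "{rec.biotype}";'
            )
            fh.write(
                f"{rec.chrom}\tmethlink\ttranscript\t{rec.start + 1}\t{rec.end}"
                f"\t.\t{rec.strand}\t.\t{attrs}\n"
            )


def annotation_frame(records: Sequence[TranscriptAnnotation]) -> pd.DataFrame:
    """Tabular view of an annotation, indexed by transcript_id."""
    df = pd.DataFrame(
        [
            (r.transcript_id, r.gene_id, r.gene_name, r.biotype, r.chrom, r.start, r.end, r.strand)
            for r in records
        ],
        columns=["transcript_id", "gene_id", "gene_name", "biotype", "chrom", "start", "end", "strand"],
    )
    return df.set_index("transcript_id")


# ---------------------------------------------------------------------------
# Count matrices and generic tables
# ---------------------------------------------------------------------------

def read_count_matrix(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a transcript x sample TSV count matrix plus a sample sheet.

    The sample sheet is a TSV with columns ``sample_id`` and ``group``
    (values ``case`` / ``control``).
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise ParseError(f"{samples_path}: sample sheet missing column {col!r}")
    groups = sheet.set_index("sample_id")["group"]
    if groups.index.duplicated().any():
        raise ParseError(f"{samples_path}: duplicate sample ids in sample sheet")
    for col in counts.columns:
        values = counts[col]
        if not (values == values.astype(int)).all():
            raise ParseError(f"{counts_path}: non-integer counts in sample {col!r}")
    counts = counts.astype(int)
    if (counts < 0).any().any():
        raise ParseError(f"{counts_path}: negative counts")
    return CountMatrix(counts=counts, groups=groups)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="transcript_id")
    sheet = pd.DataFrame({"sample_id": cm.groups.index, "group": cm.groups.values})
    sheet.to_csv(samples_path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as TSV such that :func:`read_table` round-trips it."""
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    """Write a feature x sample matrix TSV, keeping the index."""
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# DMR BED6+
# ---------------------------------------------------------------------------

DMR_BED_COLUMNS = ["chrom", "start", "end", "dmr_id", "stat", "strand",
                   "pvalue", "qvalue", "direction", "n_cpgs"]


def write_dmr_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    """Write a DMR table as BED6+ (stat in the score column, strand '.')."""
    out = dmrs.copy()
    out["strand"] = "."
    out = out[["chrom", "start", "end", "dmr_id", "stat", "strand",
               "pvalue", "qvalue", "direction", "n_cpgs"]]
    out.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def read_dmr_bed(path: str | Path) -> pd.DataFrame:
    """Read a DMR BED; plain BED3/BED6 gets default stat/q columns."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: need >=3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            dmr_id = f[3] if len(f) > 3 else f"{chrom}.{lineno}"
            stat = float(f[4]) if len(f) > 4 else 0.0
            pvalue = float(f[6]) if len(f) > 6 else float("nan")
            qvalue = float(f[7]) if len(f) > 7 else float("nan")
            direction = f[8] if len(f) > 8 else ("hyper" if stat > 0 else "hypo")
            n_cpgs = int(f[9]) if len(f) > 9 else 0
            rows.append((chrom, start, end, dmr_id, n_cpgs, stat, pvalue, qvalue, direction))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "dmr_id", "n_cpgs", "stat",
                 "pvalue", "qvalue", "direction"],
    )
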