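"""Readers and writers for the external formats the tool touches.

Covers bin FASTA directories, CheckM-dialect completeness/contamination
tables, Bakta-style TSV and GFF3 annotation files, and the metadata CSV.
All coordinates are 1-based inclusive; a feature of length L spans
``stop - start + 1 == L`` base pairs.
"""

from __future__ import annotations

import csv
import enum
import logging
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .reporting import MetadataRow

log = logging.getLogger(__name__)

#: Recognised bin file extensions (case-insensitive).
FASTA_EXTENSIONS = (".fasta", ".fna", ".fa")

#: Column order of the metadata CSV.  The first fourteen columns follow the
#: MIMAG-recommended metadata layout (quality, scores, software provenance,
#: assembly statistics); 5S/23S recovery flags are appended at the end so the
#: high-quality rule can be audited from the CSV alone.
METADATA_COLUMNS = (
    "bin_id",
    "assembly_quality",
    "completeness",
    "contamination",
    "completeness_software",
    "rrna_16s_recovered",
    "rrna_16s_software",
    "trna_extracted",
    "trna_software",
    "completeness_approach",
    "size_bp",
    "n50_bp",
    "max_contig_bp",
    "n_contigs",
    "rrna_5s_recovered",
    "rrna_23s_recovered",
)


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def strip_bin_extension(name: str) -> str:
    """Strip exactly one recognised FASTA extension from ``name``, if present.

    Bin ids are filename stems; completeness tables variously report bin ids
    with and without the extension, so both sides are normalised through this
    function before joining.
    """
    lower = name.lower()
    for ext in FASTA_EXTENSIONS:
        if lower.endswith(ext):
            return name[: -len(ext)]
    return name


@dataclass(frozen=True)
class BinRecord:
    """One metagenome bin: its id, origin and per-contig lengths (bp)."""

    bin_id: str
    source_path: str
    contig_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.bin_id:
            raise ValueError("bin_id must be non-empty")
        for contig, length in self.contig_lengths.items():
            if length < 1:
                raise ValueError(
                    f"bin {self.bin_id!r}: contig {contig!r} has non-positive "
                    f"length {length}"
                )

    @property
    def total_bp(self) -> int:
        return sum(self.contig_lengths.values())

    @property
    def n_contigs(self) -> int:
        return len(self.contig_lengths)


@dataclass(frozen=True)
class QualityEstimate:
    """Completeness/contamination for one bin, with software provenance.

    Completeness is a percentage in [0, 100]. Contamination is a percentage
    that may exceed 100 (marker-gene redundancy is unbounded above).
    """

    bin_id: str
    completeness: float
    contamination: float
    software: str = "CheckM"

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(
                f"bin {self.bin_id!r}: completeness {self.completeness} "
                "outside [0, 100]"
            )
        if self.contamination < 0.0:
            raise ValueError(
                f"bin {self.bin_id!r}: contamination {self.contamination} < 0"
            )


class FeatureType(enum.Enum):
    TRNA = "tRNA"
    RRNA = "rRNA"
    OTHER = "other"


def _feature_type(raw: str) -> FeatureType:
    low = raw.strip().lower()
    if low == "trna":
        return FeatureType.TRNA
    if low == "rrna":
        return FeatureType.RRNA
    return FeatureType.OTHER


@dataclass(frozen=True)
class AnnotationFeature:
    """One annotated feature, 1-based inclusive coordinates."""

    contig_id: str
    feature_type: FeatureType
    start: int
    stop: int
    strand: str = "?"
    product: str = ""
    gene: str | None = None
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.stop:
            raise ValueError(
                f"feature on {self.contig_id!r}: invalid coordinates "
                f"{self.start}..{self.stop}"
            )
        if self.strand not in ("+", "-", "?"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


def _parse_fasta_lengths(path: Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in lengths:
                raise FormatError(
                    f"{path}: duplicate contig id {record.id!r}"
                )
            if len(record.seq) == 0:
                raise FormatError(f"{path}: contig {record.id!r} is empty")
            lengths[record.id] = len(record.seq)
    except FormatError:
        raise
    except Exception as exc:  # Bio raises assorted ValueErrors on bad input
        raise FormatError(f"{path}: unparseable FASTA ({exc})") from exc
    if not lengths:
        raise FormatError(f"{path}: unparseable FASTA (no records found)")
    return lengths


def read_assembly(path: str | Path) -> BinRecord:
    """Read a (meta)genome assembly FASTA into a BinRecord."""
    p = Path(path)
    return BinRecord(
        bin_id=strip_bin_extension(p.name),
        source_path=str(p),
        contig_lengths=_parse_fasta_lengths(p),
    )


def scan_bin_directory(dir_path: str | Path) -> list[BinRecord]:
    """Collect every ``.fasta``/``.fna``/``.fa`` file in a directory as a bin.

    Returns records sorted by bin id (so repeated scans are order-stable).
    Raises :class:`FormatError` if the directory holds no matching files or
    any matching file is not valid FASTA.
    """
    d = Path(dir_path)
    if not d.is_dir():
        raise FormatError(f"{d}: not a directory")
    records: list[BinRecord] = []
    for entry in sorted(d.iterdir()):
        if not entry.is_file():
            continue
        if not entry.name.lower().endswith(FASTA_EXTENSIONS):
            continue
        records.append(
            BinRecord(
                bin_id=strip_bin_extension(entry.name),
                source_path=str(entry),
                contig_lengths=_parse_fasta_lengths(entry),
            )
        )
    if not records:
        raise FormatError(f"{d}: no bins found (extensions {FASTA_EXTENSIONS})")
    records.sort(key=lambda r: r.bin_id)
    ids = [r.bin_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise FormatError(f"{d}: duplicate bin ids after extension strip: {sorted(dupes)}")
    return records


def _find_column(headers: list[str], *needles: str) -> int | None:
    for i, h in enumerate(headers):
        norm = h.strip().lower().replace("_", " ")
        if any(norm.startswith(n) for n in needles):
            return i
    return None


def parse_quality_table(
    path: str | Path, software: str = "CheckM"
) -> dict[str, QualityEstimate]:
    """Parse a CheckM-dialect quality table into per-bin estimates.

    The file is tab- or comma-separated (sniffed from the header line) with a
    header row containing a bin-id column plus ``Completeness`` and
    ``Contamination`` (case-insensitive); extra columns such as marker lineage
    or strain heterogeneity are ignored. Bin ids are normalised by stripping a
    recognised FASTA extension so they join against filename stems.
    """
    p = Path(path)
    lines = [ln for ln in p.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{p}: empty quality table")
    delimiter = "\t" if "\t" in lines[0] else ","
    rows = list(csv.reader(lines, delimiter=delimiter))
    headers = rows[0]
    comp_col = _find_column(headers, "completeness")
    cont_col = _find_column(headers, "contamination")
    bin_col = _find_column(headers, "bin id", "bin", "genome", "name", "id")
    if bin_col is None:
        bin_col = 0
    if comp_col is None or cont_col is None:
        raise FormatError(
            f"{p}: missing Completeness/Contamination column; "
            f"found headers {headers}"
        )
    out: dict[str, QualityEstimate] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) <= max(bin_col, comp_col, cont_col):
            raise FormatError(f"{p}: row {lineno}: too few columns")
        bin_id = strip_bin_extension(row[bin_col].strip())
        if bin_id in out:
            raise FormatError(f"{p}: row {lineno}: duplicate bin id {bin_id!r}")
        try:
            comp = float(row[comp_col])
            cont = float(row[cont_col])
        except ValueError as exc:
            raise FormatError(
                f"{p}: row {lineno} (bin {bin_id!r}): non-numeric "
                "completeness/contamination"
            ) from exc
        try:
            out[bin_id] = QualityEstimate(bin_id, comp, cont, software)
        except ValueError as exc:
            raise FormatError(f"{p}: row {lineno}: {exc}") from exc
    return out


_TSV_DEFAULT_COLUMNS = [
    "sequence id", "type", "start", "stop", "strand",
    "locus tag", "gene", "product",
]


def _is_pseudo(text: str) -> bool:
    return "pseudo" in text.lower()


def parse_annotation_tsv(path: str | Path) -> list[AnnotationFeature]:
    """Parse a Bakta-style feature TSV.

    Header lines start with ``#``; the last such line may carry the column
    names (``#Sequence Id\\tType\\tStart\\tStop\\tStrand\\tLocus Tag\\tGene\\t
    Product``). Rows whose Type is tRNA or rRNA become typed features; every
    other type maps to ``other``.
    """
    p = Path(path)
    columns = list(_TSV_DEFAULT_COLUMNS)
    features: list[AnnotationFeature] = []
    for lineno, line in enumerate(p.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if "\t" in line:  # commented header row names the columns
                columns = [c.strip().lower() for c in line.lstrip("#").split("\t")]
            continue
        cells = line.split("\t")
        if len(cells) < 5:
            raise FormatError(f"{p}: line {lineno}: expected >=5 columns")

        def cell(name: str) -> str:
            try:
                idx = columns.index(name)
            except ValueError:
                return ""
            return cells[idx].strip() if idx < len(cells) else ""

        try:
            start = int(cell("start"))
            stop = int(cell("stop"))
        except ValueError as exc:
            raise FormatError(
                f"{p}: line {lineno}: malformed coordinates"
            ) from exc
        strand = cell("strand")
        product = cell("product")
        gene = cell("gene") or None
        try:
            features.append(
                AnnotationFeature(
                    contig_id=cells[columns.index("sequence id")].strip(),
                    feature_type=_feature_type(cell("type")),
                    start=start,
                    stop=stop,
                    strand=strand if strand in ("+", "-") else "?",
                    product=product,
                    gene=gene,
                    pseudo=_is_pseudo(product),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{p}: line {lineno}: {exc}") from exc
    return features


def _gff3_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip().lower()] = urllib.parse.unquote(value.strip())
        else:
            attrs[part.lower()] = "true"
    return attrs


def parse_annotation_gff3(path: str | Path) -> list[AnnotationFeature]:
    """Parse a GFF3 annotation file (directives skipped, ``##FASTA`` trailer
    ignored); ``product`` and ``gene`` are read from the attributes column."""
    p = Path(path)
    features: list[AnnotationFeature] = []
    for lineno, line in enumerate(p.read_text().splitlines(), start=1):
        if line.startswith("##FASTA"):
            break
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise FormatError(
                f"{p}: line {lineno}: expected 9 tab-separated columns, "
                f"got {len(cols)}"
            )
        try:
            start = int(cols[3])
            stop = int(cols[4])
        except ValueError as exc:
            raise FormatError(
                f"{p}: line {lineno}: malformed coordinates"
            ) from exc
        attrs = _gff3_attributes(cols[8])
        product = attrs.get("product", "")
        pseudo = (
            attrs.get("pseudo", "").lower() == "true"
            or "pseudogene" in attrs
            or _is_pseudo(product)
        )
        try:
            features.append(
                AnnotationFeature(
                    contig_id=cols[0],
                    feature_type=_feature_type(cols[2]),
                    start=start,
                    stop=stop,
                    strand=cols[6] if cols[6] in ("+", "-") else "?",
                    product=product,
                    gene=attrs.get("gene") or None,
                    pseudo=pseudo,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{p}: line {lineno}: {exc}") from exc
    return features


def write_metadata_csv(rows: Iterable["MetadataRow"], path: str | Path) -> None:
    """Write metadata rows as RFC-4180 CSV (header + one line per bin,
    input order preserved)."""
    rows = list(rows)
    if not rows:
        raise FormatError("no metadata rows to write")
    p = Path(path)
    with p.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=METADATA_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow(row.to_record())


def read_metadata_csv(path: str | Path) -> list["MetadataRow"]:
    """Read a metadata CSV back into rows (exact round trip of
    :func:`write_metadata_csv`)."""
    from .reporting import MetadataRow  # local import avoids a cycle

    p = Path(path)
    with p.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != list(
            METADATA_COLUMNS
        ):
            raise FormatError(
                f"{p}: unexpected metadata header {reader.fieldnames}"
            )
        return [MetadataRow.from_record(rec) for rec in reader]
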