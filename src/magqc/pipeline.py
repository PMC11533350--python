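"""End-to-end orchestration: read the four inputs, classify every bin and
write the metadata CSV, quality-sorted directories, JSON sidecar and report.
"""

from __future__ import annotations

import datetime as _dt
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from .assembly_stats import BinnedSummary, ContigStats, binned_summary, contig_stats
from .formats_io import (
    AnnotationFeature,
    BinRecord,
    FormatError,
    QualityEstimate,
    parse_annotation_gff3,
    parse_annotation_tsv,
    parse_quality_table,
    read_assembly,
    scan_bin_directory,
    strip_bin_extension,
    write_metadata_csv,
)
from .mimag import (
    DEFAULT_THRESHOLDS,
    Classification,
    ClassificationThresholds,
    classify_all,
)
from .reporting import (
    MetadataRow,
    Provenance,
    RunReport,
    build_metadata_rows,
    discover_runs,
    render_report,
    sort_bins_by_quality,
    summarize_run,
    write_run_sidecar,
)
from .rna_census import RnaCensus, census

log = logging.getLogger(__name__)

_ANNOTATION_SUFFIXES = (".tsv", ".gff", ".gff3")


def default_prefix(today: _dt.date | None = None) -> str:
    """Default run prefix, ``magqc_YYYYMMDD``."""
    d = today or _dt.date.today()
    return f"magqc_{d:%Y%m%d}"


def _parse_annotation_file(path: Path) -> list[AnnotationFeature]:
    if path.suffix.lower() in (".gff", ".gff3"):
        return parse_annotation_gff3(path)
    return parse_annotation_tsv(path)


def load_annotations(
    annotations: str | Path,
    bins: list[BinRecord],
    min_rrna_len_fraction: float = 0.0,
    jobs: int = 1,
) -> dict[str, RnaCensus]:
    """Build per-bin RNA censuses from an annotation directory or file.

    A directory may hold one file per bin (file stem == bin id) and/or
    concatenated files; features in files whose stem matches no bin are
    assigned to bins by contig-id membership.
    """
    p = Path(annotations)
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir()
            if f.is_file() and f.suffix.lower() in _ANNOTATION_SUFFIXES
        )
        if not files:
            raise FormatError(f"{p}: no annotation files (*.tsv, *.gff, *.gff3)")
    elif p.is_file():
        files = [p]
    else:
        raise FormatError(f"{p}: no such annotation file or directory")

    if jobs > 1:
        with ThreadPoolExecutor(max_workers=jobs) as pool:
            parsed = list(pool.map(_parse_annotation_file, files))
    else:
        parsed = [_parse_annotation_file(f) for f in files]

    bin_ids = {b.bin_id for b in bins}
    contig_to_bin = {
        contig: b.bin_id for b in bins for contig in b.contig_lengths
    }
    per_bin: dict[str, list[AnnotationFeature]] = {b.bin_id: [] for b in bins}
    for f, features in zip(files, parsed):
        stem = strip_bin_extension(f.stem)
        if stem in bin_ids:
            per_bin[stem].extend(features)
            continue
        for feat in features:  # concatenated file: assign by contig id
            owner = contig_to_bin.get(feat.contig_id)
            if owner is None:
                log.warning(
                    "%s: feature contig %r matches no bin; skipped",
                    f, feat.contig_id,
                )
                continue
            per_bin[owner].append(feat)
    return {
        bin_id: census(feats, min_rrna_len_fraction)
        for bin_id, feats in per_bin.items()
    }


@dataclass
class PipelineResult:
    prefix: str
    bins: list[BinRecord]
    qualities: dict[str, QualityEstimate]
    censuses: dict[str, RnaCensus]
    classifications: list[Classification]
    stats: dict[str, ContigStats]
    binned: BinnedSummary
    rows: list[MetadataRow]
    report: RunReport
    csv_path: Path
    sidecar_path: Path
    html_path: Path | None
    quality_dirs: Path


def run_pipeline(
    asm_path: str | Path,
    bins_dir: str | Path,
    quality_table: str | Path,
    annotations: str | Path,
    out_dir: str | Path,
    prefix: str | None = None,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    provenance: Provenance = Provenance(),
    min_rrna_len_fraction: float = 0.0,
    mode: str = "copy",
    jobs: int = 1,
    write_report: bool = True,
) -> PipelineResult:
    """Run the full quality-assignment pipeline and write all outputs.

    Outputs under ``out_dir``: ``<prefix>.magqc.csv`` (metadata),
    ``<prefix>.magqc.json`` (run sidecar), ``<prefix>_bins/<category>/``
    (bins sorted by quality) and, when ``write_report`` is set,
    ``<prefix>_report.html`` (+ ``.json``) comparing every run whose sidecar
    lives in ``out_dir``.
    """
    prefix = prefix or default_prefix()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bins = scan_bin_directory(bins_dir)
    assembly = read_assembly(asm_path)
    qualities = parse_quality_table(
        quality_table, software=provenance.completeness_software
    )
    censuses = load_annotations(
        annotations, bins, min_rrna_len_fraction, jobs=jobs
    )
    classifications = classify_all(qualities, censuses, thresholds, bins=bins)
    stats = {
        b.bin_id: contig_stats(list(b.contig_lengths.values())) for b in bins
    }
    binned = binned_summary(assembly, bins)
    rows = build_metadata_rows(
        bins, qualities, censuses, classifications, stats, provenance
    )

    csv_path = out / f"{prefix}.magqc.csv"
    write_metadata_csv(rows, csv_path)
    quality_dirs = out / f"{prefix}_bins"
    sort_bins_by_quality(
        classifications,
        {b.bin_id: b.source_path for b in bins},
        quality_dirs,
        mode=mode,
    )
    report = summarize_run(classifications, binned, prefix, rows=rows)
    sidecar_path = write_run_sidecar(report, out)

    html_path: Path | None = None
    if write_report:
        runs = discover_runs(out)  # cross-run: every sidecar in out_dir
        html_path = render_report(runs, out / f"{prefix}_report.html")

    log.info(
        "run %s: %d bins classified (%s)",
        prefix,
        len(classifications),
        ", ".join(f"{k}={v}" for k, v in report.category_counts.items() if v),
    )
    return PipelineResult(
        prefix=prefix,
        bins=bins,
        qualities=qualities,
        censuses=censuses,
        classifications=classifications,
        stats=stats,
        binned=binned,
        rows=rows,
        report=report,
        csv_path=csv_path,
        sidecar_path=sidecar_path,
        html_path=html_path,
        quality_dirs=quality_dirs,
    )
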