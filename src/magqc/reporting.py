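"""Metadata CSV rows, quality-sorted output directories, and the per-run /
cross-run summary report (static HTML + JSON sidecar).

The JSON sidecar is the machine-readable record of a run (schema field
``magqc_schema``); the cross-run report is rebuilt purely from sidecars, so
report bytes are a deterministic function of the runs and the tool version.
"""

from __future__ import annotations

import html
import io
import json
import logging
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .assembly_stats import BinnedSummary, ContigStats
from .formats_io import (
    METADATA_COLUMNS,
    BinRecord,
    FormatError,
    QualityEstimate,
)
from .mimag import Category, Classification
from .rna_census import RnaCensus

log = logging.getLogger(__name__)

SCHEMA_KEY = "magqc_schema"
SCHEMA_VERSION = 1
SIDECAR_SUFFIX = ".magqc.json"

#: Fixed salt so matplotlib's generated SVG ids are reproducible.
_SVG_HASHSALT = "magqc-report"


@dataclass(frozen=True)
class Provenance:
    """Software provenance strings carried verbatim into the metadata CSV."""

    completeness_software: str = "CheckM (unspecified version)"
    annotation_software: str = "Bakta (unspecified version)"


@dataclass(frozen=True)
class MetadataRow:
    """One bin's MIMAG-recommended metadata record.

    ``trna_extracted`` holds the numerator of the "N/20" amino-acid coverage;
    booleans render as Yes/No in the CSV. ``completeness_approach`` is the
    literal "Marker gene" (the estimates come from single-copy marker genes).
    """

    bin_id: str
    assembly_quality: str
    completeness: float
    contamination: float
    completeness_software: str
    rrna_16s_recovered: bool
    rrna_16s_software: str
    trna_extracted: int
    trna_software: str
    completeness_approach: str
    size_bp: int
    n50_bp: int
    max_contig_bp: int
    n_contigs: int
    rrna_5s_recovered: bool
    rrna_23s_recovered: bool

    def __post_init__(self) -> None:
        if not 0 <= self.trna_extracted <= 20:
            raise ValueError("trna_extracted numerator must be in [0, 20]")
        Category.from_label(self.assembly_quality)  # validates the label

    def to_record(self) -> dict[str, str]:
        rec = {
            "bin_id": self.bin_id,
            "assembly_quality": self.assembly_quality,
            "completeness": str(self.completeness),
            "contamination": str(self.contamination),
            "completeness_software": self.completeness_software,
            "rrna_16s_recovered": "Yes" if self.rrna_16s_recovered else "No",
            "rrna_16s_software": self.rrna_16s_software,
            "trna_extracted": f"{self.trna_extracted}/20",
            "trna_software": self.trna_software,
            "completeness_approach": self.completeness_approach,
            "size_bp": str(self.size_bp),
            "n50_bp": str(self.n50_bp),
            "max_contig_bp": str(self.max_contig_bp),
            "n_contigs": str(self.n_contigs),
            "rrna_5s_recovered": "Yes" if self.rrna_5s_recovered else "No",
            "rrna_23s_recovered": "Yes" if self.rrna_23s_recovered else "No",
        }
        assert tuple(rec) == METADATA_COLUMNS
        return rec

    @classmethod
    def from_record(cls, rec: Mapping[str, str]) -> "MetadataRow":
        return cls(
            bin_id=rec["bin_id"],
            assembly_quality=rec["assembly_quality"],
            completeness=float(rec["completeness"]),
            contamination=float(rec["contamination"]),
            completeness_software=rec["completeness_software"],
            rrna_16s_recovered=rec["rrna_16s_recovered"] == "Yes",
            rrna_16s_software=rec["rrna_16s_software"],
            trna_extracted=int(rec["trna_extracted"].split("/")[0]),
            trna_software=rec["trna_software"],
            completeness_approach=rec["completeness_approach"],
            size_bp=int(rec["size_bp"]),
            n50_bp=int(rec["n50_bp"]),
            max_contig_bp=int(rec["max_contig_bp"]),
            n_contigs=int(rec["n_contigs"]),
            rrna_5s_recovered=rec["rrna_5s_recovered"] == "Yes",
            rrna_23s_recovered=rec["rrna_23s_recovered"] == "Yes",
        )


def build_metadata_rows(
    bins: Sequence[BinRecord],
    qualities: Mapping[str, QualityEstimate],
    censuses: Mapping[str, RnaCensus],
    classifications: Sequence[Classification],
    stats: Mapping[str, ContigStats],
    provenance: Provenance = Provenance(),
) -> list[MetadataRow]:
    """One metadata row per bin, sorted by bin id."""
    by_class = {c.bin_id: c for c in classifications}
    rows: list[MetadataRow] = []
    for b in sorted(bins, key=lambda b: b.bin_id):
        missing = [
            name
            for name, mapping in (
                ("quality", qualities),
                ("classification", by_class),
                ("stats", stats),
            )
            if b.bin_id not in mapping
        ]
        if missing:
            raise KeyError(f"bin {b.bin_id!r}: missing {', '.join(missing)}")
        q = qualities[b.bin_id]
        cen = censuses.get(b.bin_id, RnaCensus.empty())
        st = stats[b.bin_id]
        rows.append(
            MetadataRow(
                bin_id=b.bin_id,
                assembly_quality=by_class[b.bin_id].category.label,
                completeness=q.completeness,
                contamination=q.contamination,
                completeness_software=provenance.completeness_software,
                rrna_16s_recovered=cen.rrna_16s,
                rrna_16s_software=provenance.annotation_software,
                trna_extracted=cen.trna_count,
                trna_software=provenance.annotation_software,
                completeness_approach="Marker gene",
                size_bp=st.size_bp,
                n50_bp=st.n50_bp,
                max_contig_bp=st.max_contig_bp,
                n_contigs=st.n_contigs,
                rrna_5s_recovered=cen.rrna_5s,
                rrna_23s_recovered=cen.rrna_23s,
            )
        )
    return rows


def sort_bins_by_quality(
    classifications: Sequence[Classification],
    bin_paths: Mapping[str, str | Path],
    out_dir: str | Path,
    mode: str = "copy",
) -> dict[Category, list[Path]]:
    """Place each bin file into a per-category subdirectory.

    All five category directories are created even when empty. ``mode`` is
    ``copy`` or ``link`` (symlinks back to the originals).
    """
    if mode not in ("copy", "link"):
        raise ValueError(f"mode must be 'copy' or 'link', got {mode!r}")
    out = Path(out_dir)
    placed: dict[Category, list[Path]] = {}
    for cat in Category:
        (out / cat.dirname).mkdir(parents=True, exist_ok=True)
        placed[cat] = []
    names = [Path(bin_paths[c.bin_id]).name for c in classifications]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise FormatError(f"bin filename collision: {dupes}")
    for c in classifications:
        src = Path(bin_paths[c.bin_id])
        dest = out / c.category.dirname / src.name
        if mode == "copy":
            shutil.copy2(src, dest)
        else:
            if dest.is_symlink() or dest.exists():
                dest.unlink()
            os.symlink(src.resolve(), dest)
        placed[c.category].append(dest)
    return placed


@dataclass
class RunReport:
    """Summary of one run: category counts, binning totals and per-bin rows."""

    run_prefix: str
    category_counts: dict[str, int]
    binned_summary: BinnedSummary | None
    rows: list[MetadataRow] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return sum(self.category_counts.values())

    def to_dict(self) -> dict:
        d: dict = {
            SCHEMA_KEY: SCHEMA_VERSION,
            "run_prefix": self.run_prefix,
            "category_counts": dict(self.category_counts),
            "rows": [r.to_record() for r in self.rows],
        }
        if self.binned_summary is not None:
            b = self.binned_summary
            d["binned_summary"] = {
                "bases_binned": b.bases_binned,
                "contigs_binned": b.contigs_binned,
                "assembly_bases": b.assembly_bases,
                "assembly_contigs": b.assembly_contigs,
                "fraction_bases": b.fraction_bases,
                "fraction_contigs": b.fraction_contigs,
                "warnings": list(b.warnings),
            }
        else:
            d["binned_summary"] = None
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunReport":
        if d.get(SCHEMA_KEY) != SCHEMA_VERSION:
            raise FormatError(
                f"unsupported sidecar schema {d.get(SCHEMA_KEY)!r}"
            )
        b = d.get("binned_summary")
        binned = (
            BinnedSummary(
                bases_binned=b["bases_binned"],
                contigs_binned=b["contigs_binned"],
                assembly_bases=b["assembly_bases"],
                assembly_contigs=b["assembly_contigs"],
                fraction_bases=b["fraction_bases"],
                fraction_contigs=b["fraction_contigs"],
                warnings=tuple(b.get("warnings", ())),
            )
            if b
            else None
        )
        return cls(
            run_prefix=d["run_prefix"],
            category_counts=dict(d["category_counts"]),
            binned_summary=binned,
            rows=[MetadataRow.from_record(r) for r in d.get("rows", [])],
        )


def summarize_run(
    classifications: Sequence[Classification],
    binned_summary: BinnedSummary | None,
    prefix: str,
    rows: Sequence[MetadataRow] = (),
) -> RunReport:
    """Aggregate a run's classifications into per-category counts."""
    counts = {cat.label: 0 for cat in Category}
    for c in classifications:
        counts[c.category.label] += 1
    return RunReport(
        run_prefix=prefix,
        category_counts=counts,
        binned_summary=binned_summary,
        rows=list(rows),
    )


def write_run_sidecar(report: RunReport, out_dir: str | Path) -> Path:
    """Write a run's JSON sidecar (``<prefix>.magqc.json``) for later
    cross-run discovery."""
    path = Path(out_dir) / f"{report.run_prefix}{SIDECAR_SUFFIX}"
    path.write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return path


def discover_runs(directory: str | Path) -> list[RunReport]:
    """Load every run sidecar found in ``directory``, sorted by prefix."""
    runs = [
        RunReport.from_dict(json.loads(p.read_text()))
        for p in sorted(Path(directory).glob(f"*{SIDECAR_SUFFIX}"))
    ]
    return sorted(runs, key=lambda r: r.run_prefix)


# --- figure rendering -------------------------------------------------------

def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def _category_counts_figure(runs: Sequence[RunReport]) -> str:
    labels = [cat.label for cat in reversed(Category)]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    width = 0.8 / len(runs)
    xs = range(len(labels))
    for i, run in enumerate(runs):
        ax.bar(
            [x + i * width for x in xs],
            [run.category_counts.get(l, 0) for l in labels],
            width=width,
            label=run.run_prefix,
        )
    ax.set_xticks([x + 0.4 - width / 2 for x in xs])
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_ylabel("MAGs")
    ax.set_title("MAG quality categories per run")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _binned_totals_figure(runs: Sequence[RunReport]) -> str:
    with_summary = [r for r in runs if r.binned_summary is not None]
    if not with_summary:
        return ""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(7, 3))
    names = [r.run_prefix for r in with_summary]
    ax1.bar(names, [r.binned_summary.bases_binned for r in with_summary])
    ax1.set_ylabel("bases binned (bp)")
    ax2.bar(names, [r.binned_summary.contigs_binned for r in with_summary])
    ax2.set_ylabel("contigs binned")
    for ax in (ax1, ax2):
        ax.tick_params(axis="x", labelrotation=45, labelsize=7)
    fig.suptitle("Assembly captured by binning")
    fig.tight_layout()
    return _fig_to_svg(fig)


def _distribution_figure(runs: Sequence[RunReport]) -> str:
    metrics = [
        ("completeness", "Completeness (%)", lambda r: r.completeness),
        ("contamination", "Contamination (%)", lambda r: r.contamination),
        ("n50", "N50 (bp)", lambda r: r.n50_bp),
        ("size", "Size (bp)", lambda r: r.size_bp),
        ("trna", "tRNA aa /20", lambda r: r.trna_extracted),
    ]
    fig, axes = plt.subplots(1, len(metrics), figsize=(11, 3))
    names = [r.run_prefix for r in runs]
    for ax, (_, title, getter) in zip(axes, metrics):
        data = [[getter(row) for row in run.rows] or [0] for run in runs]
        ax.boxplot(data, tick_labels=names)
        ax.set_title(title, fontsize=8)
        ax.tick_params(axis="x", labelrotation=90, labelsize=6)
        ax.tick_params(axis="y", labelsize=7)
    fig.tight_layout()
    return _fig_to_svg(fig)


_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>MAG quality report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
th, td {{ border: 1px solid #999; padding: 0.3em 0.7em; text-align: right; }}
th:first-child, td:first-child {{ text-align: left; }}
</style>
</head>
<body>
<h1>MAG quality report</h1>
<p>Generated by magqc v{version}. Runs compared: {n_runs}.</p>
<h2>Quality category counts</h2>
{count_table}
{count_figure}
<h2>Bases and contigs binned</h2>
{binned_table}
{binned_figure}
<h2>Per-bin distributions</h2>
{dist_figure}
</body>
</html>
"""


def _counts_table_html(runs: Sequence[RunReport]) -> str:
    head = "".join(f"<th>{html.escape(r.run_prefix)}</th>" for r in runs)
    body_rows = []
    for cat in reversed(Category):
        cells = "".join(
            f"<td>{r.category_counts.get(cat.label, 0)}</td>" for r in runs
        )
        body_rows.append(f"<tr><td>{cat.label}</td>{cells}</tr>")
    totals = "".join(f"<td><b>{r.n_bins}</b></td>" for r in runs)
    body_rows.append(f"<tr><td><b>Total MAGs</b></td>{totals}</tr>")
    return (
        f"<table><tr><th>Quality</th>{head}</tr>"
        + "".join(body_rows)
        + "</table>"
    )


def _binned_table_html(runs: Sequence[RunReport]) -> str:
    rows = []
    for r in runs:
        b = r.binned_summary
        if b is None:
            continue
        rows.append(
            f"<tr><td>{html.escape(r.run_prefix)}</td>"
            f"<td>{b.bases_binned}</td><td>{b.contigs_binned}</td>"
            f"<td>{b.fraction_bases:.4f}</td>"
            f"<td>{b.fraction_contigs:.4f}</td></tr>"
        )
    if not rows:
        return "<p>No binning summary available.</p>"
    return (
        "<table><tr><th>Run</th><th>Bases binned</th><th>Contigs binned</th>"
        "<th>Fraction bases</th><th>Fraction contigs</th></tr>"
        + "".join(rows)
        + "</table>"
    )


def render_report(runs: Sequence[RunReport], out_path: str | Path) -> Path:
    """Render the cross-run HTML report and its JSON sidecar.

    Writes the HTML to ``out_path`` and the combined machine-readable JSON to
    ``out_path`` with a ``.json`` suffix. Output bytes depend only on the
    runs and the tool version.
    """
    if not runs:
        raise ValueError("render_report requires at least one run")
    out = Path(out_path)
    with matplotlib.rc_context(
        {"svg.hashsalt": _SVG_HASHSALT, "svg.fonttype": "none"}
    ):
        count_fig = _category_counts_figure(runs)
        binned_fig = _binned_totals_figure(runs)
        dist_fig = _distribution_figure(runs)
    html_text = _HTML_TEMPLATE.format(
        version=__version__,
        n_runs=len(runs),
        count_table=_counts_table_html(runs),
        count_figure=count_fig,
        binned_table=_binned_table_html(runs),
        binned_figure=binned_fig,
        dist_figure=dist_fig,
    )
    out.write_text(html_text)
    sidecar = out.with_suffix(out.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {SCHEMA_KEY: SCHEMA_VERSION, "runs": [r.to_dict() for r in runs]},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return out
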