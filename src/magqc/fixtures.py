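"""Synthetic test data: bins, an assembly, a quality table and annotation
files with requested properties, so the whole pipeline runs with no external
tools or downloads.

Completeness and contamination are injected straight into the quality table
rather than simulated from marker genes — the tool's scope starts downstream
of the completeness estimator, so fixtures stay desk-scale and exactly
reproducible. Sequence content is uniform random A/C/G/T and makes no claim
to biological realism.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .mimag import (
    DEFAULT_THRESHOLDS,
    Category,
    ClassificationThresholds,
    classify,
)
from .formats_io import QualityEstimate
from .rna_census import RRNA_REFERENCE_LENGTHS, STANDARD_AMINO_ACIDS, RnaCensus


class FixtureError(ValueError):
    """Raised when a fixture spec is internally inconsistent."""


@dataclass(frozen=True)
class FixtureBinSpec:
    """Ground truth for one synthetic bin."""

    bin_id: str
    target_category: Category
    completeness: float
    contamination: float
    trna_aa_count: int
    rrna_5s: bool
    rrna_16s: bool
    rrna_23s: bool
    n_contigs: int = 4
    min_contig_bp: int = 500
    max_contig_bp: int = 3000

    def __post_init__(self) -> None:
        if not 0 <= self.trna_aa_count <= 20:
            raise FixtureError(f"bin {self.bin_id!r}: trna_aa_count not in [0, 20]")
        if self.n_contigs < 1 or self.min_contig_bp < 1:
            raise FixtureError(f"bin {self.bin_id!r}: invalid contig plan")
        if self.min_contig_bp > self.max_contig_bp:
            raise FixtureError(f"bin {self.bin_id!r}: min_contig_bp > max_contig_bp")


@dataclass(frozen=True)
class FixtureSpec:
    """A full synthetic dataset: bins plus a fraction of unbinned assembly
    contigs. Each bin's requested scores and census must actually classify to
    its target category under the given thresholds — checked at construction.
    """

    bins: tuple[FixtureBinSpec, ...]
    seed: int
    unbinned_fraction: float = 0.25
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if not self.bins:
            raise FixtureError("spec contains no bins")
        ids = [b.bin_id for b in self.bins]
        if len(set(ids)) != len(ids):
            raise FixtureError("duplicate bin ids in spec")
        if not 0 <= self.unbinned_fraction:
            raise FixtureError("unbinned_fraction must be >= 0")
        for b in self.bins:
            got = _expected_category(b, self.thresholds)
            if got is not b.target_category:
                raise FixtureError(
                    f"bin {b.bin_id!r}: requested scores classify as "
                    f"{got.label!r}, not target {b.target_category.label!r}"
                )


def _expected_category(
    b: FixtureBinSpec, thresholds: ClassificationThresholds
) -> Category:
    aa = frozenset(sorted(STANDARD_AMINO_ACIDS)[: b.trna_aa_count])
    cen = RnaCensus(aa, b.rrna_5s, b.rrna_16s, b.rrna_23s)
    q = QualityEstimate(b.bin_id, b.completeness, b.contamination, "fixture")
    return classify(q, cen, thresholds).category


def random_bin_spec(
    rng: random.Random, bin_id: str, target: Category
) -> FixtureBinSpec:
    """Draw a bin spec consistent with ``target`` under default thresholds."""
    r2 = lambda lo, hi: round(rng.uniform(lo, hi), 2)
    if target is Category.HIGH:
        comp, cont = r2(90.01, 99.99), r2(0.0, 5.0)
        trna, rrna = rng.randint(18, 20), (True, True, True)
    elif target is Category.NEAR_COMPLETE:
        comp, cont = r2(90.01, 99.99), r2(0.0, 5.0)
        if rng.random() < 0.5:  # short of high on tRNAs
            trna, rrna = rng.randint(0, 17), (True, True, True)
        else:  # short of high on an rRNA gene
            trna = rng.randint(0, 20)
            rrna = [True, True, True]
            rrna[rng.randrange(3)] = False
            rrna = tuple(rrna)
    elif target is Category.MEDIUM:
        comp, cont = r2(50.0, 90.0), r2(0.0, 10.0)
        trna = rng.randint(0, 20)
        rrna = tuple(rng.random() < 0.5 for _ in range(3))
    elif target is Category.LOW:
        comp, cont = r2(0.0, 49.9), r2(0.0, 10.0)
        trna = rng.randint(0, 10)
        rrna = (False, False, False)
    else:  # Failed: contamination above the medium bound
        comp, cont = r2(0.0, 100.0), r2(10.01, 60.0)
        trna = rng.randint(0, 20)
        rrna = tuple(rng.random() < 0.5 for _ in range(3))
    return FixtureBinSpec(
        bin_id=bin_id,
        target_category=target,
        completeness=comp,
        contamination=cont,
        trna_aa_count=trna,
        rrna_5s=rrna[0],
        rrna_16s=rrna[1],
        rrna_23s=rrna[2],
        n_contigs=rng.randint(1, 6),
        min_contig_bp=rng.randint(300, 600),
        max_contig_bp=rng.randint(1000, 4000),
    )


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _write_fasta(path: Path, records: Sequence[tuple[str, str]]) -> None:
    with path.open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Materialise a spec on disk; returns (and writes) the manifest.

    Layout: ``bins/<bin_id>.fa``, ``assembly.fa``, ``quality.tsv``,
    ``annotations/<bin_id>.tsv`` and ``manifest.json``. Identical specs and
    seeds produce byte-identical files.
    """
    rng = random.Random(spec.seed)
    out = Path(out_dir)
    (out / "bins").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)

    assembly_records: list[tuple[str, str]] = []
    quality_lines = [
        "Bin Id\tMarker lineage\tCompleteness\tContamination\tStrain heterogeneity"
    ]
    manifest_bins = []
    amino_order = sorted(STANDARD_AMINO_ACIDS)
    total_bin_contigs = 0
    for b in spec.bins:
        contigs = []
        for i in range(b.n_contigs):
            length = rng.randint(b.min_contig_bp, b.max_contig_bp)
            contigs.append((f"{b.bin_id}_c{i + 1}", _random_seq(rng, length)))
        total_bin_contigs += len(contigs)
        _write_fasta(out / "bins" / f"{b.bin_id}.fa", contigs)
        assembly_records.extend(contigs)
        quality_lines.append(
            f"{b.bin_id}\troot (UID1)\t{b.completeness}\t{b.contamination}\t0.0"
        )
        ann_lines = [
            "#Annotated with magqc fixture generator",
            "#Sequence Id\tType\tStart\tStop\tStrand\tLocus Tag\tGene\tProduct",
        ]
        host = contigs[0][0]
        pos = 1
        for aa in rng.sample(amino_order, b.trna_aa_count):
            ann_lines.append(
                f"{host}\ttRNA\t{pos}\t{pos + 74}\t+\t\ttrn{aa[0]}\ttRNA-{aa}"
            )
            pos += 80
        for flag, subunit in (
            (b.rrna_5s, "5S"),
            (b.rrna_16s, "16S"),
            (b.rrna_23s, "23S"),
        ):
            if flag:
                length = RRNA_REFERENCE_LENGTHS[subunit]
                ann_lines.append(
                    f"{host}\trRNA\t{pos}\t{pos + length - 1}\t+\t\t\t"
                    f"{subunit} ribosomal RNA"
                )
                pos += length + 10
        (out / "annotations" / f"{b.bin_id}.tsv").write_text(
            "\n".join(ann_lines) + "\n"
        )
        manifest_bins.append(
            {
                "bin_id": b.bin_id,
                "target_category": b.target_category.label,
                "completeness": b.completeness,
                "contamination": b.contamination,
                "trna_aa_count": b.trna_aa_count,
                "rrna": [b.rrna_5s, b.rrna_16s, b.rrna_23s],
                "n_contigs": b.n_contigs,
            }
        )

    n_unbinned = round(total_bin_contigs * spec.unbinned_fraction)
    for i in range(n_unbinned):
        length = rng.randint(300, 2000)
        assembly_records.append((f"unbinned_c{i + 1}", _random_seq(rng, length)))
    _write_fasta(out / "assembly.fa", assembly_records)
    (out / "quality.tsv").write_text("\n".join(quality_lines) + "\n")

    manifest = {
        "seed": spec.seed,
        "unbinned_fraction": spec.unbinned_fraction,
        "n_unbinned_contigs": n_unbinned,
        "bins": manifest_bins,
        "paths": {
            "bins_dir": "bins",
            "assembly": "assembly.fa",
            "quality_table": "quality.tsv",
            "annotations_dir": "annotations",
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def demo_spec(seed: int = 0) -> FixtureSpec:
    """Five bins, one per quality category — the smallest complete dataset."""
    rng = random.Random(seed)
    bins = tuple(
        random_bin_spec(rng, f"bin_{cat.dirname}", cat)
        for cat in Category
    )
    return FixtureSpec(bins=bins, seed=seed)
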