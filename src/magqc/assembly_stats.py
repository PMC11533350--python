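"""Per-bin assembly statistics and run-level binning totals.

N50 follows the usual convention: the largest observed contig length L such
that contigs of length >= L together cover at least half the total size.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats_io import BinRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContigStats:
    size_bp: int
    n50_bp: int
    max_contig_bp: int
    n_contigs: int


@dataclass(frozen=True)
class BinnedSummary:
    """How much of the source assembly the bins capture.

    Overlapping bins double-count shared contigs (competing binners may
    legitimately place one contig in several bins); overlaps and bin contigs
    missing from the assembly are recorded in ``warnings``, never raised.
    """

    bases_binned: int
    contigs_binned: int
    assembly_bases: int
    assembly_contigs: int
    fraction_bases: float
    fraction_contigs: float
    warnings: tuple[str, ...] = ()


def contig_stats(lengths: Sequence[int]) -> ContigStats:
    """Compute size, N50, longest contig and contig count from lengths (bp)."""
    if not lengths:
        raise ValueError("contig_stats requires a non-empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    half = total / 2
    cumulative = 0
    n50 = ordered[-1]
    for l in ordered:
        cumulative += l
        if cumulative >= half:
            n50 = l
            break
    return ContigStats(
        size_bp=total,
        n50_bp=n50,
        max_contig_bp=ordered[0],
        n_contigs=len(ordered),
    )


def binned_summary(
    assembly: BinRecord, bins: Iterable[BinRecord]
) -> BinnedSummary:
    """Total bases/contigs binned across ``bins``, as fractions of the
    assembly totals."""
    warnings: list[str] = []
    bases = 0
    contigs = 0
    seen: Counter[str] = Counter()
    for b in bins:
        for contig, length in b.contig_lengths.items():
            bases += length
            contigs += 1
            seen[contig] += 1
            if contig not in assembly.contig_lengths:
                warnings.append(
                    f"bin {b.bin_id!r}: contig {contig!r} absent from assembly"
                )
    overlaps = {c: n for c, n in seen.items() if n > 1}
    if overlaps:
        warnings.append(
            f"{len(overlaps)} contig(s) shared between bins "
            "(double-counted in totals)"
        )
    for w in warnings:
        log.warning(w)
    asm_bases = assembly.total_bp
    asm_contigs = assembly.n_contigs
    return BinnedSummary(
        bases_binned=bases,
        contigs_binned=contigs,
        assembly_bases=asm_bases,
        assembly_contigs=asm_contigs,
        fraction_bases=bases / asm_bases if asm_bases else 0.0,
        fraction_contigs=contigs / asm_contigs if asm_contigs else 0.0,
        warnings=tuple(warnings),
    )
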