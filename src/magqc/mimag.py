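"""MIMAG quality classification of metagenome bins.

Each bin is assigned exactly one of five categories from its completeness,
contamination and RNA census. Rules are evaluated in a strict order and the
first match wins:

1. High quality    — completeness > 90, contamination <= 5, tRNAs for >= 18
                     of the 20 standard amino acids, and 5S+16S+23S rRNA.
2. Near complete   — completeness > 90 and contamination <= 5 (the RNA
                     complement falls short of high quality).
3. Medium quality  — completeness >= 50 and contamination <= 10.
4. Low quality     — completeness < 50 and contamination <= 10.
5. Failed          — anything else (contamination above 10).

The medium/failed bounds overlap at contamination exactly 10%; first-match
ordering resolves it in favour of medium (every printed inclusive bound is
preserved, only the ambiguous point is adjudicated). Completeness and
contamination are compared exactly as parsed, with no rounding.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .formats_io import BinRecord, QualityEstimate
from .rna_census import RnaCensus

log = logging.getLogger(__name__)


class Category(enum.Enum):
    """The five quality tiers, ordered worst to best."""

    FAILED = ("Failed", "failed", 0)
    LOW = ("Low quality", "low_quality", 1)
    MEDIUM = ("Medium quality", "medium_quality", 2)
    NEAR_COMPLETE = ("Near complete", "near_complete", 3)
    HIGH = ("High quality", "high_quality", 4)

    def __init__(self, label: str, dirname: str, rank: int) -> None:
        self.label = label
        self.dirname = dirname
        self.rank = rank

    @classmethod
    def from_label(cls, label: str) -> "Category":
        for cat in cls:
            if cat.label == label:
                return cat
        raise ValueError(f"unknown quality label {label!r}")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Tunable classification bounds; defaults are the MIMAG standard plus
    the near-complete extension.

    ``hq_completeness`` is an exclusive lower bound (a bin must *exceed* it);
    the contamination and medium-completeness bounds are inclusive.
    """

    hq_completeness: float = 90.0
    hq_contamination: float = 5.0
    hq_min_trna: int = 18
    mq_completeness: float = 50.0
    mq_contamination: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.mq_completeness <= self.hq_completeness <= 100:
            raise ValueError(
                "require 0 <= mq_completeness <= hq_completeness <= 100"
            )
        if self.hq_contamination > self.mq_contamination:
            raise ValueError("require hq_contamination <= mq_contamination")


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass(frozen=True)
class RuleCheck:
    rule: str
    passed: bool


@dataclass(frozen=True)
class Classification:
    bin_id: str
    category: Category
    trace: tuple[RuleCheck, ...]

    def __post_init__(self) -> None:
        if not self.trace:
            raise ValueError("trace must be non-empty")


def classify(
    quality: QualityEstimate,
    census: RnaCensus,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> Classification:
    """Assign one quality category; total on every valid input."""
    t = thresholds
    comp, cont = quality.completeness, quality.contamination
    nc_eligible = comp > t.hq_completeness and cont <= t.hq_contamination
    rules: list[tuple[str, Category, bool]] = [
        (
            f"high: completeness > {t.hq_completeness} and contamination <= "
            f"{t.hq_contamination} and tRNA aa >= {t.hq_min_trna} and "
            "5S+16S+23S rRNA",
            Category.HIGH,
            nc_eligible
            and census.trna_count >= t.hq_min_trna
            and census.all_rrna,
        ),
        (
            f"near-complete: completeness > {t.hq_completeness} and "
            f"contamination <= {t.hq_contamination}",
            Category.NEAR_COMPLETE,
            nc_eligible,
        ),
        (
            f"medium: completeness >= {t.mq_completeness} and contamination "
            f"<= {t.mq_contamination}",
            Category.MEDIUM,
            comp >= t.mq_completeness and cont <= t.mq_contamination,
        ),
        (
            f"low: completeness < {t.mq_completeness} and contamination <= "
            f"{t.mq_contamination}",
            Category.LOW,
            comp < t.mq_completeness and cont <= t.mq_contamination,
        ),
        (
            f"failed: contamination > {t.mq_contamination}",
            Category.FAILED,
            True,
        ),
    ]
    trace: list[RuleCheck] = []
    for rule, category, passed in rules:
        trace.append(RuleCheck(rule, passed))
        if passed:
            return Classification(quality.bin_id, category, tuple(trace))
    raise AssertionError("unreachable: the failed rule always matches")


def classify_all(
    qualities: Mapping[str, QualityEstimate],
    censuses: Mapping[str, RnaCensus],
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    bins: Iterable[BinRecord] | None = None,
) -> list[Classification]:
    """Classify every bin with a quality estimate, sorted by bin id.

    A bin lacking a census is classified against an empty census (with a
    logged warning) — such bins top out at near-complete. If ``bins`` is
    given, any bin absent from ``qualities`` is a hard error listing the
    offenders.
    """
    if bins is not None:
        missing = sorted(b.bin_id for b in bins if b.bin_id not in qualities)
        if missing:
            raise KeyError(
                f"bins without a quality-table entry: {missing}"
            )
    out: list[Classification] = []
    for bin_id in sorted(qualities):
        cen = censuses.get(bin_id)
        if cen is None:
            log.warning(
                "bin %r has no annotation census; using an empty census",
                bin_id,
            )
            cen = RnaCensus.empty()
        out.append(classify(qualities[bin_id], cen, thresholds))
    return out
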