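"""Reduce a bin's annotation to the RNA evidence the MIMAG high-quality
criterion needs: how many of the 20 standard amino acids have at least one
annotated tRNA, and whether the 5S/16S/23S rRNA genes are present.

tRNA coverage counts distinct standard amino acids, not tRNA genes:
duplicates collapse, the initiator fMet counts as Met, and the
non-standard/undetermined isotypes (Sec, Pyl, Xxx) fall outside the
20-amino-acid denominator.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable

from .formats_io import AnnotationFeature, FeatureType

log = logging.getLogger(__name__)

STANDARD_AMINO_ACIDS = frozenset(
    {
        "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    }
)

#: Isotypes excluded from the 20-amino-acid universe.
_EXCLUDED_ISOTYPES = {"sec", "sec)", "pyl", "xxx"}

#: Approximate full-length prokaryotic rRNA gene sizes (bp), used only when a
#: minimum-length fraction is requested.
RRNA_REFERENCE_LENGTHS = {"5S": 120, "16S": 1500, "23S": 2900}

#: Conventional rRNA gene names, used as fallback when the product string
#: does not name the subunit.
_GENE_TO_SUBUNIT = {"rrf": "5S", "rrs": "16S", "rrl": "23S"}

_TRNA_PRODUCT_RE = re.compile(r"tRNA[-_ ]\(?([A-Za-z]{3,4})\)?", re.IGNORECASE)
_RRNA_SUBUNIT_RE = re.compile(r"\b(5S|16S|23S)\b", re.IGNORECASE)


@dataclass(frozen=True)
class RnaCensus:
    """tRNA amino-acid coverage and 5S/16S/23S presence for one bin."""

    trna_amino_acids: frozenset[str]
    rrna_5s: bool
    rrna_16s: bool
    rrna_23s: bool

    def __post_init__(self) -> None:
        unknown = self.trna_amino_acids - STANDARD_AMINO_ACIDS
        if unknown:
            raise ValueError(f"non-standard amino acids in census: {unknown}")

    @property
    def trna_count(self) -> int:
        return len(self.trna_amino_acids)

    @property
    def all_rrna(self) -> bool:
        return self.rrna_5s and self.rrna_16s and self.rrna_23s

    @classmethod
    def empty(cls) -> "RnaCensus":
        return cls(frozenset(), False, False, False)


def _amino_acid_from_product(product: str) -> str | None:
    """Extract a standard amino-acid three-letter code from a tRNA product
    string, or None when the product names no standard amino acid."""
    m = _TRNA_PRODUCT_RE.search(product)
    if not m:
        return None
    token = m.group(1).lower()
    if token == "fmet":  # initiator tRNA charges methionine
        return "Met"
    if token in _EXCLUDED_ISOTYPES:
        return None
    code = token.capitalize()
    return code if code in STANDARD_AMINO_ACIDS else None


def trna_coverage(features: Iterable[AnnotationFeature]) -> frozenset[str]:
    """Set of standard amino acids with >=1 non-pseudo annotated tRNA."""
    covered: set[str] = set()
    for f in features:
        if f.feature_type is not FeatureType.TRNA or f.pseudo:
            continue
        aa = _amino_acid_from_product(f.product)
        if aa is None:
            log.warning(
                "skipping tRNA feature on %s with unrecognised product %r",
                f.contig_id, f.product,
            )
            continue
        covered.add(aa)
    return frozenset(covered)


def rrna_presence(
    features: Iterable[AnnotationFeature], min_len_fraction: float = 0.0
) -> tuple[bool, bool, bool]:
    """Presence flags for (5S, 16S, 23S) rRNA genes.

    A subunit counts as present when a non-pseudo rRNA feature names it in
    its product (or carries the conventional gene name rrf/rrs/rrl) and, if
    ``min_len_fraction`` > 0, the feature spans at least that fraction of the
    subunit's reference length. The default 0 disables the length filter, i.e.
    presence only.
    """
    flags = {"5S": False, "16S": False, "23S": False}
    for f in features:
        if f.feature_type is not FeatureType.RRNA or f.pseudo:
            continue
        m = _RRNA_SUBUNIT_RE.search(f.product)
        subunit = m.group(1).upper() if m else None
        if subunit is None and f.gene:
            subunit = _GENE_TO_SUBUNIT.get(f.gene.strip().lower()[:3])
        if subunit is None:
            log.warning(
                "skipping rRNA feature on %s with unrecognised product %r",
                f.contig_id, f.product,
            )
            continue
        if f.length >= min_len_fraction * RRNA_REFERENCE_LENGTHS[subunit]:
            flags[subunit] = True
    return flags["5S"], flags["16S"], flags["23S"]


def census(
    features: Iterable[AnnotationFeature], min_len_fraction: float = 0.0
) -> RnaCensus:
    """Full RNA census of a feature list."""
    features = list(features)
    r5, r16, r23 = rrna_presence(features, min_len_fraction)
    return RnaCensus(
        trna_amino_acids=trna_coverage(features),
        rrna_5s=r5,
        rrna_16s=r16,
        rrna_23s=r23,
    )
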