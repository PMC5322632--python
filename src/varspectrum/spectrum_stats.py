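"""Allele frequencies and the three variant-spectrum statistics.

A resequenced case cohort is compared with a genotyped control population by
summarising, per gene and over the whole panel, (1) the number of rare sites
(folded minor-allele frequency at or below a threshold, 1% by default),
(2) the number of population-specific sites (alternate allele observed in one
population, absent in the other), and (3) the number of sites whose alternate
allele is concordantly called damaging by SIFT and PolyPhen-2.

Frequency threshold comparisons are carried out on exact rationals so the
"MAF <= 1%" boundary is deterministic: 5/576 is rare, 6/576 is not, with no
floating-point edge cases.  A site must be *present* (alt count >= 1) to be
counted rare — an unobserved allele has MAF 0 but is not a detected variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Union

from .variant_model import (
    CohortCounts,
    UndefinedFrequencyError,
    VariantSite,
)

STAT_KINDS = ("rare_count", "case_specific_count", "damaging_count")

Scope = Union[str, Sequence[str], None]


@dataclass(frozen=True)
class SpectrumStatistic:
    """One spectrum summary: statistic kind, gene scope, integer value."""

    kind: str
    scope: str
    value: int

    def __post_init__(self) -> None:
        if self.kind not in STAT_KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("statistic value must be >= 0")


def alt_frequency(alt_count: int, chrom_count: int) -> float:
    """Alternate-allele frequency, same referent allele for all populations."""
    if chrom_count <= 0:
        raise UndefinedFrequencyError(
            f"frequency undefined for chrom_count={chrom_count}")
    if not 0 <= alt_count <= chrom_count:
        raise ValueError(f"alt_count {alt_count} outside [0, {chrom_count}]")
    return alt_count / chrom_count


def maf(alt_count: int, chrom_count: int) -> float:
    """Folded minor-allele frequency min(f, 1-f), in [0, 0.5]."""
    f = alt_frequency(alt_count, chrom_count)
    return min(f, 1.0 - f)


def is_present(alt_count: int) -> bool:
    """A variant is detected in a cohort when it carries >= 1 alternate copy."""
    return alt_count >= 1


def threshold_fraction(threshold: Union[float, str, Fraction]) -> Fraction:
    """Exact rational form of a frequency threshold (0.01 -> 1/100)."""
    if isinstance(threshold, Fraction):
        frac = threshold
    else:
        frac = Fraction(str(threshold))
    if not 0 < frac <= Fraction(1, 2):
        raise ValueError(f"threshold {threshold} outside (0, 0.5]")
    return frac


def is_rare(alt_count: int, chrom_count: int,
            threshold: Union[float, Fraction] = 0.01) -> bool:
    """Present with folded MAF <= threshold (inclusive), compared exactly."""
    if not is_present(alt_count):
        return False
    thr = threshold_fraction(threshold)
    folded = min(alt_count, chrom_count - alt_count)
    return Fraction(folded, chrom_count) <= thr


# ---------------------------------------------------------------------------
# scope handling
# ---------------------------------------------------------------------------

def scope_label(scope: Scope) -> str:
    if scope is None or scope == "ALL":
        return "ALL"
    if isinstance(scope, str):
        return scope
    return "+".join(scope)


def sites_in_scope(sites: Iterable[VariantSite], scope: Scope) -> list[VariantSite]:
    """Subset of sites belonging to a gene, a list of genes, or all ("ALL")."""
    if scope is None or scope == "ALL":
        return list(sites)
    wanted = {scope} if isinstance(scope, str) else set(scope)
    return [s for s in sites if s.gene in wanted]


# ---------------------------------------------------------------------------
# the three statistics
# ---------------------------------------------------------------------------

def stat_rare_count(cohort: CohortCounts, sites: Sequence[VariantSite],
                    scope: Scope = None,
                    threshold: Union[float, Fraction] = 0.01) -> SpectrumStatistic:
    """Number of sites in scope present and rare (MAF <= threshold) in a cohort."""
    value = sum(
        1 for s in sites_in_scope(sites, scope)
        if is_rare(cohort.alt_count(s.key), cohort.chrom_count(s.key), threshold))
    return SpectrumStatistic("rare_count", scope_label(scope), value)


def stat_case_specific(case: CohortCounts, control: CohortCounts,
                       sites: Sequence[VariantSite],
                       scope: Scope = None) -> SpectrumStatistic:
    """Number of sites carried by the case cohort and absent from the control."""
    value = sum(
        1 for s in sites_in_scope(sites, scope)
        if is_present(case.alt_count(s.key)) and control.alt_count(s.key) == 0)
    return SpectrumStatistic("case_specific_count", scope_label(scope), value)


def stat_damaging_count(cohort: CohortCounts, sites: Sequence[VariantSite],
                        scope: Scope = None,
                        mode: str = "concordant") -> SpectrumStatistic:
    """Damaging-variant burden among sites present in a cohort.

    ``concordant`` (default) counts sites called damaging by both SIFT and
    PolyPhen-2; sites with a missing call on either predictor cannot be
    concordantly damaging and are effectively excluded.  ``score_sum`` sums,
    over present sites, the number of predictors (0-2) calling the site
    damaging — a coarser dosage of the same evidence.
    """
    value = 0
    for s in sites_in_scope(sites, scope):
        if not is_present(cohort.alt_count(s.key)):
            continue
        if mode == "concordant":
            value += int(s.concordant_damaging)
        elif mode == "score_sum":
            value += int(s.sift_call == "damaging") + int(s.polyphen_call == "damaging")
        else:
            raise ValueError(f"unknown damaging mode {mode!r}")
    return SpectrumStatistic("damaging_count", scope_label(scope), value)


def rare_count_contrast(case: CohortCounts, control: CohortCounts,
                        sites: Sequence[VariantSite], scope: Scope = None,
                        threshold: Union[float, Fraction] = 0.01) -> int:
    """Case-minus-control difference in rare-site counts over a scope.

    The case-side count is the default test statistic; the contrast is the
    alternative reading (both orderings of the permutation null coincide for
    the case-side count because per-site totals are conserved, but not for
    the contrast, so both are exposed).
    """
    return (stat_rare_count(case, sites, scope, threshold).value
            - stat_rare_count(control, sites, scope, threshold).value)


def damaging_site_mask(sites: Sequence[VariantSite]) -> list[bool]:
    """Concordant-damaging flags in site order (for vectorised tests)."""
    return [s.concordant_damaging for s in sites]
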