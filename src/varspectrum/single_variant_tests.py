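"""Single-SNP layer: two-proportion association tests and HWE screening.

Common variants (MAF >= 5% in at least one cohort by default) are tested one
at a time for an allele-frequency difference between the case and control
cohorts with the two-proportion normal-approximation (pooled) z-test,
two-sided.  Genotype-level data are additionally screened for departure from
Hardy-Weinberg equilibrium with a 1-df chi-square test (an exact conditional
test is available for small or borderline counts); for X-linked sites only
female genotypes are diploid and only they enter the HWE test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .variant_model import (
    CohortCounts,
    GenePanel,
    GenotypeCounts,
    VariantSite,
)
from .spectrum_stats import maf, threshold_fraction

from fractions import Fraction


@dataclass(frozen=True)
class SnpTestResult:
    """Per-site two-proportion test outcome."""

    key: tuple
    case_freq: float
    ctrl_freq: float
    z: float
    p_value: float
    eligible: bool
    degenerate: bool = False

    @property
    def freq_diff(self) -> float:
        return self.case_freq - self.ctrl_freq


@dataclass(frozen=True)
class HweResult:
    """Per-site Hardy-Weinberg screen outcome."""

    key: tuple
    hom_ref: int
    het: int
    hom_alt: int
    chi_square: float
    p_value: float
    tested: bool
    method: str = "chisq"


def two_proportion_test(case_alt: int, case_n: int, ctrl_alt: int, ctrl_n: int,
                        *, continuity: bool = False,
                        key: tuple = (), eligible: bool = True) -> SnpTestResult:
    """Two-sided pooled two-proportion z-test on allele counts.

    z = (f1 - f2) / sqrt(pbar (1 - pbar) (1/n1 + 1/n2)) with pbar the pooled
    alternate-allele proportion.  ``continuity`` applies the Yates-style
    correction of half a count per cohort to |f1 - f2|.  A pooled proportion
    of exactly 0 or 1 leaves z undefined: the result is flagged degenerate
    with z = 0 and P = 1.
    """
    if case_n <= 0 or ctrl_n <= 0:
        raise ValueError("cohort chromosome counts must be positive")
    if not (0 <= case_alt <= case_n and 0 <= ctrl_alt <= ctrl_n):
        raise ValueError("allele counts outside [0, chrom_count]")
    f1, f2 = case_alt / case_n, ctrl_alt / ctrl_n
    pbar = (case_alt + ctrl_alt) / (case_n + ctrl_n)
    if pbar in (0.0, 1.0):
        return SnpTestResult(key, f1, f2, 0.0, 1.0, eligible, degenerate=True)
    se = math.sqrt(pbar * (1.0 - pbar) * (1.0 / case_n + 1.0 / ctrl_n))
    diff = f1 - f2
    if continuity:
        cc = 0.5 * (1.0 / case_n + 1.0 / ctrl_n)
        diff = math.copysign(max(abs(diff) - cc, 0.0), diff)
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    return SnpTestResult(key, f1, f2, z, max(p, np.finfo(float).tiny), eligible)


def hwe_chisq(hom_ref: int, het: int, hom_alt: int, *, key: tuple = ()) -> HweResult:
    """1-df chi-square goodness of fit to p^2 : 2pq : q^2 expectations.

    Allele frequencies are estimated from the genotypes themselves (one
    estimated parameter; 3 classes - 1 - 1 = 1 df).  Monomorphic sites carry
    no information and are returned untested.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("negative genotype counts")
    n = hom_ref + het + hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * hom_ref + het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return HweResult(key, hom_ref, het, hom_alt, 0.0, 1.0, tested=False)
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([hom_ref, het, hom_alt], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(key, hom_ref, het, hom_alt, chi2,
                     float(stats.chi2.sf(chi2, df=1)), tested=True)


def hwe_exact(hom_ref: int, het: int, hom_alt: int, *, key: tuple = ()) -> HweResult:
    """Exact conditional HWE test (sum of probabilities <= observed).

    Enumerates the distribution of the heterozygote count conditional on the
    minor-allele count; the P-value sums the probabilities of all outcomes no
    more likely than the observed one.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("negative genotype counts")
    n = hom_ref + het + hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_alt = 2 * hom_alt + het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return HweResult(key, hom_ref, het, hom_alt, 0.0, 1.0, tested=False,
                         method="exact")
    het_obs = het

    def log_prob(h: int) -> float:
        # P(het = h | n, n_minor) under HWE, Levene/Haldane conditional form
        n_major = 2 * n - n_minor
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        return (h * math.log(2) + gammaln(n + 1)
                - gammaln(hom_min + 1) - gammaln(h + 1) - gammaln(hom_maj + 1)
                + gammaln(n_minor + 1) + gammaln(n_major + 1)
                - gammaln(2 * n + 1))

    hs = [h for h in range(n_minor % 2, n_minor + 1, 2) if n - h - (n_minor - h) // 2 >= 0]
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(het_obs)]
    p_value = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    chi = hwe_chisq(hom_ref, het, hom_alt).chi_square
    return HweResult(key, hom_ref, het, hom_alt, chi, min(p_value, 1.0),
                     tested=True, method="exact")


def eligibility_filter(sites: Sequence[VariantSite], case: CohortCounts,
                       control: CohortCounts,
                       threshold: Union[float, Fraction] = 0.05, *,
                       panel: Optional[GenePanel] = None) -> list[VariantSite]:
    """Sites where at least one cohort reaches MAF >= threshold (inclusive)."""
    thr = threshold_fraction(threshold)
    out = []
    for s in sites:
        xl = panel.x_linked(s.gene) if panel is not None else False
        mafs = []
        for cohort in (case, control):
            an = cohort.chrom_count(s.key, xl)
            if an > 0:
                ac = cohort.alt_count(s.key)
                mafs.append(Fraction(min(ac, an - ac), an))
        if mafs and max(mafs) >= thr:
            out.append(s)
    return out


def snp_association_scan(sites: Sequence[VariantSite], case: CohortCounts,
                         control: CohortCounts,
                         threshold: Union[float, Fraction] = 0.05, *,
                         panel: Optional[GenePanel] = None,
                         continuity: bool = False) -> list[SnpTestResult]:
    """Two-proportion test for every eligible (common) site."""
    results = []
    for s in eligibility_filter(sites, case, control, threshold, panel=panel):
        xl = panel.x_linked(s.gene) if panel is not None else False
        results.append(two_proportion_test(
            case.alt_count(s.key), case.chrom_count(s.key, xl),
            control.alt_count(s.key), control.chrom_count(s.key, xl),
            continuity=continuity, key=s.key))
    return results


def hwe_scan(sites: Sequence[VariantSite], cohort: CohortCounts,
             maf_threshold: Union[float, Fraction] = 0.05, *,
             panel: Optional[GenePanel] = None,
             exact: bool = False) -> list[HweResult]:
    """HWE screen over common genotype-level sites of one cohort.

    Only sites with genotype counts and cohort MAF >= threshold are tested;
    X-linked sites use the diploid (female) genotypes only, which the
    genotype containers already separate from hemizygous males.
    """
    thr = threshold_fraction(maf_threshold)
    test = hwe_exact if exact else hwe_chisq
    results = []
    for s in sites:
        gt: Optional[GenotypeCounts] = cohort.genotypes(s.key)
        if gt is None:
            continue
        xl = panel.x_linked(s.gene) if panel is not None else False
        an = cohort.chrom_count(s.key, xl)
        if an == 0 or Fraction(min(cohort.alt_count(s.key), an - cohort.alt_count(s.key)),
                               an) < thr:
            continue
        results.append(test(gt.hom_ref, gt.het, gt.hom_alt, key=s.key))
    return results
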