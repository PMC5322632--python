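"""One-sided per-site allele-randomization permutation test.

The null hypothesis is that case and control chromosomes are exchangeable at
every variable site.  Each replicate pools, site by site, the alternate
alleles of both cohorts and deals them back to case/control chromosome sets
of the original sizes (a hypergeometric draw per site, independently across
sites — linkage between sites is deliberately ignored).  The spectrum
statistic under test (rare, case-specific, or concordant-damaging count) is
recomputed on every permuted case cohort, with rarity/specificity judged from
the permuted counts, and the one-sided P-value is the proportion of
replicates whose permuted statistic exceeds the observed one.

Two tie-handling modes are exposed.  ``strict`` counts only replicates whose
permuted value is strictly greater than the observed (P = n_exceeding /
n_perm, the classical resequencing-study definition); ``ge`` counts ties and
applies the add-one correction P = (n_ge + 1) / (n_perm + 1), which can never
report zero and is the conservative choice for small panels.  Both counts are
carried in every result.

A scope in which no site can vary under permutation (empty scope, or every
site fixed for one allele in the pooled cohorts) yields a degenerate,
uninformative test: the result is flagged and reported with P = 1.

Randomness: per-scope substreams are derived from the master seed and a CRC
of the scope label, so each gene's result is independent of the order in
which genes are analysed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np

from .variant_model import CohortCounts, GenePanel, VariantSite
from .spectrum_stats import (
    Scope,
    STAT_KINDS,
    damaging_site_mask,
    scope_label,
    sites_in_scope,
    threshold_fraction,
)

DEFAULT_N_PERM = 100_000


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic and its Monte-Carlo permutation null summary."""

    kind: str
    scope: str
    observed: int
    n_perm: int
    n_exceeding: int          # permuted value strictly > observed
    n_exceeding_or_equal: int  # permuted value >= observed
    seed: int
    strict: bool
    degenerate: bool = False

    @property
    def p_strict(self) -> float:
        if self.degenerate:
            return 1.0
        return self.n_exceeding / self.n_perm

    @property
    def p_ge(self) -> float:
        """Add-one corrected P counting ties; never exactly zero."""
        if self.degenerate:
            return 1.0
        return (self.n_exceeding_or_equal + 1) / (self.n_perm + 1)

    @property
    def p_value(self) -> float:
        return self.p_strict if self.strict else self.p_ge


def scope_rng(seed: int, label: str) -> np.random.Generator:
    """Seedable per-scope generator, independent of analysis order."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


def permute_site(case_alt: int, case_n: int, ctrl_alt: int, ctrl_n: int,
                 rng: np.random.Generator) -> tuple[int, int]:
    """Randomize one site's pooled alleles over the two chromosome sets.

    The permuted case count is hypergeometric: ``case_n`` chromosomes drawn
    without replacement from the ``case_n + ctrl_n`` pooled chromosomes of
    which ``case_alt + ctrl_alt`` carry the alternate allele.  Per-site
    totals are conserved exactly.
    """
    total_alt = case_alt + ctrl_alt
    total_n = case_n + ctrl_n
    if not (0 <= case_alt <= case_n and 0 <= ctrl_alt <= ctrl_n):
        raise ValueError("invalid allele counts")
    new_case = int(rng.hypergeometric(total_alt, total_n - total_alt, case_n)) \
        if total_n > 0 and case_n > 0 else 0
    return new_case, total_alt - new_case


# ---------------------------------------------------------------------------
# vectorised internals
# ---------------------------------------------------------------------------

@dataclass
class _ScopeArrays:
    case_alt: np.ndarray   # (S,)
    case_n: np.ndarray
    ctrl_alt: np.ndarray
    ctrl_n: np.ndarray
    damaging: np.ndarray   # (S,) bool

    @property
    def total_alt(self) -> np.ndarray:
        return self.case_alt + self.ctrl_alt

    @property
    def variable(self) -> np.ndarray:
        """Sites whose pooled allele split can change under permutation."""
        total = self.case_n + self.ctrl_n
        return (self.total_alt > 0) & (self.total_alt < total) \
            & (self.case_n > 0) & (self.ctrl_n > 0)


def build_scope_arrays(case: CohortCounts, control: CohortCounts,
                       sites: Sequence[VariantSite], scope: Scope = None,
                       panel: Optional[GenePanel] = None) -> _ScopeArrays:
    sub = sites_in_scope(sites, scope)
    xl = {s.gene: (panel.x_linked(s.gene) if panel is not None else False) for s in sub}
    return _ScopeArrays(
        case_alt=np.array([case.alt_count(s.key) for s in sub], dtype=np.int64),
        case_n=np.array([case.chrom_count(s.key, xl[s.gene]) for s in sub], dtype=np.int64),
        ctrl_alt=np.array([control.alt_count(s.key) for s in sub], dtype=np.int64),
        ctrl_n=np.array([control.chrom_count(s.key, xl[s.gene]) for s in sub], dtype=np.int64),
        damaging=np.array(damaging_site_mask(sub), dtype=bool),
    )


def _case_statistic(case_alt: np.ndarray, arrays: _ScopeArrays, kind: str,
                    thr: Fraction, damaging_mode: str = "concordant") -> np.ndarray:
    """Statistic on (possibly permuted) case counts; last axis = sites.

    Rarity and specificity are recomputed from the supplied counts, so the
    same code path scores observed and permuted cohorts.  The MAF threshold
    is applied in integer arithmetic (q * min(a, n-a) <= p * n).
    """
    present = case_alt >= 1
    if kind == "rare_count":
        folded = np.minimum(case_alt, arrays.case_n - case_alt)
        rare = thr.denominator * folded <= thr.numerator * arrays.case_n
        return (present & rare).sum(axis=-1)
    if kind == "case_specific_count":
        ctrl_alt = arrays.total_alt - case_alt
        return (present & (ctrl_alt == 0)).sum(axis=-1)
    if kind == "damaging_count":
        if damaging_mode == "score_sum":
            raise NotImplementedError("score_sum permutation uses the concordant mask")
        return (present & arrays.damaging).sum(axis=-1)
    raise ValueError(f"unknown statistic kind {kind!r}; expected one of {STAT_KINDS}")


def permutation_test(case: CohortCounts, control: CohortCounts,
                     sites: Sequence[VariantSite], statistic_kind: str,
                     scope: Scope = None, *,
                     panel: Optional[GenePanel] = None,
                     n_perm: int = DEFAULT_N_PERM,
                     threshold: Union[float, Fraction] = 0.01,
                     strict: bool = True,
                     seed: int = 0,
                     batch: int = 20_000) -> PermutationResult:
    """Monte-Carlo permutation test of one spectrum statistic over a scope.

    Every replicate permutes every site independently (hypergeometric
    reallocation of the pooled alternate alleles) and recomputes the case
    statistic.  ``strict`` selects which P (strict or add-one ``ge``) the
    ``p_value`` property reports; both replicate counts are stored.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    label = scope_label(scope)
    arrays = build_scope_arrays(case, control, sites, scope, panel)
    thr = threshold_fraction(threshold)
    observed = int(_case_statistic(arrays.case_alt, arrays, statistic_kind, thr))

    if arrays.case_alt.size == 0 or not bool(arrays.variable.any()):
        return PermutationResult(statistic_kind, label, observed, n_perm,
                                 0, n_perm, seed, strict, degenerate=True)

    rng = scope_rng(seed, label)
    ngood = arrays.total_alt
    nbad = arrays.case_n + arrays.ctrl_n - ngood
    n_gt = n_ge = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm_case = rng.hypergeometric(ngood, nbad, arrays.case_n, size=(b, ngood.size))
        stats = _case_statistic(perm_case, arrays, statistic_kind, thr)
        n_gt += int((stats > observed).sum())
        n_ge += int((stats >= observed).sum())
        done += b
    return PermutationResult(statistic_kind, label, observed, n_perm,
                             n_gt, n_ge, seed, strict)


def global_test(case: CohortCounts, control: CohortCounts,
                sites: Sequence[VariantSite], statistic_kind: str,
                gene_list: Optional[Sequence[str]] = None, *,
                panel: Optional[GenePanel] = None,
                n_perm: int = DEFAULT_N_PERM,
                threshold: Union[float, Fraction] = 0.01,
                strict: bool = True, seed: int = 0) -> PermutationResult:
    """Panel-wide test: the statistic summed over all genes' sites.

    One joint permutation of every site per replicate, under the panel-wide
    ("ALL") substream; by additivity the observed value equals the sum of the
    per-gene observed values.
    """
    scope: Scope = "ALL" if gene_list is None else list(gene_list)
    result = permutation_test(case, control, sites, statistic_kind, scope,
                              panel=panel, n_perm=n_perm, threshold=threshold,
                              strict=strict, seed=seed)
    return result


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment min(1, m*p) with caller-supplied test count."""
    if m < 1:
        raise ValueError("m must be >= 1")
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out
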