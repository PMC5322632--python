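"""Rare-variant excess test against an aggregate (count-only) reference.

A large reference cohort such as an ExAC/gnomAD population extract provides
only per-site allele counts, so case/control chromosome permutation is not
available.  Instead, case-sized cohorts are repeatedly *simulated* from the
reference allele frequencies and the case rare-variant count is compared
with its simulated null distribution.

Sampling models: ``binomial`` (default) draws each site's simulated
alternate count from Binomial(n_chrom, AC/AN) — sampling with replacement
from an effectively infinite pool; ``hypergeometric`` samples n_chrom
chromosomes without replacement from the finite reference pool.  They agree
whenever the reference dwarfs the case cohort.

Sites carried by the cases but absent from the reference enter the
simulation with frequency zero: simulated cohorts can never reproduce them,
which is precisely what makes their observed presence evidence of an excess.

Rarity in each simulated cohort is judged, by default, from the simulated
cohort's own counts (``rarity="simulated"``) — symmetric with how the
observed statistic judges rarity within the case cohort.  The alternative
``rarity="reference"`` classifies sites once by reference MAF.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np

from .variant_model import (
    AggregateReference,
    CohortCounts,
    GenePanel,
    VariantSite,
)
from .spectrum_stats import (
    Scope,
    scope_label,
    sites_in_scope,
    stat_rare_count,
    threshold_fraction,
)

DEFAULT_N_SIM = 100_000


@dataclass(frozen=True)
class SimTestResult:
    """Observed case rare count and its simulated-reference null summary."""

    scope: str
    observed_rare: int
    n_sim: int
    n_exceeding: int           # simulated value strictly > observed
    n_exceeding_or_equal: int
    seed: int
    sampling_model: str
    rarity: str
    strict: bool
    degenerate: bool = False

    @property
    def p_strict(self) -> float:
        return self.n_exceeding / self.n_sim

    @property
    def p_ge(self) -> float:
        return (self.n_exceeding_or_equal + 1) / (self.n_sim + 1)

    @property
    def p_value(self) -> float:
        if self.degenerate:
            return 1.0
        return self.p_strict if self.strict else self.p_ge


def simulate_cohort_from_reference(reference: AggregateReference,
                                   sites: Sequence[VariantSite],
                                   n_chrom: int,
                                   rng: np.random.Generator,
                                   model: str = "binomial",
                                   population_label: str = "SIM") -> CohortCounts:
    """Draw one cohort of ``n_chrom`` chromosomes from reference frequencies.

    Reference sites with chrom_count 0 are skipped.  Returned counts use a
    uniform chrom_count of ``n_chrom`` at every site.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    from .variant_model import SiteCounts  # local import avoids cycle at module load

    cohort = CohortCounts(population_label, n_individuals=(n_chrom + 1) // 2)
    for s in sites:
        ac_an = reference.counts.get(s.key)
        if ac_an is None:
            ac, an = 0, 1
        else:
            ac, an = ac_an
            if an == 0:
                continue
        if model == "binomial":
            sim = int(rng.binomial(n_chrom, ac / an))
        elif model == "hypergeometric":
            if an < n_chrom:
                raise ValueError(
                    f"hypergeometric model needs reference AN >= n_chrom at {s.key}")
            sim = int(rng.hypergeometric(ac, an - ac, n_chrom))
        else:
            raise ValueError(f"unknown sampling model {model!r}")
        cohort.add(s.key, SiteCounts(sim, n_chrom))
    return cohort


def _reference_arrays(reference: AggregateReference, sub: Sequence[VariantSite]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ac, an) aligned with ``sub``; absent sites get (0, 1)."""
    ac = np.empty(len(sub), dtype=np.int64)
    an = np.empty(len(sub), dtype=np.int64)
    for i, s in enumerate(sub):
        pair = reference.counts.get(s.key, (0, 1))
        if pair[1] == 0:  # uncalled reference site: no information, freq 0
            pair = (0, 1)
        ac[i], an[i] = pair
    return ac, an


def sim_test_rare_excess(case: CohortCounts, reference: AggregateReference,
                         sites: Sequence[VariantSite], scope: Scope = None, *,
                         panel: Optional[GenePanel] = None,
                         n_sim: int = DEFAULT_N_SIM,
                         threshold: Union[float, Fraction] = 0.01,
                         model: str = "binomial",
                         rarity: str = "simulated",
                         strict: bool = True,
                         seed: int = 0,
                         batch: int = 20_000) -> SimTestResult:
    """One-sided test for a rare-variant excess in the cases vs the reference.

    The site universe is the scope's site list (the union of case and
    reference detections); the observed statistic is the case rare count at
    the given threshold, and each replicate simulates a case-sized cohort
    from the reference and scores it identically.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if rarity not in {"simulated", "reference"}:
        raise ValueError(f"unknown rarity basis {rarity!r}")
    label = scope_label(scope)
    sub = sites_in_scope(sites, scope)
    thr = threshold_fraction(threshold)
    observed = stat_rare_count(case, sub, None, thr).value
    if not sub:
        return SimTestResult(label, observed, n_sim, 0, n_sim, seed,
                             model, rarity, strict, degenerate=True)

    xl = {s.gene: (panel.x_linked(s.gene) if panel is not None else False) for s in sub}
    n_chrom = np.array([case.chrom_count(s.key, xl[s.gene]) for s in sub], dtype=np.int64)
    ac, an = _reference_arrays(reference, sub)
    freq = ac / an
    if rarity == "reference":
        ref_folded = np.minimum(ac, an - ac)
        ref_rare = thr.denominator * ref_folded <= thr.numerator * an

    rng = np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode()), 0x5EF]))
    n_gt = n_ge = 0
    done = 0
    while done < n_sim:
        b = min(batch, n_sim - done)
        if model == "binomial":
            sim = rng.binomial(n_chrom, freq, size=(b, len(sub)))
        elif model == "hypergeometric":
            if np.any(an < n_chrom):
                raise ValueError("hypergeometric model needs reference AN >= n_chrom")
            sim = rng.hypergeometric(ac, an - ac, n_chrom, size=(b, len(sub)))
        else:
            raise ValueError(f"unknown sampling model {model!r}")
        present = sim >= 1
        if rarity == "simulated":
            folded = np.minimum(sim, n_chrom - sim)
            rare = thr.denominator * folded <= thr.numerator * n_chrom
            stats = (present & rare).sum(axis=1)
        else:
            stats = (present & ref_rare).sum(axis=1)
        n_gt += int((stats > observed).sum())
        n_ge += int((stats >= observed).sum())
        done += b
    return SimTestResult(label, observed, n_sim, n_gt, n_ge, seed,
                         model, rarity, strict)
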