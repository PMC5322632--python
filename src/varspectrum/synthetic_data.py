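"""Synthetic panels, cohorts, and aggregate references for the analysis.

The generator emulates the statistical structure the spectrum analysis
assumes: a ten-gene candidate panel (two X-linked genes, study-like coding
lengths), a shared pool of common variants binomially sampled into both
cohorts, a pool of rare-band variants likewise sampled into both cohorts
(sites detected in only one cohort emerge naturally as population-specific),
a neutral-like site frequency spectrum (class probabilities proportional to
1/i over allele-count classes), and a count-only aggregate reference of tens
of thousands of individuals.

A case enrichment factor rho >= 1 adds, in designated genes, extra
case-private rare variants at rate (rho - 1) times the baseline rare-site
rate — the risk-variant alternative for power studies.  At rho = 1 nothing
is added and case and control chromosomes are exchangeable draws from the
same frequency model, so permutation p-values are valid by construction;
this exchangeable null is what the calibration tests rely on.

Default cohort geometry mirrors the study design this pipeline targets:
288 cases (140 female / 148 male), 379 controls, a reference of 33,000
individuals, and roughly a dozen detected sites per gene.

What the generator does *not* emulate: linkage disequilibrium between sites
(the permutation test ignores it by design), sequencing error, and
coverage-driven per-site call-rate variation (reference AN jitter is
optional and uniform).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .variant_model import (
    AggregateReference,
    CohortCounts,
    GeneDef,
    GenePanel,
    GenotypeCounts,
    RegionInterval,
    SiteCounts,
    VariantSite,
    chromosome_count,
)

# Ten-gene panel geometry: names, coding lengths (bp), chromosomes, X-linkage.
TLR_GENES = ["TLR1", "TLR2", "TLR3", "TLR4", "TLR5",
             "TLR6", "TLR7", "TLR8", "TLR9", "TLR10"]
TLR_CODING_LENGTHS = [2358, 2352, 2712, 2517, 2574, 2388, 3147, 3123, 3096, 2433]
TLR_CHROMOSOMES = ["4", "4", "4", "9", "1", "4", "X", "X", "3", "4"]
TLR_X_LINKED = ("TLR7", "TLR8")

_PROMOTER_LEN = 551  # 500 bp upstream + start + 50 bp downstream
_BASES = np.array(list("ACGT"))


def default_panel(region_class: str = "coding") -> GenePanel:
    """Ten-gene panel with invented coordinates and study-like geometry.

    Genes are laid out 1 Mbp apart on their chromosomes; each gene gets a
    promoter interval of 551 bp immediately upstream of a contiguous coding
    interval of its coding length (introns are irrelevant to the counts).
    """
    genes = []
    per_chrom: dict[str, int] = {}
    for name, length, chrom in zip(TLR_GENES, TLR_CODING_LENGTHS, TLR_CHROMOSOMES):
        slot = per_chrom.get(chrom, 0)
        per_chrom[chrom] = slot + 1
        start = 1_000_000 * (slot + 1)
        intervals = (
            RegionInterval("promoter", start - _PROMOTER_LEN, start - 1, "+"),
            RegionInterval("coding", start, start + length - 1, "+"),
        )
        genes.append(GeneDef(name=name, chromosome=chrom,
                             x_linked=name in TLR_X_LINKED, intervals=intervals))
    return GenePanel(genes)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the study-like conditions."""

    gene_names: tuple[str, ...] = tuple(TLR_GENES)
    coding_lengths: tuple[int, ...] = tuple(TLR_CODING_LENGTHS)
    x_linked_genes: tuple[str, ...] = TLR_X_LINKED
    region_class: str = "coding"
    n_case: int = 288
    n_case_female: int = 140
    n_case_male: int = 148
    n_control: int = 379
    n_control_female: int = 190
    n_control_male: int = 189
    n_reference: int = 33_000
    variant_density: float = 0.0045   # expected detected sites per coding bp (~12/gene)
    shared_fraction: float = 0.6      # fraction of site mass drawn from the common pool
    sfs_model: str = "neutral"        # or "beta"
    sfs_classes: int = 757            # allele-count classes for the neutral SFS
    beta_a: float = 0.5
    beta_b: float = 5.0
    rare_freq_max: float = 0.01       # private variants arise in this frequency band
    enrichment: float = 1.0           # rho: case private rare-site rate multiplier
    enriched_genes: tuple[str, ...] = ()
    p_missense: float = 0.58
    p_nonsense: float = 0.025
    p_damaging_given_missense: float = 0.30
    p_dbsnp_shared: float = 0.95
    p_dbsnp_private: float = 0.15
    genotype_level: bool = False      # also emit HWE-consistent genotype counts
    reference_an_jitter: float = 0.0  # fractional per-site AN down-jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment < 1.0:
            raise ValueError("enrichment rho must be >= 1")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction outside [0, 1]")
        for p in (self.p_missense, self.p_nonsense, self.p_damaging_given_missense,
                  self.p_dbsnp_shared, self.p_dbsnp_private):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_missense + self.p_nonsense > 1.0:
            raise ValueError("functional-class probabilities exceed 1")
        if min(self.coding_lengths, default=1) <= 0:
            raise ValueError("coding lengths must be positive")
        if len(self.gene_names) != len(self.coding_lengths):
            raise ValueError("gene_names and coding_lengths lengths differ")


def sample_sfs(n_sites: int, model: str, rng: np.random.Generator, *,
               n_classes: int = 757, beta_a: float = 0.5,
               beta_b: float = 5.0) -> np.ndarray:
    """Population frequencies in (0, 1) from a site frequency spectrum model.

    ``neutral``: allele-count class i in 1..K with probability proportional
    to 1/i (the standard neutral expectation), mapped to frequency
    i / (K + 1).  ``beta``: Beta(a, b) draws, a skewed continuous SFS.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if n_sites == 0:
        return np.empty(0)
    if model == "neutral":
        classes = np.arange(1, n_classes + 1)
        probs = 1.0 / classes
        probs /= probs.sum()
        return rng.choice(classes, size=n_sites, p=probs) / (n_classes + 1)
    if model == "beta":
        f = rng.beta(beta_a, beta_b, size=n_sites)
        return np.clip(f, 1e-9, 1.0 - 1e-9)
    raise ValueError(f"unknown SFS model {model!r}")


def _panel_from_config(config: SimConfig) -> GenePanel:
    """Panel matching the config's gene names, lengths, and X-linkage.

    Gene i sits at 1 Mbp * (slot + 1) on its chromosome (study chromosomes
    for the default ten-gene names, consecutive chromosomes otherwise), with
    a 551 bp promoter directly upstream of a contiguous coding interval.
    """
    genes = []
    per_chrom: dict[str, int] = {}
    for ci, (name, length) in enumerate(zip(config.gene_names, config.coding_lengths)):
        chrom = (TLR_CHROMOSOMES[TLR_GENES.index(name)] if name in TLR_GENES
                 else str(ci + 1))
        slot = per_chrom.get(chrom, 0)
        per_chrom[chrom] = slot + 1
        start = 1_000_000 * (slot + 1)
        genes.append(GeneDef(
            name=name, chromosome=chrom, x_linked=name in config.x_linked_genes,
            intervals=(RegionInterval("promoter", start - _PROMOTER_LEN, start - 1, "+"),
                       RegionInterval("coding", start, start + length - 1, "+"))))
    return GenePanel(genes)


def _rare_sfs(n_sites: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """SFS draws truncated to the private-variant (rare) frequency band."""
    if n_sites == 0:
        return np.empty(0)
    if config.sfs_model == "neutral":
        k = config.sfs_classes
        max_class = max(1, int(config.rare_freq_max * (k + 1)))
        classes = np.arange(1, max_class + 1)
        probs = 1.0 / classes
        probs /= probs.sum()
        return rng.choice(classes, size=n_sites, p=probs) / (k + 1)
    f = sample_sfs(n_sites * 4 + 16, config.sfs_model, rng,
                   beta_a=config.beta_a, beta_b=config.beta_b)
    f = f[f <= config.rare_freq_max]
    while f.size < n_sites:  # rejection sampling top-up
        extra = sample_sfs(n_sites * 4 + 16, config.sfs_model, rng,
                           beta_a=config.beta_a, beta_b=config.beta_b)
        f = np.concatenate([f, extra[extra <= config.rare_freq_max]])
    return f[:n_sites]


def _draw_annotation(config: SimConfig, shared: bool,
                     rng: np.random.Generator) -> dict:
    if config.region_class == "promoter":
        func, sift, polyphen = "noncoding", "missing", "missing"
    else:
        u = rng.random()
        if u < config.p_missense:
            func = "missense"
            damaging = rng.random() < config.p_damaging_given_missense
            sift = "damaging" if damaging else "tolerated"
            polyphen = "damaging" if damaging else "benign"
        elif u < config.p_missense + config.p_nonsense:
            func, sift, polyphen = "nonsense", "damaging", "damaging"
        else:
            func, sift, polyphen = "synonymous", "tolerated", "benign"
    p_db = config.p_dbsnp_shared if shared else config.p_dbsnp_private
    return {"functional_class": func, "sift_call": sift, "polyphen_call": polyphen,
            "in_dbsnp": bool(rng.random() < p_db)}


def _genotypes_from_freq(n_female: int, n_male: int, x_linked: bool, freq: float,
                         rng: np.random.Generator) -> GenotypeCounts:
    """HWE-consistent genotype counts; X-linked males are hemizygous."""
    n_dip = n_female if x_linked else n_female + n_male
    g = rng.multinomial(n_dip, [(1 - freq) ** 2, 2 * freq * (1 - freq), freq ** 2])
    hemi_alt = int(rng.binomial(n_male, freq)) if x_linked else 0
    hemi_ref = (n_male - hemi_alt) if x_linked else 0
    return GenotypeCounts(int(g[0]), int(g[1]), int(g[2]), hemi_ref, hemi_alt)


def generate_cohort_pair(config: SimConfig,
                         rng: Optional[np.random.Generator] = None,
                         ) -> tuple[CohortCounts, CohortCounts, list[VariantSite], GenePanel]:
    """Case and control cohorts over a shared site universe, plus the panel.

    Every baseline site (common pool and rare pool alike) gets one
    population frequency and independent binomial draws into each cohort;
    a site absent from both cohorts is undetected and dropped.  Enriched
    genes additionally receive case-private rare sites at rate
    (rho - 1) x the rare-pool rate, guaranteed present in the cases
    (1 + binomial extra copies) and absent from the controls.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    panel = _panel_from_config(config)

    case = CohortCounts("CASE", config.n_case, config.n_case_female, config.n_case_male)
    ctrl = CohortCounts("CTRL", config.n_control, config.n_control_female,
                        config.n_control_male)
    sites: list[VariantSite] = []

    case_sex = (config.n_case_female, config.n_case_male)
    ctrl_sex = (config.n_control_female, config.n_control_male)
    for gene_name, length in zip(config.gene_names, config.coding_lengths):
        gene = panel[gene_name]
        x_linked = gene.x_linked
        case_n = chromosome_count(*case_sex, x_linked)
        ctrl_n = chromosome_count(*ctrl_sex, x_linked)
        iv = next(i for i in gene.intervals if i.region_class == config.region_class)
        lam = length * config.variant_density
        rare_lam = lam * (1.0 - config.shared_fraction)
        rho = config.enrichment if gene_name in config.enriched_genes else 1.0

        n_common = rng.poisson(lam * config.shared_fraction)
        n_rare = rng.poisson(rare_lam)
        n_enriched = rng.poisson(rare_lam * (rho - 1.0))

        n_total = n_common + n_rare + n_enriched
        positions = rng.choice(np.arange(iv.start, iv.end + 1),
                               size=min(n_total, iv.length), replace=False)
        pos_iter = iter(int(p) for p in positions)

        def make_site(pos: int, common_pool: bool) -> VariantSite:
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            return VariantSite(chrom=gene.chromosome, pos=pos, ref=str(ref),
                               alt=str(alt), gene=gene_name,
                               region_class=config.region_class,
                               **_draw_annotation(config, common_pool, rng))

        # baseline pools: one population frequency, binomial into both cohorts
        baseline = [(f, True) for f in sample_sfs(
            n_common, config.sfs_model, rng, n_classes=config.sfs_classes,
            beta_a=config.beta_a, beta_b=config.beta_b)]
        baseline += [(f, False) for f in _rare_sfs(n_rare, config, rng)]
        for f, common_pool in baseline:
            pos = next(pos_iter, None)
            if pos is None:
                break
            ac_case = int(rng.binomial(case_n, f))
            ac_ctrl = int(rng.binomial(ctrl_n, f))
            if ac_case == 0 and ac_ctrl == 0:
                continue  # undetected in both cohorts
            site = make_site(pos, common_pool)
            sites.append(site)
            for cohort, ac, n, sex in ((case, ac_case, case_n, case_sex),
                                       (ctrl, ac_ctrl, ctrl_n, ctrl_sex)):
                gt = (_gt_matching_count(*sex, x_linked, ac, rng)
                      if config.genotype_level else None)
                cohort.add(site.key, SiteCounts(ac, n, gt))

        # enrichment channel: case-private rare risk variants
        for f in _rare_sfs(n_enriched, config, rng):
            pos = next(pos_iter, None)
            if pos is None:
                break
            copies = 1 + int(rng.binomial(case_n - 1, f))
            site = make_site(pos, False)
            sites.append(site)
            case_gt = (_gt_matching_count(*case_sex, x_linked, copies, rng)
                       if config.genotype_level else None)
            ctrl_gt = (_gt_matching_count(*ctrl_sex, x_linked, 0, rng)
                       if config.genotype_level else None)
            case.add(site.key, SiteCounts(copies, case_n, case_gt))
            ctrl.add(site.key, SiteCounts(0, ctrl_n, ctrl_gt))

    sites.sort(key=lambda s: (s.chrom, s.pos, s.ref, s.alt))
    return case, ctrl, sites, panel


def generate_case_reference_pair(config: SimConfig,
                                 rng: Optional[np.random.Generator] = None,
                                 ) -> tuple[CohortCounts, AggregateReference,
                                            list[VariantSite], GenePanel]:
    """Case cohort plus an aggregate reference drawn from the same frequencies.

    Candidate sites arise per gene at the configured density with SFS
    frequencies (common and rare pools as in :func:`generate_cohort_pair`);
    the case cohort samples each binomially, and the reference samples the
    same frequency with 2 * n_reference chromosomes — deep enough to
    catalogue essentially every candidate, the way an exome aggregate dwarfs
    a single study.  The site universe is the union of case and reference
    detections, which is what makes the rare-excess simulation test
    calibrated at rho = 1: sites the case cohort happened to miss still
    contribute to the simulated null.  Enriched genes add case-private rare
    variants absent from the reference.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    panel = _panel_from_config(config)
    case = CohortCounts("CASE", config.n_case, config.n_case_female, config.n_case_male)
    reference = AggregateReference("REF")
    sites: list[VariantSite] = []
    an_full = 2 * config.n_reference

    for gene_name, length in zip(config.gene_names, config.coding_lengths):
        gene = panel[gene_name]
        x_linked = gene.x_linked
        case_n = chromosome_count(config.n_case_female, config.n_case_male, x_linked)
        iv = next(i for i in gene.intervals if i.region_class == config.region_class)
        lam = length * config.variant_density
        rare_lam = lam * (1.0 - config.shared_fraction)
        rho = config.enrichment if gene_name in config.enriched_genes else 1.0

        n_common = rng.poisson(lam * config.shared_fraction)
        n_rare = rng.poisson(rare_lam)
        n_enriched = rng.poisson(rare_lam * (rho - 1.0))
        n_total = n_common + n_rare + n_enriched
        positions = rng.choice(np.arange(iv.start, iv.end + 1),
                               size=min(n_total, iv.length), replace=False)
        pos_iter = iter(int(p) for p in positions)

        freqs = [(f, True) for f in sample_sfs(
            n_common, config.sfs_model, rng, n_classes=config.sfs_classes,
            beta_a=config.beta_a, beta_b=config.beta_b)]
        freqs += [(f, False) for f in _rare_sfs(n_rare, config, rng)]
        for f, common_pool in freqs:
            pos = next(pos_iter, None)
            if pos is None:
                break
            an = an_full
            if config.reference_an_jitter > 0:
                an = int(an_full * (1.0 - config.reference_an_jitter * rng.random()))
            ac_case = int(rng.binomial(case_n, f))
            ac_ref = int(rng.binomial(an, f))
            if ac_case == 0 and ac_ref == 0:
                continue
            ref_b, alt_b = rng.choice(_BASES, size=2, replace=False)
            site = VariantSite(chrom=gene.chromosome, pos=pos, ref=str(ref_b),
                               alt=str(alt_b), gene=gene_name,
                               region_class=config.region_class,
                               **_draw_annotation(config, common_pool, rng))
            sites.append(site)
            if ac_case:
                case.add(site.key, SiteCounts(ac_case, case_n))
            reference.add(site.key, ac_ref, an)

        for f in _rare_sfs(n_enriched, config, rng):
            pos = next(pos_iter, None)
            if pos is None:
                break
            copies = 1 + int(rng.binomial(case_n - 1, f))
            ref_b, alt_b = rng.choice(_BASES, size=2, replace=False)
            site = VariantSite(chrom=gene.chromosome, pos=pos, ref=str(ref_b),
                               alt=str(alt_b), gene=gene_name,
                               region_class=config.region_class,
                               **_draw_annotation(config, False, rng))
            sites.append(site)
            case.add(site.key, SiteCounts(copies, case_n))

    sites.sort(key=lambda s: (s.chrom, s.pos, s.ref, s.alt))
    return case, reference, sites, panel


def _gt_matching_count(n_female: int, n_male: int, x_linked: bool, ac: int,
                       rng: np.random.Generator) -> GenotypeCounts:
    """Genotype counts consistent with a given alt copy total.

    Alt copies are placed uniformly at random on the cohort's chromosomes
    (the same allele-level model that produced the count), so genotype
    frequencies follow HWE conditionally on the count.
    """
    n_dip = n_female if x_linked else n_female + n_male
    n_hemi = n_male if x_linked else 0
    n_chrom = 2 * n_dip + n_hemi
    chroms = np.zeros(n_chrom, dtype=np.int8)
    chroms[rng.choice(n_chrom, size=ac, replace=False)] = 1
    dip = chroms[:2 * n_dip].reshape(n_dip, 2).sum(axis=1)
    hemi = chroms[2 * n_dip:]
    return GenotypeCounts(int((dip == 0).sum()), int((dip == 1).sum()),
                          int((dip == 2).sum()),
                          int((hemi == 0).sum()), int((hemi == 1).sum()))


def generate_reference(config: SimConfig,
                       base_frequencies: dict,
                       rng: Optional[np.random.Generator] = None,
                       population_label: str = "REF") -> AggregateReference:
    """Count-only aggregate reference from per-site population frequencies.

    ``base_frequencies`` maps site keys to frequencies; each site's AC is
    Binomial(AN, freq) with AN = 2 * n_reference, optionally down-jittered
    per site to emulate variable call rates.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    ref = AggregateReference(population_label)
    an_full = 2 * config.n_reference
    for key, f in base_frequencies.items():
        an = an_full
        if config.reference_an_jitter > 0:
            an = int(an_full * (1.0 - config.reference_an_jitter * rng.random()))
        ref.add(key, int(rng.binomial(an, f)), an)
    return ref


def cohort_frequencies(cohort: CohortCounts) -> dict:
    """Observed per-site alt frequencies of a cohort (for null references)."""
    return {k: sc.alt_count / sc.chrom_count
            for k, sc in cohort.counts.items() if sc.chrom_count > 0}


def true_parameter_manifest(config: SimConfig) -> dict:
    """True generator parameters, for manifests and parameter-recovery tests."""
    from dataclasses import asdict
    return asdict(config)
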