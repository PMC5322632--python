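import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from varspectrum import (
    CohortCounts,
    GeneDef,
    GenePanel,
    RegionInterval,
    SiteCounts,
    VariantSite,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_panel():
    """Two genes, one autosomal and one X-linked, promoter + coding intervals."""
    return GenePanel([
        GeneDef("GENE_A", "4", False, (
            RegionInterval("promoter", 449, 999), RegionInterval("coding", 1000, 1999))),
        GeneDef("GENE_X", "X", True, (
            RegionInterval("promoter", 449, 999), RegionInterval("coding", 1000, 1999))),
    ])


def make_site(chrom="4", pos=1000, ref="A", alt="G", gene="GENE_A", **kw):
    kw.setdefault("region_class", "coding")
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, **kw)


def make_cohort(label, n, site_counts, n_female=-1, n_male=-1):
    """Cohort from {site_key: (ac, an)} or {site_key: SiteCounts}."""
    cohort = CohortCounts(label, n, n_female, n_male)
    for key, val in site_counts.items():
        cohort.add(key, val if isinstance(val, SiteCounts) else SiteCounts(*val))
    return cohort
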