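"""Data model and I/O for variant sites, cohort allele counts, gene panels.

The containers here describe the inputs of a candidate-gene resequencing
comparison: a panel of genes (with promoter and coding intervals, and
X-linkage flags), biallelic SNV sites annotated with functional class and
categorical deleteriousness predictions (SIFT / PolyPhen-2), and per-site
alternate-allele counts for one or more populations.  Counts are the primary
representation — pooled sequencing yields allele counts, not genotypes — with
optional genotype-level detail where individual-level data exist (Sanger-typed
promoter variants).

Coordinates are 1-based inclusive throughout (VCF convention).  Indels are
rejected everywhere: only single-nucleotide ref/alt pairs are modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

logger = logging.getLogger("varspectrum")

REGION_CLASSES = frozenset({"promoter", "coding"})
FUNCTIONAL_CLASSES = frozenset({"missense", "nonsense", "synonymous", "noncoding", "unknown"})
SIFT_CALLS = frozenset({"damaging", "tolerated", "missing"})
POLYPHEN_CALLS = frozenset({"damaging", "benign", "missing"})
_BASES = frozenset("ACGT")

SiteKey = tuple[str, int, str, str]


class VariantModelError(ValueError):
    """Malformed or inconsistent variant data."""


class ValidationError(VariantModelError):
    """Input violates a hard model invariant."""


class UndefinedFrequencyError(VariantModelError):
    """Frequency requested for a site with zero called chromosomes."""


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionInterval:
    """A 1-based inclusive genomic interval of a gene region."""

    region_class: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(f"unknown region_class {self.region_class!r}")
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"bad interval [{self.start}, {self.end}]")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class GeneDef:
    """One gene of the panel: chromosome, X-linkage, region intervals.

    ``coding_length_bp`` defaults to the summed length of the coding
    intervals; an explicitly supplied value must agree with that sum when
    coding intervals are present.
    """

    name: str
    chromosome: str
    x_linked: bool = False
    intervals: tuple[RegionInterval, ...] = ()
    coding_length_bp: int = -1  # sentinel: derive from intervals

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"{self.name}: overlapping intervals [{a.start},{a.end}] / [{b.start},{b.end}]"
                )
        coding_sum = sum(iv.length for iv in self.intervals if iv.region_class == "coding")
        if self.coding_length_bp < 0:
            object.__setattr__(self, "coding_length_bp", coding_sum)
        elif self.intervals and coding_sum and self.coding_length_bp != coding_sum:
            raise ValidationError(
                f"{self.name}: coding_length_bp {self.coding_length_bp} != interval sum {coding_sum}"
            )

    def region_at(self, chrom: str, pos: int) -> Optional[str]:
        """Region class covering (chrom, pos), or None if outside the gene."""
        if chrom != self.chromosome:
            return None
        for iv in self.intervals:
            if iv.contains(pos):
                return iv.region_class
        return None


def promoter_interval(exon1_start: int, strand: str = "+",
                      upstream: int = 500, downstream: int = 50) -> RegionInterval:
    """Promoter interval around the start of exon 1, strand-aware.

    The promoter is the region from ``upstream`` bp before to ``downstream``
    bp after the first transcribed base, in transcription orientation.
    """
    if strand == "+":
        return RegionInterval("promoter", exon1_start - upstream, exon1_start + downstream, "+")
    return RegionInterval("promoter", exon1_start - downstream, exon1_start + upstream, "-")


class GenePanel:
    """Ordered collection of GeneDef with position lookup."""

    def __init__(self, genes: Iterable[GeneDef]):
        self.genes: dict[str, GeneDef] = {}
        for g in genes:
            if g.name in self.genes:
                raise ValidationError(f"duplicate gene {g.name!r} in panel")
            self.genes[g.name] = g

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, name: str) -> GeneDef:
        return self.genes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.genes

    @property
    def gene_names(self) -> list[str]:
        return list(self.genes)

    def x_linked(self, gene: str) -> bool:
        return self.genes[gene].x_linked if gene in self.genes else False

    def locate(self, chrom: str, pos: int) -> Optional[tuple[str, str]]:
        """(gene name, region class) covering a position, or None."""
        for g in self.genes.values():
            rc = g.region_at(chrom, pos)
            if rc is not None:
                return g.name, rc
        return None

    # -- TSV: gene, chrom, x_linked, region_class, start, end, strand -------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenePanel":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"gene", "chrom", "x_linked", "region_class", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise VariantModelError(f"panel file missing columns: {sorted(missing)}")
        genes: dict[str, dict] = {}
        for i, row in df.iterrows():
            try:
                name = row["gene"]
                entry = genes.setdefault(name, {
                    "chrom": row["chrom"],
                    "x_linked": str(row["x_linked"]).strip().lower() in {"1", "true", "yes"},
                    "intervals": [],
                })
                entry["intervals"].append(
                    RegionInterval(row["region_class"], int(row["start"]), int(row["end"]),
                                   row["strand"]))
            except (KeyError, ValueError, ValidationError) as exc:
                raise VariantModelError(f"panel file line {i + 2}: {exc}") from exc
        return cls(GeneDef(name=n, chromosome=e["chrom"], x_linked=e["x_linked"],
                           intervals=tuple(e["intervals"])) for n, e in genes.items())

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene": g.name, "chrom": g.chromosome, "x_linked": str(g.x_linked).lower(),
             "region_class": iv.region_class, "start": iv.start, "end": iv.end,
             "strand": iv.strand}
            for g in self for iv in g.intervals
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def chromosome_count(n_female: int, n_male: int, x_linked: bool) -> int:
    """Number of chromosomes carried by a mixed-sex cohort at a locus.

    Autosomal loci: two per individual.  X-linked loci: two per female, one
    per (hemizygous) male.
    """
    if n_female < 0 or n_male < 0:
        raise ValidationError("negative individual counts")
    if x_linked:
        return 2 * n_female + n_male
    return 2 * (n_female + n_male)


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNV with gene/region/annotation metadata."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    region_class: str = "coding"
    functional_class: str = "unknown"
    sift_call: str = "missing"
    polyphen_call: str = "missing"
    in_dbsnp: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValidationError(
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt}: SNVs only (single A/C/G/T alleles)")
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos}: ref == alt ({self.ref})")
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(f"unknown region_class {self.region_class!r}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValidationError(f"unknown functional_class {self.functional_class!r}")
        if self.sift_call not in SIFT_CALLS:
            raise ValidationError(f"unknown sift_call {self.sift_call!r}")
        if self.polyphen_call not in POLYPHEN_CALLS:
            raise ValidationError(f"unknown polyphen_call {self.polyphen_call!r}")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def concordant_damaging(self) -> bool:
        return self.sift_call == "damaging" and self.polyphen_call == "damaging"


# ---------------------------------------------------------------------------
# cohort counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts plus hemizygous (single-X male) counts."""

    hom_ref: int
    het: int
    hom_alt: int
    hemi_ref: int = 0
    hemi_alt: int = 0

    def __post_init__(self) -> None:
        if min(self.hom_ref, self.het, self.hom_alt, self.hemi_ref, self.hemi_alt) < 0:
            raise ValidationError("negative genotype counts")

    @property
    def alt_copies(self) -> int:
        return 2 * self.hom_alt + self.het + self.hemi_alt

    @property
    def chromosomes(self) -> int:
        return 2 * (self.hom_ref + self.het + self.hom_alt) + self.hemi_ref + self.hemi_alt

    @property
    def n_diploid(self) -> int:
        return self.hom_ref + self.het + self.hom_alt


@dataclass(frozen=True)
class SiteCounts:
    """Alternate-allele count out of called chromosomes at one site."""

    alt_count: int
    chrom_count: int
    genotypes: Optional[GenotypeCounts] = None

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.chrom_count:
            raise ValidationError(
                f"alt_count {self.alt_count} outside [0, chrom_count={self.chrom_count}]")
        g = self.genotypes
        if g is not None:
            if g.alt_copies != self.alt_count:
                raise ValidationError(
                    f"genotype alt copies {g.alt_copies} != alt_count {self.alt_count}")
            if g.chromosomes != self.chrom_count:
                raise ValidationError(
                    f"genotype chromosomes {g.chromosomes} != chrom_count {self.chrom_count}")


@dataclass
class CohortCounts:
    """Per-site allele counts for one population.

    Sites absent from ``counts`` are treated as observed with alt_count 0 at
    the cohort's default (sex-adjusted) chromosome count; missing genotypes
    reduce the stored per-site chrom_count instead of being imputed.
    """

    population_label: str
    n_individuals: int
    n_female: int = -1
    n_male: int = -1
    counts: dict[SiteKey, SiteCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_female < 0 and self.n_male < 0:
            # unknown sex split: assume an even split for X-linked accounting
            self.n_female = self.n_individuals // 2
            self.n_male = self.n_individuals - self.n_female
        if self.n_female + self.n_male != self.n_individuals:
            raise ValidationError(
                f"{self.population_label}: n_female + n_male != n_individuals")

    def default_chrom_count(self, x_linked: bool = False) -> int:
        return chromosome_count(self.n_female, self.n_male, x_linked)

    def add(self, key: SiteKey, counts: SiteCounts) -> None:
        if key in self.counts:
            raise ValidationError(f"duplicate site key {key} in {self.population_label}")
        self.counts[key] = counts

    def alt_count(self, key: SiteKey) -> int:
        sc = self.counts.get(key)
        return 0 if sc is None else sc.alt_count

    def chrom_count(self, key: SiteKey, x_linked: bool = False) -> int:
        sc = self.counts.get(key)
        return self.default_chrom_count(x_linked) if sc is None else sc.chrom_count

    def genotypes(self, key: SiteKey) -> Optional[GenotypeCounts]:
        sc = self.counts.get(key)
        return None if sc is None else sc.genotypes


@dataclass
class AggregateReference:
    """ExAC/gnomAD-style reference: per-site AC/AN only, no individuals.

    chrom_count (AN) may vary site to site with per-site call rates.
    """

    population_label: str
    counts: dict[SiteKey, tuple[int, int]] = field(default_factory=dict)

    def add(self, key: SiteKey, alt_count: int, chrom_count: int) -> None:
        if key in self.counts:
            raise ValidationError(f"duplicate site key {key} in {self.population_label}")
        if not 0 <= alt_count <= chrom_count:
            raise ValidationError(f"{key}: alt_count {alt_count} outside [0, {chrom_count}]")
        self.counts[key] = (alt_count, chrom_count)

    def frequency(self, key: SiteKey) -> float:
        """Reference alternate-allele frequency; 0.0 for absent sites."""
        ac_an = self.counts.get(key)
        if ac_an is None:
            return 0.0
        ac, an = ac_an
        if an == 0:
            raise UndefinedFrequencyError(f"{key}: chrom_count 0 in reference")
        return ac / an

    @classmethod
    def from_tsv(cls, path: str | Path, population_label: str = "REF") -> "AggregateReference":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        required = {"chrom", "pos", "ref", "alt", "ac", "an"}
        missing = required - set(df.columns)
        if missing:
            raise VariantModelError(f"reference file missing columns: {sorted(missing)}")
        ref = cls(population_label)
        for i, row in df.iterrows():
            try:
                ref.add((str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"]),
                        int(row["ac"]), int(row["an"]))
            except (ValueError, ValidationError) as exc:
                raise VariantModelError(f"reference file line {i + 2}: {exc}") from exc
        return ref

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "ac": ac, "an": an}
                for k, (ac, an) in self.counts.items()]
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ac", "an"]).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant table I/O
# ---------------------------------------------------------------------------

class VariantTable(NamedTuple):
    sites: list[VariantSite]
    cohorts: dict[str, CohortCounts]
    n_indels_dropped: int


_SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "region_class",
                 "functional_class", "sift", "polyphen", "in_dbsnp"]
_GT_SUFFIXES = ["hom_ref", "het", "hom_alt", "hemi_ref", "hemi_alt"]


def read_variant_table(path: str | Path, dialect: str = "tsv", *,
                       panel: Optional[GenePanel] = None,
                       sample_map: Optional[Mapping[str, str]] = None) -> VariantTable:
    """Read sites plus per-population counts from TSV or VCF.

    TSV dialect: the documented flat table (site/annotation columns, then
    ``<pop>_ac`` / ``<pop>_an`` pairs, optionally genotype-count columns);
    ``##population`` header lines carry cohort sizes.  VCF dialect: biallelic
    split of each record, counts from ``AC_<pop>`` / ``AN_<pop>`` INFO fields
    or from per-sample genotypes with a sample→population map.  Indel alleles
    are dropped and counted, never modelled.
    """
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path, panel=panel, sample_map=sample_map)
    raise VariantModelError(f"unknown dialect {dialect!r}")


def _read_tsv(path: str | Path) -> VariantTable:
    meta: dict[str, dict[str, int]] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##population"):
                parts = line.rstrip("\n").split("\t")
                label = parts[1]
                kv = dict(p.split("=", 1) for p in parts[2:])
                meta[label] = {k: int(v) for k, v in kv.items()}
            elif line.startswith("##"):
                continue
            else:
                body_lines.append(line)
    df = pd.read_csv(StringIO("".join(body_lines)), sep="\t", dtype={"chrom": str})
    missing = set(_SITE_COLUMNS) - set(df.columns)
    if missing:
        raise VariantModelError(f"variant table missing columns: {sorted(missing)}")
    pops = sorted({c[:-3] for c in df.columns if c.endswith("_ac")
                   if f"{c[:-3]}_an" in df.columns})
    if not pops:
        raise VariantModelError("variant table has no <pop>_ac/<pop>_an column pairs")

    cohorts: dict[str, CohortCounts] = {}
    for pop in pops:
        m = meta.get(pop, {})
        n_ind = m.get("n_individuals", int(-(-df[f"{pop}_an"].max() // 2)))
        cohorts[pop] = CohortCounts(
            population_label=pop, n_individuals=n_ind,
            n_female=m.get("n_female", -1), n_male=m.get("n_male", -1))

    sites: list[VariantSite] = []
    seen: set[SiteKey] = set()
    n_indels = 0
    for i, row in df.iterrows():
        line_no = i + 2 + len(meta)
        ref_a, alt_a = str(row["ref"]), str(row["alt"])
        if len(ref_a) != 1 or len(alt_a) != 1:
            n_indels += 1
            continue
        try:
            site = VariantSite(
                chrom=str(row["chrom"]), pos=int(row["pos"]), ref=ref_a, alt=alt_a,
                gene=str(row["gene"]), region_class=str(row["region_class"]),
                functional_class=str(row["functional_class"]),
                sift_call=str(row["sift"]), polyphen_call=str(row["polyphen"]),
                in_dbsnp=str(row["in_dbsnp"]).strip().lower() in {"1", "true", "yes"})
        except (ValueError, ValidationError) as exc:
            raise VariantModelError(f"{path} line {line_no}: {exc}") from exc
        if site.key in seen:
            raise VariantModelError(f"{path} line {line_no}: duplicate site key {site.key}")
        seen.add(site.key)
        sites.append(site)
        for pop in pops:
            try:
                gt = None
                gt_cols = [f"{pop}_{s}" for s in _GT_SUFFIXES]
                if all(c in df.columns for c in gt_cols) and not any(
                        pd.isna(row[c]) for c in gt_cols):
                    gt = GenotypeCounts(*(int(row[c]) for c in gt_cols))
                cohorts[pop].add(site.key, SiteCounts(
                    alt_count=int(row[f"{pop}_ac"]), chrom_count=int(row[f"{pop}_an"]),
                    genotypes=gt))
            except (ValueError, ValidationError) as exc:
                raise VariantModelError(f"{path} line {line_no} ({pop}): {exc}") from exc
    if n_indels:
        logger.info("dropped %d indel rows from %s", n_indels, path)
    return VariantTable(sites, cohorts, n_indels)


def write_variant_table(path: str | Path, sites: Sequence[VariantSite],
                        cohorts: Mapping[str, CohortCounts],
                        header_comments: Sequence[str] = ()) -> None:
    """Write the TSV dialect read back by :func:`read_variant_table`."""
    pops = list(cohorts)
    with_gt = [p for p in pops
               if any(cohorts[p].genotypes(s.key) is not None for s in sites)]
    rows = []
    for s in sites:
        row: dict[str, object] = {
            "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt, "gene": s.gene,
            "region_class": s.region_class, "functional_class": s.functional_class,
            "sift": s.sift_call, "polyphen": s.polyphen_call,
            "in_dbsnp": str(s.in_dbsnp).lower()}
        for p in pops:
            c = cohorts[p]
            row[f"{p}_ac"] = c.alt_count(s.key)
            row[f"{p}_an"] = c.chrom_count(s.key)
            if p in with_gt:
                gt = c.genotypes(s.key)
                for suf in _GT_SUFFIXES:
                    row[f"{p}_{suf}"] = "" if gt is None else getattr(gt, suf)
        rows.append(row)
    cols = _SITE_COLUMNS + [f"{p}_{c}" for p in pops
                            for c in (["ac", "an"] + (_GT_SUFFIXES if p in with_gt else []))]
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"## {line}\n")
        for p in pops:
            c = cohorts[p]
            fh.write(f"##population\t{p}\tn_individuals={c.n_individuals}"
                     f"\tn_female={c.n_female}\tn_male={c.n_male}\n")
        pd.DataFrame(rows, columns=cols).to_csv(fh, sep="\t", index=False)


def _read_vcf(path: str | Path, *, panel: Optional[GenePanel] = None,
              sample_map: Optional[Mapping[str, str]] = None) -> VariantTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    pops_gt: dict[str, list[int]] = {}
    if sample_map is not None:
        for idx, sample in enumerate(vcf.samples):
            if sample in sample_map:
                pops_gt.setdefault(sample_map[sample], []).append(idx)

    sites: list[VariantSite] = []
    seen: set[SiteKey] = set()
    cohorts: dict[str, CohortCounts] = {}
    info_pops: Optional[list[str]] = None
    n_indels = 0

    for var in vcf:
        chrom = var.CHROM
        if info_pops is None and sample_map is None:
            info_pops = sorted({k[3:] for k in dict(var.INFO) if k.startswith("AC_")
                                if f"AN_{k[3:]}" in dict(var.INFO)})
            if not info_pops:
                raise VariantModelError(
                    "VCF has neither AC_<pop>/AN_<pop> INFO fields nor a sample map")
        gts = var.genotypes if pops_gt else None  # [[a0, a1, phased], ...] or [[a0, phased]]
        for ai, alt in enumerate(var.ALT, start=1):
            if len(var.REF) != 1 or len(alt) != 1 or alt == "*":
                n_indels += 1
                continue
            located = panel.locate(chrom, var.POS) if panel is not None else None
            gene, region = located if located is not None else ("", "coding")
            site = VariantSite(
                chrom=chrom, pos=var.POS, ref=var.REF, alt=alt, gene=gene,
                region_class=region,
                functional_class=str(var.INFO.get("FUNC", "unknown")),
                sift_call=str(var.INFO.get("SIFT", "missing")),
                polyphen_call=str(var.INFO.get("POLYPHEN", "missing")),
                in_dbsnp=bool(var.ID) and str(var.ID).startswith("rs"))
            if site.key in seen:
                raise VariantModelError(f"duplicate site key {site.key} in {path}")
            seen.add(site.key)
            sites.append(site)
            if pops_gt:
                for pop, idxs in pops_gt.items():
                    ac = an = 0
                    for i in idxs:
                        for allele in gts[i][:-1]:  # last entry is the phase flag
                            if allele < 0:
                                continue  # missing allele lowers chrom_count
                            an += 1
                            if allele == ai:
                                ac += 1
                    cohorts.setdefault(pop, CohortCounts(pop, len(idxs))).add(
                        site.key, SiteCounts(ac, an))
            else:
                info = dict(var.INFO)
                for pop in info_pops:
                    ac_raw, an = info[f"AC_{pop}"], int(info[f"AN_{pop}"])
                    ac = int(ac_raw[ai - 1] if isinstance(ac_raw, tuple) else ac_raw)
                    cohorts.setdefault(
                        pop, CohortCounts(pop, an // 2 + an % 2)).add(
                        site.key, SiteCounts(ac, an))
    if n_indels:
        logger.info("dropped %d indel alleles from %s", n_indels, path)
    return VariantTable(sites, cohorts, n_indels)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_cohort(cohort: CohortCounts, panel: GenePanel,
                    sites: Optional[Sequence[VariantSite]] = None) -> list[str]:
    """Consistency report for a cohort against a panel; empty when clean.

    Flags sites outside every panel interval, allele counts exceeding
    chromosome totals, genotype/allele-count mismatches, and X-linked sites
    whose diploid/hemizygous totals exceed the cohort's sex counts.
    Report-based: never raises on inconsistent data.
    """
    issues: list[str] = []
    site_by_key = {s.key: s for s in sites} if sites is not None else {}
    for key, sc in cohort.counts.items():
        chrom, pos, ref, alt = key
        label = f"{chrom}:{pos} {ref}>{alt}"
        located = panel.locate(chrom, pos)
        if located is None:
            issues.append(f"{label}: outside all panel intervals")
            gene = None
        else:
            gene = located[0]
        if sc.alt_count > sc.chrom_count:
            issues.append(f"{label}: alt_count {sc.alt_count} > chrom_count {sc.chrom_count}")
        g = sc.genotypes
        if g is not None:
            if g.alt_copies != sc.alt_count:
                issues.append(f"{label}: genotype alt copies {g.alt_copies} "
                              f"!= alt_count {sc.alt_count}")
            if g.chromosomes != sc.chrom_count:
                issues.append(f"{label}: genotype chromosomes {g.chromosomes} "
                              f"!= chrom_count {sc.chrom_count}")
            x_linked = panel.x_linked(gene) if gene else False
            if x_linked:
                if g.n_diploid > cohort.n_female:
                    issues.append(f"{label}: {g.n_diploid} diploid genotypes at X-linked "
                                  f"site exceed {cohort.n_female} females "
                                  "(heterozygous male calls are invalid)")
                if g.hemi_ref + g.hemi_alt > cohort.n_male:
                    issues.append(f"{label}: hemizygous count exceeds {cohort.n_male} males")
        expected_max = cohort.default_chrom_count(
            panel.x_linked(gene) if gene else False)
        if sc.chrom_count > expected_max:
            issues.append(f"{label}: chrom_count {sc.chrom_count} exceeds cohort "
                          f"maximum {expected_max}")
        if sites is not None and key in site_by_key and gene:
            if site_by_key[key].gene and site_by_key[key].gene != gene:
                issues.append(f"{label}: annotated gene {site_by_key[key].gene!r} "
                              f"but position lies in {gene!r}")
    return issues
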