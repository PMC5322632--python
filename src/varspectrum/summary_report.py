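"""Per-gene summary tables and cross-population comparisons.

Builds, for one region class (promoter or coding), a table with one row per
panel gene plus a Total row.  For each population the row reports: sites
detected, rare sites (MAF <= 1%), population-specific sites, sites not in
dbSNP ("new"), the functional-class breakdown (missense / nonsense /
synonymous), and concordantly damaging sites.  Every cell is produced by the
spectrum statistics, so the table is a pure function of the loaded data.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .variant_model import CohortCounts, GenePanel, VariantSite
from .spectrum_stats import (
    is_present,
    stat_case_specific,
    stat_damaging_count,
    stat_rare_count,
)


@dataclass(frozen=True)
class GeneSummaryRow:
    """One gene's spectrum summary for one population."""

    gene: str
    region_class: str
    population: str
    total: int
    n_rare: int
    n_specific: int
    n_new: int
    n_missense: int
    n_nonsense: int
    n_synonymous: int
    n_damaging: int


def _population_row(gene: str, region_class: str, cohort: CohortCounts,
                    other: CohortCounts, sites: Sequence[VariantSite],
                    threshold: Union[float, Fraction]) -> GeneSummaryRow:
    present = [s for s in sites if is_present(cohort.alt_count(s.key))]
    return GeneSummaryRow(
        gene=gene, region_class=region_class, population=cohort.population_label,
        total=len(present),
        n_rare=stat_rare_count(cohort, sites, None, threshold).value,
        n_specific=stat_case_specific(cohort, other, sites, None).value,
        n_new=sum(1 for s in present if not s.in_dbsnp),
        n_missense=sum(1 for s in present if s.functional_class == "missense"),
        n_nonsense=sum(1 for s in present if s.functional_class == "nonsense"),
        n_synonymous=sum(1 for s in present if s.functional_class == "synonymous"),
        n_damaging=stat_damaging_count(cohort, sites, None).value,
    )


_ROW_FIELDS = ["total", "n_rare", "n_specific", "n_new",
               "n_missense", "n_nonsense", "n_synonymous", "n_damaging"]


def gene_summary(case: CohortCounts, control: CohortCounts,
                 sites: Sequence[VariantSite], region_class: str, *,
                 panel: Optional[GenePanel] = None,
                 gene_order: Optional[Sequence[str]] = None,
                 threshold: Union[float, Fraction] = 0.01) -> pd.DataFrame:
    """Per-gene summary table for one region class, with a Total row.

    Genes with no sites are retained as zero rows.  Columns come in two
    population blocks (``<pop>_total``, ``<pop>_rare``, ...); "specific"
    always means specific relative to the other population in the table.
    """
    region_sites = [s for s in sites if s.region_class == region_class]
    if gene_order is None:
        gene_order = (panel.gene_names if panel is not None
                      else sorted({s.gene for s in region_sites}))
    records = []
    for gene in gene_order:
        gsites = [s for s in region_sites if s.gene == gene]
        for cohort, other in ((case, control), (control, case)):
            records.append(_population_row(gene, region_class, cohort, other,
                                           gsites, threshold))
    rows = {}
    for gene in gene_order:
        row: dict[str, object] = {"gene": gene}
        for rec in records:
            if rec.gene == gene:
                for f in _ROW_FIELDS:
                    row[f"{rec.population}_{f[2:] if f.startswith('n_') else f}"] = \
                        getattr(rec, f)
        rows[gene] = row
    df = pd.DataFrame(list(rows.values()))
    total = {"gene": "Total"}
    for col in df.columns:
        if col != "gene":
            total[col] = int(df[col].sum())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def correlation_of_totals(totals_a: Sequence[float],
                          totals_b: Sequence[float]) -> float:
    """Pearson correlation of per-gene site totals between two populations."""
    a = np.asarray(totals_a, dtype=float)
    b = np.asarray(totals_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of >= 3 per-gene totals")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: zero variance in a totals vector")
    return float(np.corrcoef(a, b)[0, 1])


def summary_correlation(summary: pd.DataFrame, pop_a: str, pop_b: str) -> float:
    """Pearson correlation of the two populations' per-gene totals in a table."""
    genes = summary[summary["gene"] != "Total"]
    return correlation_of_totals(genes[f"{pop_a}_total"], genes[f"{pop_b}_total"])


def render_markdown(summary: pd.DataFrame) -> str:
    """GitHub-style markdown rendering of a summary table."""
    cols = list(summary.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in summary.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def write_summary(summary: pd.DataFrame, path, *,
                  header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"## {line}\n")
        summary.to_csv(fh, sep="\t", index=False)
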