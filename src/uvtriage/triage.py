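"""Panel tiering and the diagnostic-yield summary.

Classified, non-artifact variants are intersected with two gene panels:

* ``asd_panel`` — the primary panel (the SFARI-style ASD gene list);
* ``ndd_extension`` — a literature-curated NDD list used to expand the
  analysis, applied only to genes carrying at most ``gene cap`` distinct
  class 3-5 variants cohort-wide (the "no more than three variants per
  gene" expansion rule).

Only possibly-causative variants (class 3-5) are ever tiered; a gene in
both panels resolves to the primary panel.

Diagnostic yield counts PATIENTS: a patient with at least one class 4-5
(P/LP) variant in a tiered gene counts toward yield. VUS (class 3)
patients are reported separately and never added to yield; a patient
with any P/LP finding is not double-counted in a VUS cell even when
they also carry a VUS (the VUS variant is still listed). Percentages
are rounded half-up to one decimal.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import warnings

from .acmg import AcmgClass
from .catalog import DEFAULT_GENE_CAP, CohortCatalogEntry, GeneSummary, summarize_genes
from .models import GenePanel, VariantKey, Zygosity
from .segregation import InheritanceCall, InheritanceCategory, NOT_TESTED


class Tier(str, Enum):
    ASD_PANEL = "asd_panel"
    NDD_EXTENSION = "ndd_extension"
    NONE = "none"


@dataclass(frozen=True)
class TriageRecord:
    sample_id: str
    key: VariantKey
    gene_symbol: str
    acmg_class: AcmgClass
    tier: Tier
    single_event: bool = False
    ultrarare: bool = False
    inheritance: InheritanceCall = NOT_TESTED
    zygosity: Zygosity = Zygosity.HET
    compound_het_partner: Optional[VariantKey] = None

    @property
    def is_plp(self) -> bool:
        return self.acmg_class.value >= 4

    @property
    def is_vus(self) -> bool:
        return self.acmg_class.value == 3


def round_pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (30/147 -> 20.4)."""
    if total == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def assign_tiers(
    catalog: Sequence[CohortCatalogEntry],
    classes: Mapping[VariantKey, AcmgClass],
    asd_panel: GenePanel,
    ndd_panel: GenePanel,
    gene_summaries: Optional[Sequence[GeneSummary]] = None,
    inheritance: Optional[Mapping[tuple[str, VariantKey], InheritanceCall]] = None,
    zygosities: Optional[Mapping[tuple[str, VariantKey], Zygosity]] = None,
    gene_cap: int = DEFAULT_GENE_CAP,
) -> list[TriageRecord]:
    """One TriageRecord per (carrier, non-artifact catalog entry).

    Class 3-5 variants in primary-panel genes tier as ``asd_panel``;
    class 3-5 variants in NDD-extension genes tier as ``ndd_extension``
    when the gene carries at most ``gene_cap`` distinct class 3-5
    variants cohort-wide; everything else (including every class 1-2
    variant) tiers as ``none``. Genes present in both panels resolve to
    the primary panel with a warning.
    """
    overlap = asd_panel.genes & ndd_panel.genes
    if overlap:
        warnings.warn(
            f"{len(overlap)} genes in both panels resolved to {asd_panel.name}",
            stacklevel=2,
        )
    if gene_summaries is None:
        causative_keys = {
            e.key for e in catalog
            if e.key in classes and classes[e.key].possibly_causative and not e.artifact
        }
        gene_summaries = summarize_genes(catalog, cap=gene_cap, restrict_keys=causative_keys)
    summary_by_gene = {s.gene_symbol: s for s in gene_summaries}

    records = []
    for entry in catalog:
        if entry.artifact:
            continue
        klass = classes.get(entry.key)
        if klass is None:
            continue
        gene = entry.gene_symbol
        summary = summary_by_gene.get(gene)
        if not klass.possibly_causative:
            tier = Tier.NONE
        elif gene in asd_panel:
            tier = Tier.ASD_PANEL
        elif gene in ndd_panel and summary is not None and summary.expansion_eligible:
            tier = Tier.NDD_EXTENSION
        else:
            tier = Tier.NONE
        for sample_id in sorted(entry.carrier_ids):
            inh = NOT_TESTED
            if inheritance is not None:
                inh = inheritance.get((sample_id, entry.key), NOT_TESTED)
            zyg = Zygosity.HET
            if zygosities is not None:
                zyg = zygosities.get((sample_id, entry.key), Zygosity.HET)
            records.append(
                TriageRecord(
                    sample_id=sample_id,
                    key=entry.key,
                    gene_symbol=gene,
                    acmg_class=klass,
                    tier=tier,
                    single_event=summary.single_event if summary else False,
                    ultrarare=entry.ultrarare,
                    inheritance=inh,
                    zygosity=zyg,
                )
            )
    return records


_INHERITANCE_ROWS = (
    InheritanceCategory.DE_NOVO,
    InheritanceCategory.MATERNAL,
    InheritanceCategory.PATERNAL,
    InheritanceCategory.BIPARENTAL,
    InheritanceCategory.NOT_TESTED,
    InheritanceCategory.EXCLUDED_ONE_PARENT,
)


@dataclass
class YieldCell:
    patients: frozenset[str]
    n_variants: int
    pct: float
    inheritance: dict[str, int]

    @property
    def n_patients(self) -> int:
        return len(self.patients)


@dataclass
class YieldSummary:
    """The cohort diagnostic-yield table.

    Cells are keyed by (tier, class-group) where class-group is "plp"
    (class 4-5) or "vus" (class 3); ``overall_plp`` is the union of
    P/LP-positive patients across tiers.
    """

    total_patients: int
    cells: dict[tuple[Tier, str], YieldCell]
    multi_variant: dict[Tier, int]
    overall_plp_patients: frozenset[str]

    @property
    def overall_plp_count(self) -> int:
        return len(self.overall_plp_patients)

    @property
    def overall_plp_pct(self) -> float:
        return round_pct(self.overall_plp_count, self.total_patients)

    def cell(self, tier: Tier, group: str) -> YieldCell:
        return self.cells[(tier, group)]

    def to_dict(self) -> dict:
        out = {
            "total_patients": self.total_patients,
            "overall_plp": {
                "n_patients": self.overall_plp_count,
                "pct": self.overall_plp_pct,
            },
            "cells": {},
            "patients_with_multiple_variants": {
                t.value: n for t, n in self.multi_variant.items()
            },
        }
        for (tier, group), cell in self.cells.items():
            out["cells"][f"{tier.value}.{group}"] = {
                "n_patients": cell.n_patients,
                "pct": cell.pct,
                "n_variants": cell.n_variants,
                "inheritance": dict(cell.inheritance),
            }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_table(self) -> str:
        """A text rendering in the n/total (pct%) style."""
        lines = [f"Diagnostic yield in {self.total_patients} patients"]
        for (tier, group), cell in self.cells.items():
            lines.append(
                f"  {tier.value:14s} {group.upper():4s}: "
                f"{cell.n_patients}/{self.total_patients} ({cell.pct}%), "
                f"{cell.n_variants} variants"
            )
        lines.append(
            f"  overall P/LP yield: {self.overall_plp_count}/{self.total_patients} "
            f"({self.overall_plp_pct}%)"
        )
        return "\n".join(lines)


def build_yield_summary(
    records: Sequence[TriageRecord],
    total_patients: int,
) -> YieldSummary:
    """Aggregate triage records into the yield table.

    Records are deduplicated per (sample, key); patients with any P/LP
    tiered variant are excluded from VUS patient counts (cross-tier
    precedence); multi-variant patients are attributed to the primary
    panel column when all their tiered variants are primary-panel, and
    to the extension column otherwise.
    """
    dedup: dict[tuple[str, VariantKey], TriageRecord] = {}
    for r in records:
        dedup[(r.sample_id, r.key)] = r
    tiered = [r for r in dedup.values() if r.tier is not Tier.NONE]

    n_samples = len({r.sample_id for r in dedup.values()})
    if total_patients < n_samples:
        raise ValueError(
            f"total_patients={total_patients} smaller than {n_samples} distinct samples"
        )

    plp_patients_any = frozenset(r.sample_id for r in tiered if r.is_plp)

    cells: dict[tuple[Tier, str], YieldCell] = {}
    for tier in (Tier.ASD_PANEL, Tier.NDD_EXTENSION):
        for group, pred in (("plp", lambda r: r.is_plp), ("vus", lambda r: r.is_vus)):
            subset = [r for r in tiered if r.tier is tier and pred(r)]
            patients = {r.sample_id for r in subset}
            if group == "vus":
                patients -= plp_patients_any
            inh = Counter(r.inheritance.category.value for r in subset)
            cells[(tier, group)] = YieldCell(
                patients=frozenset(patients),
                n_variants=len(subset),
                pct=round_pct(len(patients), total_patients),
                inheritance={c.value: inh.get(c.value, 0) for c in _INHERITANCE_ROWS
                             if inh.get(c.value, 0)},
            )

    variants_per_patient: dict[str, list[TriageRecord]] = {}
    for r in tiered:
        variants_per_patient.setdefault(r.sample_id, []).append(r)
    multi = {Tier.ASD_PANEL: 0, Tier.NDD_EXTENSION: 0}
    for sample_id, rs in variants_per_patient.items():
        if len(rs) < 2:
            continue
        if all(r.tier is Tier.ASD_PANEL for r in rs):
            multi[Tier.ASD_PANEL] += 1
        else:
            multi[Tier.NDD_EXTENSION] += 1

    return YieldSummary(
        total_patients=total_patients,
        cells=cells,
        multi_variant=multi,
        overall_plp_patients=plp_patients_any,
    )
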