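"""End-to-end orchestration: filter -> catalog -> artifact flag ->
classify -> segregation -> tier -> yield summary."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .acmg import AcmgClass, AcmgEvidence, CombiningRule, combine, default_rule_table
from .catalog import (
    DEFAULT_GENE_CAP,
    DEFAULT_MAX_RECURRENCE,
    CohortCatalogEntry,
    GeneSummary,
    build_catalog,
    flag_artifacts,
    summarize_genes,
)
from .filtering import FilterConfig, FilterOutcome, apply_sample_filters, kept_calls
from .models import GenePanel, Sex, VariantAnnotation, VariantCall, VariantKey
from .segregation import (
    CompoundHetCall,
    InheritanceCall,
    PatientVariant,
    cohort_inheritance,
    detect_compound_het,
)
from .triage import Tier, TriageRecord, YieldSummary, assign_tiers, build_yield_summary

logger = logging.getLogger(__name__)

_EMPTY_EVIDENCE = AcmgEvidence(frozenset())


@dataclass
class PipelineResult:
    outcomes_by_sample: dict[str, list[FilterOutcome]]
    kept_by_sample: dict[str, list[VariantCall]]
    catalog: list[CohortCatalogEntry]
    classes: dict[VariantKey, AcmgClass]
    gene_summaries: list[GeneSummary]
    inheritance: dict[tuple[str, VariantKey], InheritanceCall]
    records: list[TriageRecord]
    compound_hets: dict[str, list[CompoundHetCall]]
    summary: YieldSummary

    def stage_counts(self) -> dict[str, int]:
        return {
            "input_calls": sum(len(o) for o in self.outcomes_by_sample.values()),
            "kept_calls": sum(len(c) for c in self.kept_by_sample.values()),
            "catalog_entries": len(self.catalog),
            "artifacts": sum(1 for e in self.catalog if e.artifact),
            "tiered_asd": sum(1 for r in self.records if r.tier is Tier.ASD_PANEL),
            "tiered_ndd": sum(1 for r in self.records if r.tier is Tier.NDD_EXTENSION),
        }


def run_pipeline(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    annotations: Mapping[VariantKey, VariantAnnotation],
    evidence: Mapping[VariantKey, AcmgEvidence],
    asd_panel: GenePanel,
    ndd_panel: GenePanel,
    parent_genotypes: Optional[Mapping[tuple[str, VariantKey], str]] = None,
    pedigree_index: Optional[Mapping[str, tuple[Optional[str], Optional[str], Sex]]] = None,
    filter_config: FilterConfig = FilterConfig(),
    max_recurrence: int = DEFAULT_MAX_RECURRENCE,
    gene_cap: int = DEFAULT_GENE_CAP,
    rules: Optional[Sequence[CombiningRule]] = None,
    total_patients: Optional[int] = None,
) -> PipelineResult:
    """Run the full triage workflow on per-patient calls.

    Classification uses the supplied evidence tags; a catalog variant
    with no evidence row defaults to VUS (no criteria met).
    """
    if rules is None:
        rules = default_rule_table()

    outcomes_by_sample = {
        sid: apply_sample_filters(calls, annotations, filter_config)
        for sid, calls in calls_by_sample.items()
    }
    kept_by_sample = {sid: kept_calls(o) for sid, o in outcomes_by_sample.items()}

    catalog = build_catalog(kept_by_sample, annotations)
    catalog = flag_artifacts(catalog, max_recurrence=max_recurrence)

    classes = {
        e.key: combine(evidence.get(e.key, _EMPTY_EVIDENCE), rules)
        for e in catalog
        if not e.artifact
    }
    causative_keys = {k for k, c in classes.items() if c.possibly_causative}
    gene_summaries = summarize_genes(catalog, cap=gene_cap, restrict_keys=causative_keys)

    inheritance: dict[tuple[str, VariantKey], InheritanceCall] = {}
    if parent_genotypes is not None and pedigree_index is not None:
        inheritance = cohort_inheritance(
            kept_by_sample, dict(parent_genotypes), dict(pedigree_index)
        )

    zygosities = {
        (c.sample_id, c.key): c.zygosity
        for calls in kept_by_sample.values()
        for c in calls
    }
    records = assign_tiers(
        catalog,
        classes,
        asd_panel,
        ndd_panel,
        gene_summaries=gene_summaries,
        inheritance=inheritance,
        zygosities=zygosities,
        gene_cap=gene_cap,
    )

    compound_hets: dict[str, list[CompoundHetCall]] = {}
    per_patient: dict[str, list[TriageRecord]] = {}
    for r in records:
        per_patient.setdefault(r.sample_id, []).append(r)
    partner: dict[tuple[str, VariantKey], VariantKey] = {}
    for sid, rs in per_patient.items():
        pvs = [
            PatientVariant(
                key=r.key,
                gene_symbol=r.gene_symbol,
                acmg_class=r.acmg_class.value,
                inheritance=r.inheritance,
                zygosity=r.zygosity,
            )
            for r in rs
            if r.acmg_class.possibly_causative
        ]
        hits = detect_compound_het(pvs)
        if hits:
            compound_hets[sid] = hits
            for hit in hits:
                a, b = hit.variant_pair
                partner.setdefault((sid, a), b)
                partner.setdefault((sid, b), a)
    if partner:
        records = [
            dataclasses.replace(r, compound_het_partner=partner.get((r.sample_id, r.key)))
            for r in records
        ]

    summary = build_yield_summary(records, total_patients or len(calls_by_sample))
    logger.info("pipeline: %s", PipelineResult(
        outcomes_by_sample, kept_by_sample, catalog, classes, gene_summaries,
        inheritance, records, compound_hets, summary).stage_counts())
    return PipelineResult(
        outcomes_by_sample=outcomes_by_sample,
        kept_by_sample=kept_by_sample,
        catalog=catalog,
        classes=classes,
        gene_summaries=gene_summaries,
        inheritance=inheritance,
        records=records,
        compound_hets=compound_hets,
        summary=summary,
    )


def run_pipeline_on_cohort(cohort, **kwargs) -> PipelineResult:
    """Run the workflow on a :class:`~uvtriage.simulate.SyntheticCohort`."""
    return run_pipeline(
        calls_by_sample=cohort.calls_by_sample,
        annotations=cohort.annotations,
        evidence=cohort.evidence,
        asd_panel=cohort.asd_panel,
        ndd_panel=cohort.ndd_panel,
        parent_genotypes=cohort.parent_genotypes,
        pedigree_index=cohort.pedigree_index(),
        total_patients=len(cohort.patients),
        **kwargs,
    )
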