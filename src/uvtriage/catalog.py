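"""Cohort catalog: merge per-patient filtered variants, flag recurrence
artifacts, and summarize per-gene variant occurrence.

Filtered call sets from all patients are combined into one catalog sorted
by canonical transcript and genomic position. Variants carried by more
than ``max_recurrence`` distinct patients (more than five by default) are
presumed sequencing artifacts and flagged; flagged entries are excluded
from every downstream stage but retained in the catalog file.

Two distinct rarity notions are exposed, because both are used in
practice and they are often conflated:

* variant-level ``ultrarare``: the variant is carried by exactly one
  patient in the cohort;
* gene-level ``single_event``: the gene harbors exactly one distinct
  non-artifact variant across the whole cohort.

Recurrence counts DISTINCT CARRIER PATIENTS, not alleles: a homozygote is
one carrier. Siblings and twins each count as a carrier (a shared true
variant in a twin pair yields carrier_count 2, well below the artifact
threshold); ``count_families`` switches to counting families instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .models import Pedigree, VariantAnnotation, VariantCall, VariantKey

logger = logging.getLogger(__name__)

DEFAULT_MAX_RECURRENCE = 5
DEFAULT_GENE_CAP = 3


@dataclass(frozen=True)
class CohortCatalogEntry:
    key: VariantKey
    gene_symbol: str
    carrier_ids: frozenset[str]
    artifact: bool = False

    @property
    def carrier_count(self) -> int:
        return len(self.carrier_ids)

    @property
    def ultrarare(self) -> bool:
        """Carried by exactly one patient (and not an artifact)."""
        return self.carrier_count == 1 and not self.artifact


@dataclass(frozen=True)
class GeneSummary:
    gene_symbol: str
    distinct_variant_count: int
    cap: int = DEFAULT_GENE_CAP

    @property
    def single_event(self) -> bool:
        return self.distinct_variant_count == 1

    @property
    def expansion_eligible(self) -> bool:
        return self.distinct_variant_count <= self.cap


class GeneInconsistencyError(ValueError):
    """The same variant key is annotated to two different genes."""


def build_catalog(
    per_patient_kept: Mapping[str, Sequence[VariantCall]],
    annotations: Mapping[VariantKey, VariantAnnotation] | Iterable[VariantAnnotation],
) -> list[CohortCatalogEntry]:
    """Combine post-filter calls from all patients into a sorted catalog.

    One entry per distinct variant key; identical keys within a patient
    are deduplicated before counting carriers. Output is sorted by
    (transcript, chrom, pos, ref, alt).
    """
    if not isinstance(annotations, Mapping):
        ann_map: dict[VariantKey, VariantAnnotation] = {}
        for a in annotations:
            prev = ann_map.get(a.key)
            if prev is not None and prev.gene_symbol != a.gene_symbol:
                raise GeneInconsistencyError(
                    f"variant {a.key.chrom}:{a.key.pos} {a.key.ref}>{a.key.alt} "
                    f"annotated to both {prev.gene_symbol!r} and {a.gene_symbol!r}"
                )
            ann_map[a.key] = a
        annotations = ann_map
    carriers: dict[VariantKey, set[str]] = {}
    total_kept = 0
    for sample_id, calls in per_patient_kept.items():
        seen: set[VariantKey] = set()
        for call in calls:
            if call.key in seen:
                continue
            seen.add(call.key)
            carriers.setdefault(call.key, set()).add(sample_id)
        total_kept += len(seen)

    entries = []
    for key, ids in carriers.items():
        ann = annotations.get(key)
        gene = ann.gene_symbol if ann is not None else ""
        entries.append(CohortCatalogEntry(key=key, gene_symbol=gene, carrier_ids=frozenset(ids)))
    entries.sort(key=lambda e: e.key.sort_key)
    n_patients = len(per_patient_kept)
    if n_patients:
        logger.info(
            "catalog: %d distinct variants from %d patients (mean %.1f kept variants/patient)",
            len(entries), n_patients, total_kept / n_patients,
        )
    return entries


def flag_artifacts(
    catalog: Sequence[CohortCatalogEntry],
    max_recurrence: int = DEFAULT_MAX_RECURRENCE,
    pedigrees: Optional[Sequence[Pedigree]] = None,
    count_families: bool = False,
) -> list[CohortCatalogEntry]:
    """Flag presumed recurrence artifacts.

    An entry is an artifact when its carrier count exceeds
    ``max_recurrence`` (carrier_count 6 is eliminated under the default
    threshold of 5; carrier_count 5 is retained). With
    ``count_families=True``, carriers in the same family collapse to one
    before comparison.
    """
    if max_recurrence < 1:
        raise ValueError(f"max_recurrence must be >= 1, got {max_recurrence}")
    family_of: dict[str, str] = {}
    if count_families:
        if pedigrees is None:
            raise ValueError("count_families requires pedigrees")
        for ped in pedigrees:
            for m in ped.members:
                family_of[m.sample_id] = ped.family_id
    out = []
    n_flagged = 0
    for entry in catalog:
        if count_families:
            units = {family_of.get(s, s) for s in entry.carrier_ids}
            count = len(units)
        else:
            count = entry.carrier_count
        artifact = count > max_recurrence
        n_flagged += artifact
        out.append(replace(entry, artifact=artifact))
    logger.info("flagged %d/%d catalog entries as recurrence artifacts (> %d carriers)",
                n_flagged, len(out), max_recurrence)
    return out


def summarize_genes(
    catalog: Sequence[CohortCatalogEntry],
    cap: int = DEFAULT_GENE_CAP,
    restrict_keys: Optional[frozenset[VariantKey] | set[VariantKey]] = None,
) -> list[GeneSummary]:
    """Count distinct non-artifact variants per gene.

    ``restrict_keys`` limits the count to a subset of variant keys — used
    by the triage stage to apply the per-gene cap to class 3-5 variants
    only. Intergenic entries (empty gene) are skipped.
    """
    counts: dict[str, int] = {}
    for entry in catalog:
        if entry.artifact or not entry.gene_symbol:
            continue
        if restrict_keys is not None and entry.key not in restrict_keys:
            continue
        counts[entry.gene_symbol] = counts.get(entry.gene_symbol, 0) + 1
    return [
        GeneSummary(gene_symbol=g, distinct_variant_count=n, cap=cap)
        for g, n in sorted(counts.items())
    ]


def catalog_conservation_check(
    catalog: Sequence[CohortCatalogEntry],
    per_patient_kept: Mapping[str, Sequence[VariantCall]],
) -> bool:
    """True iff carrier counts conserve the per-patient deduplicated call total."""
    total = sum(
        len({c.key for c in calls}) for calls in per_patient_kept.values()
    )
    return sum(e.carrier_count for e in catalog) == total
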