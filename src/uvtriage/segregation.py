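"""Trio/family segregation: inheritance categories and presumed compound
heterozygosity.

Parental genotypes are taken at face value (no mosaicism or non-paternity
modelling) and no read-level phasing is attempted: every compound-het
call is "presumed", inferred from parental origin compatibility only.

X-chromosome logic: a hemizygous male child inherits his X from his
mother, so the father's genotype is irrelevant — a carrier mother gives
``maternal``, a non-carrier mother gives ``de_novo`` even when only the
mother is genotyped. Y and mitochondrial contigs are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Iterable, Optional, Sequence, Union

from .models import Sex, VariantCall, VariantKey, Zygosity, is_mitochondrial, is_x, is_y


class InheritanceCategory(str, Enum):
    DE_NOVO = "de_novo"
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BIPARENTAL = "biparental"
    NOT_TESTED = "not_tested"
    EXCLUDED_ONE_PARENT = "excluded_one_parent"


class Parent(str, Enum):
    MOTHER = "mother"
    FATHER = "father"
    NONE = "none"


class Basis(str, Enum):
    TRIO = "trio"
    SINGLE_PARENT = "single_parent"
    NONE = "none"


@dataclass(frozen=True)
class InheritanceCall:
    category: InheritanceCategory
    excluded_parent: Parent = Parent.NONE
    basis: Basis = Basis.NONE

    def __post_init__(self) -> None:
        if (self.excluded_parent is not Parent.NONE) != (
            self.category is InheritanceCategory.EXCLUDED_ONE_PARENT
        ):
            raise ValueError("excluded_parent set exactly for excluded_one_parent calls")
        if (self.basis is Basis.NONE) != (self.category is InheritanceCategory.NOT_TESTED):
            raise ValueError("basis none exactly for not_tested calls")


NOT_TESTED = InheritanceCall(InheritanceCategory.NOT_TESTED)

Genotype = Union[str, bool, None]


def _carries(gt: Genotype) -> Optional[bool]:
    """Parent carrier status from a genotype string/bool; None = unavailable."""
    if gt is None:
        return None
    if isinstance(gt, bool):
        return gt
    gt = gt.strip()
    if gt in ("", ".", "./.", ".|."):
        return None
    alleles = gt.replace("|", "/").split("/")
    return any(a not in ("0", ".") for a in alleles)


class SegregationError(ValueError):
    pass


def infer_inheritance(
    child_call: VariantCall,
    mother_gt: Genotype,
    father_gt: Genotype,
    child_sex: Sex = Sex.UNKNOWN,
    chrom: Optional[str] = None,
) -> InheritanceCall:
    """Classify a child's variant by parental carriage.

    Parent genotypes are VCF-style strings ("0/0", "0/1", "1"), booleans,
    or ``None`` when that parent was not genotyped. The child must carry
    the variant.
    """
    if chrom is None:
        chrom = child_call.key.chrom
    if is_y(chrom) or is_mitochondrial(chrom):
        raise SegregationError(f"segregation logic not defined for contig {chrom}")

    mother = _carries(mother_gt)
    father = _carries(father_gt)

    hemizygous_male = (
        is_x(chrom)
        and child_sex is Sex.MALE
        and child_call.zygosity is not Zygosity.HOM_ALT
    )
    if hemizygous_male:
        # father cannot transmit an X allele to a son
        if mother is None:
            return NOT_TESTED
        basis = Basis.TRIO if father is not None else Basis.SINGLE_PARENT
        if mother:
            return InheritanceCall(InheritanceCategory.MATERNAL, basis=basis)
        return InheritanceCall(InheritanceCategory.DE_NOVO, basis=basis)

    if mother is None and father is None:
        return NOT_TESTED
    if mother is not None and father is not None:
        if mother and father:
            return InheritanceCall(InheritanceCategory.BIPARENTAL, basis=Basis.TRIO)
        if mother:
            return InheritanceCall(InheritanceCategory.MATERNAL, basis=Basis.TRIO)
        if father:
            return InheritanceCall(InheritanceCategory.PATERNAL, basis=Basis.TRIO)
        return InheritanceCall(InheritanceCategory.DE_NOVO, basis=Basis.TRIO)
    # exactly one parent genotyped
    if mother is not None:
        if mother:
            return InheritanceCall(InheritanceCategory.MATERNAL, basis=Basis.SINGLE_PARENT)
        return InheritanceCall(
            InheritanceCategory.EXCLUDED_ONE_PARENT,
            excluded_parent=Parent.MOTHER,
            basis=Basis.SINGLE_PARENT,
        )
    assert father is not None
    if father:
        return InheritanceCall(InheritanceCategory.PATERNAL, basis=Basis.SINGLE_PARENT)
    return InheritanceCall(
        InheritanceCategory.EXCLUDED_ONE_PARENT,
        excluded_parent=Parent.FATHER,
        basis=Basis.SINGLE_PARENT,
    )


@dataclass(frozen=True)
class PatientVariant:
    """One patient's classified variant, as seen by compound-het detection."""

    key: VariantKey
    gene_symbol: str
    acmg_class: int
    inheritance: InheritanceCall
    zygosity: Zygosity = Zygosity.HET


@dataclass(frozen=True)
class CompoundHetCall:
    gene_symbol: str
    variant_pair: tuple[VariantKey, VariantKey]
    origins: tuple[InheritanceCall, InheritanceCall]
    presumed: bool = True
    note: str = "phase inferred from parental origin only (no read-backed phasing)"

    def __post_init__(self) -> None:
        if self.variant_pair[0] == self.variant_pair[1]:
            raise ValueError("compound het requires two distinct variants")


_UNKNOWN_ORIGIN = frozenset(
    {InheritanceCategory.NOT_TESTED, InheritanceCategory.EXCLUDED_ONE_PARENT,
     InheritanceCategory.BIPARENTAL}
)


def _trans_compatible(a: InheritanceCall, b: InheritanceCall) -> bool:
    """Could the two variants lie on opposite alleles?

    Yes when the parental categories differ (e.g. de novo + maternal,
    maternal + paternal) or when either origin is unresolved; no when
    both are inherited from the same parent (presumed cis).
    """
    if a.category in _UNKNOWN_ORIGIN or b.category in _UNKNOWN_ORIGIN:
        return True
    return a.category is not b.category


def detect_compound_het(
    patient_variants: Sequence[PatientVariant],
    min_class: int = 3,
) -> list[CompoundHetCall]:
    """Presumed compound-het pairs among one patient's variants.

    Only heterozygous class >= ``min_class`` variants qualify; within
    each gene, every trans-compatible pair is emitted, ordered by key.
    """
    by_gene: dict[str, list[PatientVariant]] = {}
    for pv in patient_variants:
        if pv.acmg_class < min_class or pv.zygosity is not Zygosity.HET:
            continue
        if pv.gene_symbol:
            by_gene.setdefault(pv.gene_symbol, []).append(pv)

    calls = []
    for gene in sorted(by_gene):
        variants = sorted(by_gene[gene], key=lambda pv: pv.key.sort_key)
        if len(variants) < 2:
            continue
        for a, b in combinations(variants, 2):
            if a.key == b.key:
                continue
            if _trans_compatible(a.inheritance, b.inheritance):
                calls.append(
                    CompoundHetCall(
                        gene_symbol=gene,
                        variant_pair=(a.key, b.key),
                        origins=(a.inheritance, b.inheritance),
                    )
                )
    return calls


def cohort_inheritance(
    calls_by_sample: dict[str, Sequence[VariantCall]],
    parent_genotypes: dict[tuple[str, VariantKey], Genotype],
    pedigree_index: dict[str, tuple[Optional[str], Optional[str], Sex]],
) -> dict[tuple[str, VariantKey], InheritanceCall]:
    """Infer inheritance for every (sample, variant) given a lookup of
    parental genotypes and a pedigree index sample -> (mother, father, sex)."""
    out = {}
    for sample_id, calls in calls_by_sample.items():
        mother_id, father_id, sex = pedigree_index.get(sample_id, (None, None, Sex.UNKNOWN))
        for call in calls:
            mgt = parent_genotypes.get((mother_id, call.key)) if mother_id else None
            fgt = parent_genotypes.get((father_id, call.key)) if father_id else None
            out[(sample_id, call.key)] = infer_inheritance(call, mgt, fgt, sex)
    return out
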