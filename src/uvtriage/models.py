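"""Core domain types for cohort variant triage.

Coordinates follow the VCF convention: 1-based, inclusive, on whatever
reference build the upstream pipeline used (the triage layer is
build-agnostic; no liftover is attempted).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional


class Zygosity(str, Enum):
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"


class Consequence(str, Enum):
    INTERGENIC = "intergenic"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRONIC = "intronic"
    SPLICE_CANONICAL = "splice_canonical"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    START_LOSS = "start_loss"
    STOP_LOSS = "stop_loss"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


_X_NAMES = frozenset({"X", "chrX", "x", "chrx"})
_Y_NAMES = frozenset({"Y", "chrY", "y", "chry"})
_MT_NAMES = frozenset({"MT", "chrM", "chrMT", "M", "mt"})


def is_x(chrom: str) -> bool:
    return chrom in _X_NAMES


def is_y(chrom: str) -> bool:
    return chrom in _Y_NAMES


def is_mitochondrial(chrom: str) -> bool:
    return chrom in _MT_NAMES


@functools.total_ordering
@dataclass(frozen=True)
class VariantKey:
    """A genomic variant: chromosome, 1-based position, ref and alt alleles.

    Keys carry an optional canonical transcript identifier and sort by
    (transcript_id, chrom, pos, ref, alt), the order used for the cohort
    catalog.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r} at {self.chrom}:{self.pos}")

    @property
    def sort_key(self) -> tuple:
        return (self.transcript_id, self.chrom, self.pos, self.ref, self.alt)

    def __lt__(self, other: "VariantKey") -> bool:
        if not isinstance(other, VariantKey):
            return NotImplemented
        return self.sort_key < other.sort_key


@dataclass(frozen=True)
class VariantCall:
    """One sample's genotyped observation of a variant.

    ``alt_fraction`` is the fraction of reads supporting the alternate
    allele (AD_alt / DP when both are emitted by the caller).
    """

    key: VariantKey
    sample_id: str
    zygosity: Zygosity
    read_depth: int
    alt_fraction: float

    def __post_init__(self) -> None:
        if self.read_depth < 0:
            raise ValueError(f"read_depth must be non-negative, got {self.read_depth}")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError(f"alt_fraction must be in [0, 1], got {self.alt_fraction}")

    @property
    def alt_reads(self) -> int:
        return round(self.alt_fraction * self.read_depth)


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional annotation consumed as input (the pipeline never annotates).

    ``population_freqs`` maps a reference-database label (e.g. ``1KG``,
    ``EXAC``, ``EVS``) to an allele frequency; absence from every database
    is the ultrarare signal and is treated as frequency 0.
    """

    key: VariantKey
    gene_symbol: str
    consequence: Consequence
    population_freqs: Mapping[str, float] = field(default_factory=dict)
    hgvs_c: str = ""
    hgvs_p: str = ""

    def __post_init__(self) -> None:
        for db, freq in self.population_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"population frequency for {db} out of [0, 1]: {freq}")
        if (self.consequence is Consequence.INTERGENIC) != (self.gene_symbol == ""):
            raise ValueError(
                "gene_symbol must be empty exactly when consequence is intergenic "
                f"(got gene={self.gene_symbol!r}, consequence={self.consequence.value})"
            )

    @property
    def max_population_freq(self) -> float:
        """Maximum frequency across databases; 0 when unobserved everywhere."""
        return max(self.population_freqs.values(), default=0.0)


@dataclass(frozen=True)
class Individual:
    sample_id: str
    sex: Sex = Sex.UNKNOWN
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    affected: bool = False


@dataclass
class Pedigree:
    """A family: individuals with optional parent links.

    Parent references either resolve within the pedigree or are ``None``
    (unavailable); cycles are rejected.
    """

    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate sample ids in family {self.family_id}")
        self._by_id = {m.sample_id: m for m in self.members}
        for m in self.members:
            self._check_no_cycle(m)

    def _check_no_cycle(self, start: Individual) -> None:
        seen = set()
        frontier = [start.sample_id]
        while frontier:
            sid = frontier.pop()
            if sid in seen:
                raise ValueError(f"pedigree cycle involving {sid} in family {self.family_id}")
            seen.add(sid)
            member = self._by_id.get(sid)
            if member is None:
                continue
            frontier.extend(p for p in (member.mother_id, member.father_id) if p is not None)

    def get(self, sample_id: str) -> Optional[Individual]:
        return self._by_id.get(sample_id)

    @property
    def children(self) -> list[Individual]:
        """Members with at least one parent reference."""
        return [m for m in self.members if m.mother_id or m.father_id]


@dataclass
class GenePanel:
    """A named set of gene symbols (e.g. an ASD panel or an NDD extension)."""

    name: str
    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if any(not g for g in self.genes):
            raise ValueError(f"panel {self.name!r} contains an empty gene symbol")
        self.genes = frozenset(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)
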