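"""Synthetic cohort generator with a ground-truth manifest.

Generates exome-cohort structure matching what the triage pipeline
assumes: ~147 pediatric patients averaging a few hundred post-filter
variants each, with

* private background variants that pass every per-sample filter and
  carry likely-benign evidence;
* common polymorphisms (population frequency > 1%) that the frequency
  filter must remove;
* recurrent sequencing artifacts carried by more than five patients,
  which the cohort recurrence filter must eliminate;
* planted causative P/LP and VUS variants in panel genes, each in its
  own gene (so they are single-event by construction), with ACMG
  evidence tags that combine to the intended class;
* decoy variants failing the depth or allele-fraction filter;
* trio structure for a subset of families with parental genotypes
  consistent with each planted variant's true origin (de novo variants
  absent from both parents);
* sibling pairs (a subset of them twins — twins share their entire
  variant set) and X-chromosome hemizygosity in males.

Every emitted variant is recorded in a :class:`GroundTruthManifest` with
its role and true origin, enabling exact parameter-recovery tests. All
output is deterministic given the seed; genotype observations are
noise-free (an optional parental-allele-dropout rate exists to exercise
the excluded-one-parent path).

Gene names are synthetic (G0001...); per-patient kept-variant counts are
Poisson around the configured mean (real cohorts give no per-patient
variance to emulate, so Poisson is the recorded assumption).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .acmg import AcmgEvidence
from .models import (
    Consequence,
    GenePanel,
    Individual,
    Pedigree,
    Sex,
    VariantAnnotation,
    VariantCall,
    VariantKey,
    Zygosity,
)
from . import io as uio

ROLE_CAUSATIVE = "causative_plp"
ROLE_VUS = "planted_vus"
ROLE_POLYMORPHISM = "polymorphism"
ROLE_ARTIFACT = "artifact"
ROLE_BACKGROUND = "background"
ROLE_DECOY = "decoy"

_EVIDENCE_P = ("PVS1", "PS2")       # combines to class 5
_EVIDENCE_LP = ("PS1", "PM2")       # combines to class 4
_EVIDENCE_VUS = ("PM2", "PP3")      # combines to class 3
_EVIDENCE_BENIGNISH = ("BS1", "BP4")  # combines to class 2
_EVIDENCE_COMMON = ("BA1",)          # combines to class 1

_AUTOSOMES = tuple(str(c) for c in range(1, 23))
_CHROMS = _AUTOSOMES + ("X",)

_KEPT_CONSEQUENCES = (
    Consequence.MISSENSE,
    Consequence.NONSENSE,
    Consequence.FRAMESHIFT,
    Consequence.INFRAME_INDEL,
    Consequence.SPLICE_CANONICAL,
    Consequence.SPLICE_REGION,
)
_KEPT_CONSEQUENCE_P = (0.72, 0.06, 0.08, 0.06, 0.04, 0.04)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 147
    n_genes: int = 5000
    asd_panel_size: int = 1031
    ndd_panel_size: int = 242
    mean_kept_variants_per_patient: float = 268.0
    n_artifacts: int = 20
    artifact_carriers_min: int = 6
    artifact_carriers_max: int = 40
    n_polymorphisms: int = 30
    asd_plp_rate: float = 0.20
    ndd_plp_rate: float = 0.03
    asd_vus_rate: float = 0.06
    ndd_vus_rate: float = 0.04
    asd_plp_count: Optional[int] = None
    ndd_plp_count: Optional[int] = None
    asd_vus_count: Optional[int] = None
    ndd_vus_count: Optional[int] = None
    pathogenic_fraction: float = 0.5   # of planted P/LP, fraction class 5 vs 4
    trio_fraction: float = 32 / 147
    sibling_pairs: int = 10
    twin_pairs: int = 2
    sibling_background_share: float = 0.5
    de_novo_fraction: float = 0.5
    male_fraction: float = 110 / 147
    decoy_mean_per_patient: float = 15.0
    parental_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("asd_plp_rate", "ndd_plp_rate", "asd_vus_rate", "ndd_vus_rate",
                     "trio_fraction", "de_novo_fraction", "male_fraction",
                     "sibling_background_share", "parental_dropout", "pathogenic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.asd_panel_size + self.ndd_panel_size > self.n_genes:
            raise ValueError("panel sizes exceed n_genes")
        if self.artifact_carriers_min < 1 or self.artifact_carriers_max < self.artifact_carriers_min:
            raise ValueError("invalid artifact carrier range")
        if self.n_patients < 2 * self.sibling_pairs:
            raise ValueError("more sibling pairs than patients allow")
        if self.twin_pairs > self.sibling_pairs:
            raise ValueError("twin_pairs cannot exceed sibling_pairs")
        if (self.asd_plp_rate or self.asd_plp_count) and self.asd_panel_size == 0:
            raise ValueError("causative plan requires a non-empty primary panel")
        if (self.ndd_plp_rate or self.ndd_plp_count) and self.ndd_panel_size == 0:
            raise ValueError("causative plan requires a non-empty extension panel")


@dataclass(frozen=True)
class PlantedVariant:
    key: VariantKey
    role: str
    gene: str
    carriers: tuple[str, ...]
    true_origin: Optional[str] = None      # de_novo / maternal / paternal / biparental
    evidence_tags: tuple[str, ...] = ()
    intended_class: Optional[int] = None
    expected_tier: str = "none"


@dataclass
class GroundTruthManifest:
    entries: list[PlantedVariant]

    def by_role(self, role: str) -> list[PlantedVariant]:
        return [e for e in self.entries if e.role == role]

    def role_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.role] = counts.get(e.role, 0) + 1
        return counts

    def to_json(self) -> str:
        rows = []
        for e in self.entries:
            d = dataclasses.asdict(e)
            d["key"] = dataclasses.asdict(e.key)
            rows.append(d)
        return json.dumps(rows, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        rows = json.loads(text)
        entries = []
        for d in rows:
            key = VariantKey(**d.pop("key"))
            d["carriers"] = tuple(d["carriers"])
            d["evidence_tags"] = tuple(d["evidence_tags"])
            entries.append(PlantedVariant(key=key, **d))
        return cls(entries)


@dataclass(frozen=True)
class PatientInfo:
    sample_id: str
    family_id: str
    sex: Sex
    mother_id: Optional[str]
    father_id: Optional[str]
    trio: bool


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    patients: list[PatientInfo]
    pedigrees: list[Pedigree]
    calls_by_sample: dict[str, list[VariantCall]]
    annotations: dict[VariantKey, VariantAnnotation]
    evidence: dict[VariantKey, AcmgEvidence]
    parent_genotypes: dict[tuple[str, VariantKey], str]
    asd_panel: GenePanel
    ndd_panel: GenePanel
    manifest: GroundTruthManifest

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.patients]

    def pedigree_index(self) -> dict[str, tuple[Optional[str], Optional[str], Sex]]:
        return {
            p.sample_id: (p.mother_id if p.trio else None,
                          p.father_id if p.trio else None,
                          p.sex)
            for p in self.patients
        }


class _Genome:
    """Synthetic gene map: symbol -> (chrom, transcript, position allocator)."""

    def __init__(self, n_genes: int):
        self.genes = [f"G{i + 1:04d}" for i in range(n_genes)]
        self.chrom = {g: _CHROMS[i % len(_CHROMS)] for i, g in enumerate(self.genes)}
        self.transcript = {g: f"NM_{i + 1:06d}.1" for i, g in enumerate(self.genes)}
        self._base = {g: (i + 1) * 10_000 for i, g in enumerate(self.genes)}
        self._next_offset: dict[str, int] = {}

    def new_key(self, gene: str, rng: np.random.Generator) -> VariantKey:
        offset = self._next_offset.get(gene, 0)
        self._next_offset[gene] = offset + 1
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        return VariantKey(
            chrom=self.chrom[gene],
            pos=self._base[gene] + offset,
            ref=_BASES[ref],
            alt=_BASES[alt],
            transcript_id=self.transcript[gene],
        )


def _passing_call(
    key: VariantKey, sample_id: str, zygosity: Zygosity, rng: np.random.Generator
) -> VariantCall:
    depth = int(rng.integers(20, 100))
    if zygosity is Zygosity.HET:
        alt = int(rng.integers(math.ceil(0.40 * depth), math.floor(0.60 * depth) + 1))
    else:  # hom_alt or hemi
        alt = int(rng.integers(math.ceil(0.95 * depth), depth + 1))
    return VariantCall(key, sample_id, zygosity, depth, alt / depth)


def _failing_call(
    key: VariantKey, sample_id: str, rng: np.random.Generator
) -> VariantCall:
    if rng.random() < 0.5:  # fail depth (<= 10x)
        depth = int(rng.integers(1, 11))
        alt = int(rng.integers(math.ceil(0.40 * depth), depth + 1))
    else:  # fail allele fraction (< 30%)
        depth = int(rng.integers(20, 100))
        alt = int(rng.integers(1, math.ceil(0.25 * depth)))
    return VariantCall(key, sample_id, Zygosity.HET, depth, alt / depth)


def _choose_carriers(
    patients: Sequence[PatientInfo], rate: float, count: Optional[int],
    rng: np.random.Generator,
) -> list[PatientInfo]:
    if count is not None:
        if count > len(patients):
            raise ValueError(f"planted count {count} exceeds cohort size")
        idx = rng.choice(len(patients), size=count, replace=False)
        return [patients[i] for i in sorted(idx)]
    return [p for p in patients if rng.random() < rate]


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genome = _Genome(config.n_genes)

    panel_pool = rng.permutation(config.n_genes)
    asd_genes = [genome.genes[i] for i in panel_pool[: config.asd_panel_size]]
    ndd_genes = [
        genome.genes[i]
        for i in panel_pool[config.asd_panel_size: config.asd_panel_size + config.ndd_panel_size]
    ]
    asd_panel = GenePanel("asd_panel", frozenset(asd_genes), "synthetic primary panel")
    ndd_panel = GenePanel("ndd_extension", frozenset(ndd_genes), "synthetic extension panel")
    # planting pools: private copies consumed without replacement
    asd_pool = list(asd_genes)
    ndd_pool = list(ndd_genes)
    rng.shuffle(asd_pool)
    rng.shuffle(ndd_pool)

    patients, pedigrees = _build_families(config, rng)
    trio_children = [p for p in patients if p.trio]

    annotations: dict[VariantKey, VariantAnnotation] = {}
    evidence: dict[VariantKey, AcmgEvidence] = {}
    parent_genotypes: dict[tuple[str, VariantKey], str] = {}
    calls_by_sample: dict[str, list[VariantCall]] = {p.sample_id: [] for p in patients}
    manifest_entries: list[PlantedVariant] = []

    by_family: dict[str, list[PatientInfo]] = {}
    for p in patients:
        by_family.setdefault(p.family_id, []).append(p)

    def annotate(key: VariantKey, gene: str, consequence: Consequence,
                 freqs: Optional[dict] = None) -> None:
        annotations[key] = VariantAnnotation(
            key=key, gene_symbol=gene, consequence=consequence,
            population_freqs=freqs or {},
        )

    def twin_of(p: PatientInfo) -> Optional[PatientInfo]:
        sibs = [q for q in by_family[p.family_id] if q.sample_id != p.sample_id]
        if sibs and p.family_id.startswith("TWIN"):
            return sibs[0]
        return None

    def record_parent_gts(p: PatientInfo, key: VariantKey, origin: str,
                          on_x_male: bool) -> None:
        """Parental genotype strings consistent with the true origin."""
        if not p.trio:
            return
        mother = "0/1" if origin in ("maternal", "biparental") else "0/0"
        if on_x_male:
            father = "0"  # a son's X never comes from his father
        elif key.chrom == "X":
            # fathers are hemizygous on X
            father = "1" if origin in ("paternal", "biparental") else "0"
        else:
            father = "0/1" if origin in ("paternal", "biparental") else "0/0"
        if config.parental_dropout and rng.random() < config.parental_dropout:
            # drop one parent's genotype to exercise single-parent logic
            if rng.random() < 0.5:
                mother = None
            else:
                father = None
        if mother is not None:
            parent_genotypes[(p.mother_id, key)] = mother
        if father is not None:
            parent_genotypes[(p.father_id, key)] = father

    def plant(p: PatientInfo, gene: str, tags: tuple[str, ...], intended: int,
              role: str, tier: str) -> None:
        key = genome.new_key(gene, rng)
        on_x = genome.chrom[gene] == "X"
        zyg = Zygosity.HEMI if on_x and p.sex is Sex.MALE else Zygosity.HET
        origin = _draw_origin(rng, config.de_novo_fraction, on_x and p.sex is Sex.MALE)
        annotate(key, gene, Consequence(rng.choice([c.value for c in _KEPT_CONSEQUENCES],
                                                   p=_KEPT_CONSEQUENCE_P)))
        evidence[key] = AcmgEvidence(frozenset(tags))
        carriers = [p]
        tw = twin_of(p)
        if tw is not None:
            carriers.append(tw)
        for carrier in carriers:
            calls_by_sample[carrier.sample_id].append(_passing_call(key, carrier.sample_id, zyg, rng))
            record_parent_gts(carrier, key, origin, on_x and carrier.sex is Sex.MALE)
        manifest_entries.append(
            PlantedVariant(
                key=key, role=role, gene=gene,
                carriers=tuple(c.sample_id for c in carriers),
                true_origin=origin, evidence_tags=tags,
                intended_class=intended, expected_tier=tier,
            )
        )

    # --- planted causatives and VUS, each in a fresh panel gene ---
    plans = [
        (config.asd_plp_rate, config.asd_plp_count, asd_pool, "asd_panel", True),
        (config.ndd_plp_rate, config.ndd_plp_count, ndd_pool, "ndd_extension", True),
        (config.asd_vus_rate, config.asd_vus_count, asd_pool, "asd_panel", False),
        (config.ndd_vus_rate, config.ndd_vus_count, ndd_pool, "ndd_extension", False),
    ]
    for rate, count, pool, tier, is_plp in plans:
        for p in _choose_carriers(patients, rate, count, rng):
            if not pool:
                raise ValueError(
                    f"panel gene pool exhausted while planting {tier} variants; "
                    "reduce the causative plan or enlarge the panel"
                )
            gene = pool.pop()
            if is_plp:
                pathogenic = rng.random() < config.pathogenic_fraction
                tags = _EVIDENCE_P if pathogenic else _EVIDENCE_LP
                intended = 5 if pathogenic else 4
                role = ROLE_CAUSATIVE
            else:
                tags, intended, role = _EVIDENCE_VUS, 3, ROLE_VUS
            plant(p, gene, tags, intended, role, tier)

    # --- artifacts: recurrent across > 5 patients, otherwise plausible ---
    for _ in range(config.n_artifacts):
        gene = genome.genes[int(rng.integers(config.n_genes))]
        key = genome.new_key(gene, rng)
        annotate(key, gene, Consequence.MISSENSE)
        evidence[key] = AcmgEvidence(frozenset(_EVIDENCE_VUS))
        n_carriers = int(rng.integers(config.artifact_carriers_min,
                                      config.artifact_carriers_max + 1))
        n_carriers = min(n_carriers, len(patients))
        idx = rng.choice(len(patients), size=n_carriers, replace=False)
        carriers = [patients[i] for i in sorted(idx)]
        for c in carriers:
            calls_by_sample[c.sample_id].append(
                _passing_call(key, c.sample_id, Zygosity.HET, rng)
            )
        manifest_entries.append(
            PlantedVariant(key=key, role=ROLE_ARTIFACT, gene=gene,
                           carriers=tuple(c.sample_id for c in carriers),
                           evidence_tags=_EVIDENCE_VUS, intended_class=3)
        )

    # --- common polymorphisms: population frequency above 1% ---
    for _ in range(config.n_polymorphisms):
        gene = genome.genes[int(rng.integers(config.n_genes))]
        key = genome.new_key(gene, rng)
        freq = float(rng.uniform(0.011, 0.5))
        annotate(key, gene, Consequence.MISSENSE, {"1KG": round(freq, 4)})
        evidence[key] = AcmgEvidence(frozenset(_EVIDENCE_COMMON))
        n_carriers = min(int(rng.integers(5, 60)), len(patients))
        idx = rng.choice(len(patients), size=n_carriers, replace=False)
        carriers = [patients[i] for i in sorted(idx)]
        # germline common variants: an identical twin always shares them
        expanded: list[PatientInfo] = []
        seen_ids: set[str] = set()
        for c in carriers:
            group = [c] + ([twin_of(c)] if twin_of(c) is not None else [])
            for member in group:
                if member.sample_id not in seen_ids:
                    seen_ids.add(member.sample_id)
                    expanded.append(member)
        for c in expanded:
            calls_by_sample[c.sample_id].append(
                _passing_call(key, c.sample_id, Zygosity.HET, rng)
            )
        manifest_entries.append(
            PlantedVariant(key=key, role=ROLE_POLYMORPHISM, gene=gene,
                           carriers=tuple(c.sample_id for c in expanded),
                           evidence_tags=_EVIDENCE_COMMON, intended_class=1)
        )

    # --- per-patient background + decoys ---
    # Twins duplicate the first twin's entire call set; a non-twin sibling
    # inherits a share of the first sibling's background, counted toward
    # (not on top of) their own Poisson draw so the cohort mean holds.
    # artifacts also pass the per-sample filters, so the background draw is
    # reduced by both the planted and the expected artifact load per patient
    planted_rate = (config.asd_plp_rate + config.ndd_plp_rate
                    + config.asd_vus_rate + config.ndd_vus_rate)
    artifact_rate = (
        config.n_artifacts
        * (config.artifact_carriers_min + config.artifact_carriers_max)
        / 2
        / config.n_patients
    )
    background_mean = max(
        0.0, config.mean_kept_variants_per_patient - planted_rate - artifact_rate
    )
    done_twins: set[str] = set()
    background_of: dict[str, list[VariantKey]] = {}
    bg_carriers: dict[VariantKey, list[str]] = {}
    for p in patients:
        if p.sample_id in done_twins:
            continue
        tw = twin_of(p)
        elder_sibs = [q for q in by_family[p.family_id]
                      if q.sample_id < p.sample_id] if tw is None else []

        n_before = len(calls_by_sample[p.sample_id])
        n_bg = int(rng.poisson(background_mean))
        shared: list[VariantKey] = []
        if elder_sibs:
            shared = [
                k for k in background_of.get(elder_sibs[0].sample_id, [])
                if rng.random() < config.sibling_background_share
            ]
            for key in shared:
                zyg = (Zygosity.HEMI if key.chrom == "X" and p.sex is Sex.MALE
                       else Zygosity.HET)
                calls_by_sample[p.sample_id].append(
                    _passing_call(key, p.sample_id, zyg, rng)
                )
                bg_carriers[key].append(p.sample_id)
        n_own = max(0, n_bg - len(shared))
        keys = _emit_background(
            p, n_own, genome, rng, annotations, evidence, calls_by_sample,
        )
        background_of[p.sample_id] = keys + shared
        shared_with: list[str] = [tw.sample_id] if tw is not None else []
        for key in keys:
            bg_carriers[key] = [p.sample_id, *shared_with]

        n_decoys = int(rng.poisson(config.decoy_mean_per_patient))
        for _ in range(n_decoys):
            gene = genome.genes[int(rng.integers(config.n_genes))]
            key = genome.new_key(gene, rng)
            annotate(key, gene, Consequence.MISSENSE)
            calls_by_sample[p.sample_id].append(_failing_call(key, p.sample_id, rng))
            manifest_entries.append(
                PlantedVariant(key=key, role=ROLE_DECOY, gene=gene,
                               carriers=(p.sample_id, *shared_with))
            )

        if tw is not None:
            # identical twins share this iteration's background and decoys
            done_twins.add(tw.sample_id)
            for call in calls_by_sample[p.sample_id][n_before:]:
                calls_by_sample[tw.sample_id].append(
                    dataclasses.replace(call, sample_id=tw.sample_id)
                )

    for key, carriers in bg_carriers.items():
        manifest_entries.append(
            PlantedVariant(key=key, role=ROLE_BACKGROUND,
                           gene=annotations[key].gene_symbol,
                           carriers=tuple(carriers),
                           evidence_tags=_EVIDENCE_BENIGNISH, intended_class=2)
        )

    for calls in calls_by_sample.values():
        calls.sort(key=lambda c: c.key.sort_key)
    manifest_entries.sort(key=lambda e: e.key.sort_key)

    return SyntheticCohort(
        config=config,
        patients=patients,
        pedigrees=pedigrees,
        calls_by_sample=calls_by_sample,
        annotations=annotations,
        evidence=evidence,
        parent_genotypes=parent_genotypes,
        asd_panel=asd_panel,
        ndd_panel=ndd_panel,
        manifest=GroundTruthManifest(manifest_entries),
    )


def _draw_origin(rng: np.random.Generator, de_novo_fraction: float,
                 x_male: bool) -> str:
    if rng.random() < de_novo_fraction:
        return "de_novo"
    if x_male:
        return "maternal"  # a son's X allele comes from his mother
    return "maternal" if rng.random() < 0.5 else "paternal"


def _emit_background(
    p: PatientInfo,
    n: int,
    genome: _Genome,
    rng: np.random.Generator,
    annotations: dict,
    evidence: dict,
    calls_by_sample: dict,
) -> list[VariantKey]:
    keys = []
    gene_idx = rng.integers(0, genome.genes.__len__(), size=n)
    csq_choices = rng.choice(len(_KEPT_CONSEQUENCES), size=n, p=_KEPT_CONSEQUENCE_P)
    for i in range(n):
        gene = genome.genes[int(gene_idx[i])]
        key = genome.new_key(gene, rng)
        annotations[key] = VariantAnnotation(
            key=key, gene_symbol=gene,
            consequence=_KEPT_CONSEQUENCES[int(csq_choices[i])],
        )
        evidence[key] = AcmgEvidence(frozenset(_EVIDENCE_BENIGNISH))
        on_x_male = key.chrom == "X" and p.sex is Sex.MALE
        if on_x_male:
            zyg = Zygosity.HEMI
        else:
            zyg = Zygosity.HOM_ALT if rng.random() < 0.05 else Zygosity.HET
        calls_by_sample[p.sample_id].append(_passing_call(key, p.sample_id, zyg, rng))
        keys.append(key)
    return keys


def _build_families(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[PatientInfo], list[Pedigree]]:
    patients: list[PatientInfo] = []
    n_singletons = config.n_patients - 2 * config.sibling_pairs
    family_specs: list[tuple[str, int]] = []
    for i in range(config.twin_pairs):
        family_specs.append((f"TWIN{i + 1:02d}", 2))
    for i in range(config.sibling_pairs - config.twin_pairs):
        family_specs.append((f"SIB{i + 1:02d}", 2))
    for i in range(n_singletons):
        family_specs.append((f"FAM{i + 1:03d}", 1))

    n_trios = int(round(config.trio_fraction * config.n_patients))
    # trio availability is drawn per family; twins share their parents
    trio_families: set[str] = set()
    order = rng.permutation(len(family_specs))
    budget = n_trios
    for idx in order:
        fam, n_children = family_specs[int(idx)]
        if budget <= 0:
            break
        trio_families.add(fam)
        budget -= n_children

    child_no = 0
    pedigrees = []
    for fam, n_children in family_specs:
        trio = fam in trio_families
        mother_id = f"{fam}_M"
        father_id = f"{fam}_F"
        members = []
        twin_sex: Optional[Sex] = None
        for _ in range(n_children):
            child_no += 1
            sid = f"P{child_no:04d}"
            if fam.startswith("TWIN") and twin_sex is not None:
                sex = twin_sex  # identical twins share sex
            else:
                sex = Sex.MALE if rng.random() < config.male_fraction else Sex.FEMALE
                twin_sex = sex
            patients.append(
                PatientInfo(sample_id=sid, family_id=fam, sex=sex,
                            mother_id=mother_id, father_id=father_id, trio=trio)
            )
            members.append(
                Individual(sample_id=sid, sex=sex,
                           mother_id=mother_id if trio else None,
                           father_id=father_id if trio else None,
                           affected=True)
            )
        if trio:
            members.append(Individual(sample_id=mother_id, sex=Sex.FEMALE))
            members.append(Individual(sample_id=father_id, sex=Sex.MALE))
        pedigrees.append(Pedigree(family_id=fam, members=members))
    return patients, pedigrees


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as VCF + PED + panels + evidence TSV + manifest JSON.

    Trio parents appear as VCF samples: carriers get their genotype,
    genotyped non-carriers are homozygous reference. Untested parents
    are absent from the VCF entirely.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_calls = [c for calls in cohort.calls_by_sample.values() for c in calls]
    parent_calls = []
    parent_ids = sorted({pid for (pid, _k) in cohort.parent_genotypes})
    for (pid, key), gt in cohort.parent_genotypes.items():
        if gt in ("0/0", "0", None):
            continue
        zyg = Zygosity.HEMI if gt == "1" else (
            Zygosity.HOM_ALT if gt == "1/1" else Zygosity.HET
        )
        depth = 50
        alt = depth if zyg is not Zygosity.HET else 25
        parent_calls.append(VariantCall(key, pid, zyg, depth, alt / depth))
    samples = cohort.sample_ids + parent_ids

    paths = {
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "cohort.ped",
        "evidence": outdir / "evidence.tsv",
        "asd_panel": outdir / "asd_panel.tsv",
        "ndd_panel": outdir / "ndd_panel.tsv",
        "manifest": outdir / "manifest.json",
    }
    uio.write_vcf(paths["vcf"], all_calls + parent_calls,
                  cohort.annotations.values(), samples=samples)
    uio.write_pedigree(paths["ped"], cohort.pedigrees)
    uio.write_panel(paths["asd_panel"], cohort.asd_panel)
    uio.write_panel(paths["ndd_panel"], cohort.ndd_panel)
    with open(paths["evidence"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\ttranscript\tcriteria\n")
        for key in sorted(cohort.evidence, key=lambda k: k.sort_key):
            tags = ";".join(sorted(cohort.evidence[key].criteria))
            fh.write(
                f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                f"{key.transcript_id}\t{tags}\n"
            )
    paths["manifest"].write_text(cohort.manifest.to_json())
    return paths
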