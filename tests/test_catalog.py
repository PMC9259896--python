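import numpy as np
import pytest

from uvtriage.catalog import (
    GeneInconsistencyError,
    build_catalog,
    catalog_conservation_check,
    flag_artifacts,
    summarize_genes,
)
from uvtriage.models import VariantKey

from conftest import make_annotation, make_call


def cohort_of(spec):
    """spec: {sample: [(pos, gene)]} -> (per_patient, annotations)."""
    per_patient, anns = {}, {}
    for sample, variants in spec.items():
        calls = []
        for pos, gene in variants:
            call = make_call(pos=pos, sample=sample, transcript=f"TX_{gene}")
            calls.append(call)
            anns[call.key] = make_annotation(key=call.key, gene=gene)
        per_patient[sample] = calls
    return per_patient, anns


class TestBuildCatalog:
    def test_shared_and_private_variants(self):
        per_patient, anns = cohort_of(
            {
                "A": [(100, "G1")],
                "B": [(100, "G1")],
                "C": [(100, "G1"), (200, "G2")],
            }
        )
        catalog = build_catalog(per_patient, anns)
        assert len(catalog) == 2
        counts = {e.key.pos: e.carrier_count for e in catalog}
        assert counts == {100: 3, 200: 1}

    def test_empty_cohort(self):
        assert build_catalog({}, {}) == []

    def test_twin_pair_shared_variant_not_ultrarare(self):
        per_patient, anns = cohort_of({"twin1": [(100, "G1")], "twin2": [(100, "G1")]})
        (entry,) = build_catalog(per_patient, anns)
        assert entry.carrier_count == 2
        assert not entry.ultrarare

    def test_within_patient_duplicate_keys_deduplicated(self):
        per_patient, anns = cohort_of({"A": [(100, "G1"), (100, "G1")]})
        (entry,) = build_catalog(per_patient, anns)
        assert entry.carrier_count == 1

    def test_sorted_by_transcript_then_position(self):
        per_patient, anns = cohort_of(
            {"A": [(500, "G2"), (100, "G9"), (200, "G2")]}
        )
        catalog = build_catalog(per_patient, anns)
        assert [(e.key.transcript_id, e.key.pos) for e in catalog] == [
            ("TX_G2", 200), ("TX_G2", 500), ("TX_G9", 100)
        ]

    def test_gene_conflict_is_fatal(self):
        call = make_call(pos=100, sample="A")
        conflicting = [
            make_annotation(key=call.key, gene="G1"),
            make_annotation(key=call.key, gene="G2"),
        ]
        with pytest.raises(GeneInconsistencyError, match="G1"):
            build_catalog({"A": [call]}, conflicting)


class TestFlagArtifacts:
    def make_catalog(self, carrier_counts):
        per_patient = {}
        anns = {}
        for i, n in enumerate(carrier_counts):
            for j in range(n):
                sample = f"S{j}"
                call = make_call(pos=100 + i, sample=sample)
                per_patient.setdefault(sample, []).append(call)
                anns[call.key] = make_annotation(key=call.key, gene=f"G{i}")
        return build_catalog(per_patient, anns)

    def test_recurrence_boundary(self):
        catalog = flag_artifacts(self.make_catalog([6, 5, 1]))
        flags = {e.carrier_count: e.artifact for e in catalog}
        assert flags[6] is True       # present more than five times -> eliminated
        assert flags[5] is False      # exactly five -> retained
        assert flags[1] is False
        singles = [e for e in catalog if e.carrier_count == 1]
        assert singles[0].ultrarare

    def test_monotone_in_threshold(self):
        catalog = self.make_catalog([1, 3, 5, 6, 8, 12])
        flagged = [
            {e.key for e in flag_artifacts(catalog, max_recurrence=t) if e.artifact}
            for t in (2, 5, 8, 20)
        ]
        for tighter, looser in zip(flagged, flagged[1:]):
            assert looser <= tighter

    def test_family_counting_switch(self, small_cohort):
        catalog = build_catalog(small_cohort.calls_by_sample, small_cohort.annotations)
        by_individual = flag_artifacts(catalog, pedigrees=small_cohort.pedigrees)
        by_family = flag_artifacts(
            catalog, pedigrees=small_cohort.pedigrees, count_families=True
        )
        ind_flags = {e.key for e in by_individual if e.artifact}
        fam_flags = {e.key for e in by_family if e.artifact}
        assert fam_flags <= ind_flags

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            flag_artifacts([], max_recurrence=0)


class TestGeneSummaries:
    def test_single_event_and_cap_boundaries(self):
        per_patient, anns = cohort_of(
            {
                "A": [(100, "SINGLE"), (200, "TRIPLE"), (500, "QUAD")],
                "B": [(201, "TRIPLE"), (501, "QUAD")],
                "C": [(202, "TRIPLE"), (502, "QUAD"), (503, "QUAD")],
            }
        )
        catalog = flag_artifacts(build_catalog(per_patient, anns))
        summaries = {s.gene_symbol: s for s in summarize_genes(catalog, cap=3)}
        assert summaries["SINGLE"].single_event
        assert summaries["SINGLE"].expansion_eligible
        assert not summaries["TRIPLE"].single_event
        assert summaries["TRIPLE"].expansion_eligible       # exactly 3 -> eligible
        assert not summaries["QUAD"].expansion_eligible     # 4 distinct -> excluded

    def test_artifact_variants_not_counted(self):
        per_patient, anns = cohort_of(
            {f"S{i}": [(100, "G1")] for i in range(8)} | {"S0b": [(200, "G1")]}
        )
        catalog = flag_artifacts(build_catalog(per_patient, anns))
        (summary,) = summarize_genes(catalog)
        assert summary.distinct_variant_count == 1
        assert summary.single_event


class TestConservationAndOracle:
    def test_conservation_of_carrier_counts(self, small_cohort):
        catalog = build_catalog(small_cohort.calls_by_sample, small_cohort.annotations)
        assert catalog_conservation_check(catalog, small_cohort.calls_by_sample)

    def test_brute_force_recount(self):
        rng = np.random.default_rng(11)
        per_patient, anns = {}, {}
        genes = [f"G{i}" for i in range(40)]
        for s in range(50):
            sample = f"S{s:02d}"
            calls = []
            for _ in range(int(rng.integers(5, 40))):
                pos = int(rng.integers(1, 1000))
                gene = genes[pos % len(genes)]
                call = make_call(pos=pos, sample=sample, transcript=f"TX_{gene}")
                calls.append(call)
                anns[call.key] = make_annotation(key=call.key, gene=gene)
            per_patient[sample] = calls
        catalog = flag_artifacts(build_catalog(per_patient, anns))

        # independent nested-loop recount
        for entry in catalog:
            expected = {
                sid
                for sid, calls in per_patient.items()
                if any(c.key == entry.key for c in calls)
            }
            assert entry.carrier_ids == frozenset(expected)
        per_gene = {}
        for entry in catalog:
            if not entry.artifact:
                per_gene.setdefault(entry.gene_symbol, set()).add(entry.key)
        for summary in summarize_genes(catalog):
            assert summary.distinct_variant_count == len(per_gene[summary.gene_symbol])

    def test_planted_artifacts_flagged_and_causatives_not(self, small_cohort):
        from uvtriage.simulate import ROLE_ARTIFACT, ROLE_CAUSATIVE

        catalog = flag_artifacts(
            build_catalog(small_cohort.calls_by_sample, small_cohort.annotations)
        )
        flagged = {e.key for e in catalog if e.artifact}
        artifact_keys = {e.key for e in small_cohort.manifest.by_role(ROLE_ARTIFACT)}
        causative_keys = {e.key for e in small_cohort.manifest.by_role(ROLE_CAUSATIVE)}
        assert artifact_keys <= flagged
        assert not (causative_keys & flagged)
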