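import random

import pytest

from uvtriage.acmg import AcmgClass
from uvtriage.catalog import CohortCatalogEntry, GeneSummary
from uvtriage.models import GenePanel, VariantKey
from uvtriage.triage import (
    Tier,
    TriageRecord,
    assign_tiers,
    build_yield_summary,
    round_pct,
)

from conftest import make_call

ASD = GenePanel("asd", frozenset({"A1", "A2", "A3"}))
NDD = GenePanel("ndd", frozenset({"N1", "N2"}))


def entry(pos, gene, carriers=("S1",), artifact=False):
    return CohortCatalogEntry(
        key=VariantKey("1", pos, "A", "G", f"TX_{gene}"),
        gene_symbol=gene,
        carrier_ids=frozenset(carriers),
        artifact=artifact,
    )


def summaries(counts, cap=3):
    return [GeneSummary(g, n, cap) for g, n in counts.items()]


class TestAssignTiers:
    def test_class5_in_primary_panel(self):
        e = entry(100, "A1")
        (rec,) = assign_tiers([e], {e.key: AcmgClass(5, "r")}, ASD, NDD,
                              summaries({"A1": 1}))
        assert rec.tier is Tier.ASD_PANEL
        assert rec.single_event

    def test_class4_single_event_ndd_gene(self):
        e = entry(100, "N1")
        (rec,) = assign_tiers([e], {e.key: AcmgClass(4, "r")}, ASD, NDD,
                              summaries({"N1": 1}))
        assert rec.tier is Tier.NDD_EXTENSION

    def test_class2_never_tiered(self):
        e = entry(100, "A1")
        (rec,) = assign_tiers([e], {e.key: AcmgClass(2, "r")}, ASD, NDD,
                              summaries({"A1": 1}))
        assert rec.tier is Tier.NONE

    def test_ndd_gene_over_cap_not_tiered(self):
        e = entry(100, "N1")
        (rec,) = assign_tiers([e], {e.key: AcmgClass(4, "r")}, ASD, NDD,
                              summaries({"N1": 4}))
        assert rec.tier is Tier.NONE

    def test_primary_panel_not_subject_to_cap(self):
        e = entry(100, "A1")
        (rec,) = assign_tiers([e], {e.key: AcmgClass(4, "r")}, ASD, NDD,
                              summaries({"A1": 5}))
        assert rec.tier is Tier.ASD_PANEL

    def test_non_panel_gene_not_tiered(self):
        e = entry(100, "OTHER")
        (rec,) = assign_tiers([e], {e.key: AcmgClass(5, "r")}, ASD, NDD,
                              summaries({"OTHER": 1}))
        assert rec.tier is Tier.NONE

    def test_artifact_entries_skipped(self):
        e = entry(100, "A1", artifact=True)
        assert assign_tiers([e], {e.key: AcmgClass(5, "r")}, ASD, NDD, []) == []

    def test_gene_in_both_panels_resolves_to_primary(self):
        both_ndd = GenePanel("ndd", frozenset({"A1"}))
        e = entry(100, "A1")
        with pytest.warns(UserWarning, match="both panels"):
            (rec,) = assign_tiers([e], {e.key: AcmgClass(5, "r")}, ASD, both_ndd,
                                  summaries({"A1": 1}))
        assert rec.tier is Tier.ASD_PANEL

    def test_one_record_per_carrier(self):
        e = entry(100, "A1", carriers=("S1", "S2", "S3"))
        recs = assign_tiers([e], {e.key: AcmgClass(5, "r")}, ASD, NDD,
                            summaries({"A1": 1}))
        assert sorted(r.sample_id for r in recs) == ["S1", "S2", "S3"]


def rec(sample, pos, gene, klass, tier):
    return TriageRecord(
        sample_id=sample,
        key=VariantKey("1", pos, "A", "G"),
        gene_symbol=gene,
        acmg_class=AcmgClass(klass, "r"),
        tier=tier,
    )


class TestRoundPct:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(30, 147, 20.4), (9, 147, 6.1), (4, 147, 2.7), (6, 147, 4.1),
         (34, 147, 23.1), (110, 147, 74.8), (37, 147, 25.2), (0, 147, 0.0)],
    )
    def test_half_up_one_decimal(self, count, total, expected):
        assert round_pct(count, total) == expected

    def test_zero_total(self):
        assert round_pct(0, 0) == 0.0


class TestYieldSummary:
    def test_patient_level_counting_and_percentages(self):
        records = (
            [rec(f"P{i}", 100 + i, "A1", 5, Tier.ASD_PANEL) for i in range(30)]
            + [rec(f"V{i}", 200 + i, "A2", 3, Tier.ASD_PANEL) for i in range(9)]
            + [rec(f"N{i}", 300 + i, "N1", 4, Tier.NDD_EXTENSION) for i in range(4)]
            + [rec(f"W{i}", 400 + i, "N2", 3, Tier.NDD_EXTENSION) for i in range(6)]
        )
        s = build_yield_summary(records, 147)
        assert (s.cell(Tier.ASD_PANEL, "plp").n_patients,
                s.cell(Tier.ASD_PANEL, "plp").pct) == (30, 20.4)
        assert (s.cell(Tier.ASD_PANEL, "vus").n_patients,
                s.cell(Tier.ASD_PANEL, "vus").pct) == (9, 6.1)
        assert (s.cell(Tier.NDD_EXTENSION, "plp").n_patients,
                s.cell(Tier.NDD_EXTENSION, "plp").pct) == (4, 2.7)
        assert (s.cell(Tier.NDD_EXTENSION, "vus").n_patients,
                s.cell(Tier.NDD_EXTENSION, "vus").pct) == (6, 4.1)
        assert (s.overall_plp_count, s.overall_plp_pct) == (34, 23.1)

    def test_zero_records(self):
        s = build_yield_summary([], 147)
        for cell in s.cells.values():
            assert cell.n_patients == 0 and cell.pct == 0.0
        assert s.overall_plp_count == 0

    def test_plp_takes_precedence_over_vus_for_patient_counts(self):
        records = [
            rec("P1", 100, "A1", 4, Tier.ASD_PANEL),
            rec("P1", 200, "A2", 3, Tier.ASD_PANEL),
        ]
        s = build_yield_summary(records, 147)
        assert s.cell(Tier.ASD_PANEL, "plp").n_patients == 1
        assert s.cell(Tier.ASD_PANEL, "vus").n_patients == 0
        # the VUS variant is still listed in the variant row
        assert s.cell(Tier.ASD_PANEL, "vus").n_variants == 1

    def test_cross_tier_precedence(self):
        records = [
            rec("P1", 100, "A1", 3, Tier.ASD_PANEL),
            rec("P1", 200, "N1", 4, Tier.NDD_EXTENSION),
        ]
        s = build_yield_summary(records, 147)
        assert s.cell(Tier.ASD_PANEL, "vus").n_patients == 0
        assert s.cell(Tier.NDD_EXTENSION, "plp").n_patients == 1
        assert s.multi_variant[Tier.NDD_EXTENSION] == 1

    def test_multi_variant_attribution(self):
        records = [
            rec("P1", 100, "A1", 4, Tier.ASD_PANEL),
            rec("P1", 200, "A2", 3, Tier.ASD_PANEL),
            rec("P2", 300, "A1", 4, Tier.ASD_PANEL),
        ]
        s = build_yield_summary(records, 147)
        assert s.multi_variant[Tier.ASD_PANEL] == 1
        assert s.multi_variant[Tier.NDD_EXTENSION] == 0

    def test_deduplicated_per_sample_key(self):
        r = rec("P1", 100, "A1", 5, Tier.ASD_PANEL)
        s = build_yield_summary([r, r, r], 147)
        assert s.cell(Tier.ASD_PANEL, "plp").n_variants == 1

    def test_order_invariance(self):
        records = (
            [rec(f"P{i}", 100 + i, "A1", 5, Tier.ASD_PANEL) for i in range(10)]
            + [rec(f"V{i}", 300 + i, "N1", 3, Tier.NDD_EXTENSION) for i in range(5)]
        )
        base = build_yield_summary(records, 147)
        rng = random.Random(5)
        for _ in range(5):
            shuffled = records[:]
            rng.shuffle(shuffled)
            other = build_yield_summary(shuffled, 147)
            assert other.to_dict() == base.to_dict()

    def test_counts_never_exceed_total(self):
        with pytest.raises(ValueError):
            build_yield_summary(
                [rec(f"P{i}", 100 + i, "A1", 5, Tier.ASD_PANEL) for i in range(5)], 3
            )
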