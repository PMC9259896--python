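import dataclasses
import filecmp

import numpy as np
import pytest

from uvtriage.models import Sex, Zygosity
from uvtriage.pipeline import run_pipeline_on_cohort
from uvtriage.segregation import InheritanceCategory
from uvtriage.simulate import (
    ROLE_ARTIFACT,
    ROLE_BACKGROUND,
    ROLE_CAUSATIVE,
    ROLE_DECOY,
    ROLE_POLYMORPHISM,
    ROLE_VUS,
    GroundTruthManifest,
    SimulationConfig,
    generate_cohort,
    write_cohort,
)
from uvtriage.triage import Tier

from conftest import SMALL_CONFIG


class TestConfigValidation:
    def test_panels_must_fit_genome(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=100, asd_panel_size=90, ndd_panel_size=20)

    def test_causative_plan_needs_panel(self):
        with pytest.raises(ValueError, match="panel"):
            SimulationConfig(asd_panel_size=0, ndd_panel_size=0, n_genes=10,
                             asd_plp_rate=0.2)

    def test_rates_bounded(self):
        with pytest.raises(ValueError):
            SimulationConfig(asd_plp_rate=1.2)

    def test_sibling_pairs_bounded(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_patients=10, sibling_pairs=6)


class TestStructure:
    def test_default_cohort_has_147_patients(self):
        cohort = generate_cohort(SimulationConfig(
            seed=3, mean_kept_variants_per_patient=5.0, n_genes=600,
            asd_panel_size=120, ndd_panel_size=40, decoy_mean_per_patient=1.0,
            n_artifacts=2, n_polymorphisms=2,
        ))
        assert len(cohort.patients) == 147
        assert len(cohort.calls_by_sample) == 147

    def test_panel_sizes_and_disjointness(self, small_cohort):
        assert len(small_cohort.asd_panel) == SMALL_CONFIG.asd_panel_size
        assert len(small_cohort.ndd_panel) == SMALL_CONFIG.ndd_panel_size
        assert not (small_cohort.asd_panel.genes & small_cohort.ndd_panel.genes)

    def test_twins_share_all_true_variants(self, small_cohort):
        # everything germline is shared; sequencing artifacts are per-sample
        twins = [p for p in small_cohort.patients if p.family_id.startswith("TWIN")]
        assert len(twins) == 2
        a, b = twins
        artifact_keys = {
            e.key for e in small_cohort.manifest.by_role(ROLE_ARTIFACT)
        }
        keys_a = {c.key for c in small_cohort.calls_by_sample[a.sample_id]} - artifact_keys
        keys_b = {c.key for c in small_cohort.calls_by_sample[b.sample_id]} - artifact_keys
        assert keys_a == keys_b
        assert a.sex == b.sex

    def test_x_variants_hemizygous_in_males(self, small_cohort):
        for p in small_cohort.patients:
            for call in small_cohort.calls_by_sample[p.sample_id]:
                if call.key.chrom == "X" and p.sex is Sex.MALE:
                    assert call.zygosity is Zygosity.HEMI

    def test_artifact_carrier_range(self, small_cohort):
        for e in small_cohort.manifest.by_role(ROLE_ARTIFACT):
            assert SMALL_CONFIG.artifact_carriers_min <= len(e.carriers)
            assert len(e.carriers) <= SMALL_CONFIG.artifact_carriers_max

    def test_polymorphisms_have_common_frequency(self, small_cohort):
        for e in small_cohort.manifest.by_role(ROLE_POLYMORPHISM):
            ann = small_cohort.annotations[e.key]
            assert ann.max_population_freq > 0.01

    def test_trio_parent_genotypes_consistent_with_origin(self, small_cohort):
        trio_ids = {p.sample_id: p for p in small_cohort.patients if p.trio}
        for e in small_cohort.manifest.entries:
            if e.role not in (ROLE_CAUSATIVE, ROLE_VUS) or e.true_origin is None:
                continue
            for sid in e.carriers:
                p = trio_ids.get(sid)
                if p is None:
                    continue
                mgt = small_cohort.parent_genotypes.get((p.mother_id, e.key))
                assert mgt is not None
                mother_carries = "1" in mgt
                if e.true_origin == "de_novo":
                    assert not mother_carries
                elif e.true_origin == "maternal":
                    assert mother_carries


class TestDeterminismAndPlans:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = dataclasses.replace(SMALL_CONFIG, seed=99)
        paths1 = write_cohort(generate_cohort(cfg), tmp_path / "a")
        paths2 = write_cohort(generate_cohort(cfg), tmp_path / "b")
        for name in paths1:
            assert filecmp.cmp(paths1[name], paths2[name], shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        c1 = generate_cohort(dataclasses.replace(SMALL_CONFIG, seed=1))
        c2 = generate_cohort(dataclasses.replace(SMALL_CONFIG, seed=2))
        k1 = {e.key for e in c1.manifest.by_role(ROLE_CAUSATIVE)}
        k2 = {e.key for e in c2.manifest.by_role(ROLE_CAUSATIVE)}
        assert k1 != k2

    def test_exact_counts_when_plans_given_as_counts(self):
        cfg = dataclasses.replace(
            SMALL_CONFIG,
            asd_plp_count=5, ndd_plp_count=2, asd_vus_count=3, ndd_vus_count=1,
            seed=13,
        )
        manifest = generate_cohort(cfg).manifest
        assert len(manifest.by_role(ROLE_CAUSATIVE)) == 7
        assert len(manifest.by_role(ROLE_VUS)) == 4
        tiers = [e.expected_tier for e in manifest.by_role(ROLE_CAUSATIVE)]
        assert tiers.count("asd_panel") == 5 and tiers.count("ndd_extension") == 2

    def test_rate_plans_within_binomial_bounds(self):
        # 99% two-sided binomial bound for n=147, p=0.20
        from scipy.stats import binom

        cfg = SimulationConfig(
            seed=5, mean_kept_variants_per_patient=3.0, n_genes=2000,
            n_artifacts=0, n_polymorphisms=0, decoy_mean_per_patient=0.0,
        )
        manifest = generate_cohort(cfg).manifest
        n_asd_plp = sum(
            1 for e in manifest.by_role(ROLE_CAUSATIVE) if e.expected_tier == "asd_panel"
        )
        lo, hi = binom.ppf([0.005, 0.995], 147, cfg.asd_plp_rate)
        assert lo <= n_asd_plp <= hi

    def test_manifest_json_round_trip(self, small_cohort):
        text = small_cohort.manifest.to_json()
        back = GroundTruthManifest.from_json(text)
        assert back.entries == small_cohort.manifest.entries


class TestNoiseFreeEquality:
    def test_zero_noise_pipeline_output_equals_manifest(self):
        cfg = dataclasses.replace(
            SMALL_CONFIG,
            n_artifacts=0, n_polymorphisms=0, decoy_mean_per_patient=0.0, seed=21,
        )
        cohort = generate_cohort(cfg)
        result = run_pipeline_on_cohort(cohort)
        catalog_keys = {e.key for e in result.catalog}
        manifest_keys = {
            e.key
            for e in cohort.manifest.entries
            if e.role in (ROLE_CAUSATIVE, ROLE_VUS, ROLE_BACKGROUND)
        }
        assert catalog_keys == manifest_keys
        assert not any(e.artifact for e in result.catalog)


def test_mean_kept_variants_close_to_configured():
    cfg = SimulationConfig(seed=17)
    cohort = generate_cohort(cfg)
    from uvtriage.filtering import apply_sample_filters, kept_calls

    kept = [
        len({c.key for c in kept_calls(apply_sample_filters(calls, cohort.annotations))})
        for calls in cohort.calls_by_sample.values()
    ]
    mean = np.mean(kept)
    se = np.std(kept, ddof=1) / np.sqrt(len(kept))
    assert abs(mean - cfg.mean_kept_variants_per_patient) <= 3 * se
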