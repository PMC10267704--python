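"""Cascade predicates and the staged filter pipeline."""

import pytest

from famvar.errors import ConfigError, DataError, ValidationError
from famvar.prioritization import (
    CascadeConfig, ConservationThreshold, QualityThresholds, RarityThresholds,
    assign_candidate_category, index_calls, is_high_confidence,
    is_protein_altering, is_rare, run_cascade, shared_in_family,
)
from famvar.synthetic_cohort import (FamilySimConfig, PlantedVariant,
                                     simulate_families)
from famvar.variant_io import (AnnotatedVariant, Family, GenePanels, Pedigree,
                               PedigreeMember, VariantCall, VariantKey)

KEY = VariantKey("chr1", 100, "A", "G")


def call(genotype="het", total=30, variant=15, sample="S1", key=KEY):
    return VariantCall(key, sample, genotype, total, variant)


def annotated(consequence="frameshift", phylop=None, gene="GENE1", **kw):
    return AnnotatedVariant(KEY, gene, consequence, phylop=phylop, **kw)


class TestHighConfidence:
    @pytest.mark.parametrize("total,variant,expected", [
        (10, 5, True),     # every threshold exactly at its bound
        (9, 9, False),     # fails the total-read bound
        (100, 19, False),  # 19% variant reads, below the 20% bound
        (100, 20, True),   # fraction bound is inclusive
        (30, 4, False),    # fails the variant-read bound
    ])
    def test_read_support_thresholds(self, total, variant, expected):
        assert is_high_confidence(call(total=total, variant=variant)) is expected

    def test_zero_reads_with_genotype_is_a_data_error(self):
        with pytest.raises(DataError):
            is_high_confidence(call(genotype="het", total=0, variant=0))

    def test_missing_genotype_with_zero_reads_is_low_confidence(self):
        assert not is_high_confidence(call(genotype="missing", total=0, variant=0))

    def test_threshold_validation(self):
        with pytest.raises(ConfigError):
            QualityThresholds(min_variant_fraction=0.0)


class TestProteinAltering:
    @pytest.mark.parametrize("consequence,phylop,expected", [
        ("frameshift", None, True),        # truncating: conservation ignored
        ("nonsense", 0.5, True),
        ("canonical_splice", None, True),
        ("missense", 3.0, True),           # boundary is inclusive
        ("missense", 2.9, False),
        ("synonymous", 9.9, False),
        ("other", None, False),
    ])
    def test_consequence_and_conservation(self, consequence, phylop, expected):
        assert is_protein_altering(annotated(consequence, phylop)) is expected

    def test_missense_without_phylop_excluded_by_default(self):
        v = annotated("missense", None)
        assert not is_protein_altering(v)
        assert is_protein_altering(v, ConservationThreshold(
            missing_phylop_passes=True))


class TestRarity:
    def test_absent_everywhere_is_rare(self):
        assert is_rare(annotated())

    def test_any_panel_above_ceiling_fails(self):
        assert not is_rare(annotated(maf_exac=0.002))

    def test_ceiling_is_inclusive(self):
        assert is_rare(annotated(maf_dbsnp=0.001, maf_esp=0.001,
                                 maf_exac=0.001, maf_1kg=0.001))

    def test_inhouse_presence_fails_by_default(self):
        v = annotated(inhouse_present=True)
        assert not is_rare(v)
        assert is_rare(v, RarityThresholds(require_inhouse_absent=False))


class TestFamilySharing:
    FAMILY = Family("F1", (
        PedigreeMember("S1", True, True),
        PedigreeMember("S2", True, True),
    ))

    def _shared(self, calls):
        return shared_in_family(KEY, self.FAMILY, index_calls(calls))

    def test_both_index_patients_het(self):
        assert self._shared([call(sample="S1"), call(sample="S2")])

    def test_one_homozygous_reference_breaks_sharing(self):
        assert not self._shared([call(sample="S1"),
                                 call("hom_ref", 30, 0, "S2")])

    def test_missing_genotype_is_not_evidence_of_sharing(self):
        assert not self._shared([call(sample="S1"),
                                 call("missing", 0, 0, "S2")])

    def test_absent_call_record_is_a_non_carrier(self):
        assert not self._shared([call(sample="S1")])

    def test_low_quality_carrier_does_not_count(self):
        assert not self._shared([call(sample="S1"),
                                 call(sample="S2", total=8, variant=4)])


class TestCandidateCategory:
    PANELS = GenePanels(gwas_ibd=frozenset({"NOD2"}),
                        pid=frozenset({"BTK", "NOD2"}),
                        pathway=frozenset({"SIRPB1"}))

    def test_gwas_panel_wins(self):
        # NOD2 sits on two panels; the GWAS category has precedence
        assert assign_candidate_category(
            annotated(gene="NOD2", consequence="synonymous"), self.PANELS) == "gwas"

    def test_pathway_panel(self):
        assert assign_candidate_category(
            annotated(gene="SIRPB1"), self.PANELS) == "pathway"

    def test_off_panel_truncating_is_novel(self):
        assert assign_candidate_category(
            annotated(gene="UNKNOWN1"), self.PANELS) == "novel"

    def test_off_panel_synonymous_is_none(self):
        assert assign_candidate_category(
            annotated(gene="UNKNOWN1", consequence="synonymous"),
            self.PANELS) == "none"


class TestCascade:
    def test_planted_variant_is_the_sole_survivor(self, small_cohort):
        report = run_cascade(small_cohort.variants, small_cohort.calls,
                             small_cohort.pedigree, small_cohort.panels)
        assert {k.unique_id for k in report.final} == small_cohort.expected_survivors
        assert len(report.final) == 1

    def test_stage_counts_never_increase(self, small_cohort):
        report = run_cascade(small_cohort.variants, small_cohort.calls,
                             small_cohort.pedigree, small_cohort.panels)
        counts = [c for _, c in report.stages]
        assert counts == sorted(counts, reverse=True)
        assert report.final_keys <= {v.key for v in small_cohort.variants}

    def test_sharing_and_rarity_stages_commute(self, small_cohort):
        args = (small_cohort.variants, small_cohort.calls,
                small_cohort.pedigree, small_cohort.panels)
        assert (run_cascade(*args).final
                == run_cascade(*args, swap_shared_rare=True).final)

    def test_each_stage_is_idempotent(self, small_cohort):
        report = run_cascade(small_cohort.variants, small_cohort.calls,
                             small_cohort.pedigree, small_cohort.panels)
        survivors = [v for v in small_cohort.variants if v.key in report.final]
        again = run_cascade(survivors, small_cohort.calls,
                            small_cohort.pedigree, small_cohort.panels)
        assert all(count == len(survivors) for _, count in again.stages)

    def test_common_planted_variant_removed_exactly_at_rarity(self):
        # one planted variant carrying a too-high reference frequency: it
        # survives up to the sharing stage and the rarity stage removes it,
        # dropping the count by exactly one
        sim = simulate_families(FamilySimConfig(
            seed=5, n_background_variants=0,
            planted=(PlantedVariant(gene="SIRPB1",
                                    mafs=(("maf_exac", 0.01),)),)))
        assert sim.truth[0].survives is False
        assert sim.truth[0].reason == "rarity"
        report = run_cascade(sim.variants, sim.calls, sim.pedigree, sim.panels)
        stages = dict(report.stages)
        assert stages["family_shared_protein_altering"] == 1
        assert stages["rare"] == 0
        assert report.final == {}

    def test_empty_input_reports_zeros(self, small_cohort):
        report = run_cascade([], [], small_cohort.pedigree, small_cohort.panels)
        assert all(count == 0 for _, count in report.stages)

    def test_empty_pedigree_is_an_error(self, small_cohort):
        with pytest.raises(ValidationError):
            run_cascade(small_cohort.variants, small_cohort.calls,
                        Pedigree(()), small_cohort.panels)

    def test_pass_list_restricts_final_set(self, small_cohort):
        config = CascadeConfig(pass_list=frozenset())
        report = run_cascade(small_cohort.variants, small_cohort.calls,
                             small_cohort.pedigree, small_cohort.panels,
                             config)
        assert report.final == {} and report.stages[-1] == ("pass_list", 0)

    def test_report_files(self, tmp_path, small_cohort):
        report = run_cascade(small_cohort.variants, small_cohort.calls,
                             small_cohort.pedigree, small_cohort.panels)
        report.to_tsv(tmp_path / "report.tsv")
        report.to_json(tmp_path / "detail.json")
        lines = (tmp_path / "report.tsv").read_text().splitlines()
        assert lines[0] == "stage\tremaining_variants"
        assert len(lines) == len(report.stages) + 1


def test_cascade_recovers_truth_across_many_cohorts():
    """Sensitivity sweep: on 100 independently seeded cohorts every variant
    that satisfies all predicates is recovered and nothing else survives,
    re-checked against direct per-variant predicate evaluation."""
    for seed in range(100):
        sim = simulate_families(FamilySimConfig(
            seed=seed, n_families=3, members_per_family=2,
            n_background_variants=35,
            planted=(PlantedVariant(gene="SIRPB1", families=(0,)),)))
        report = run_cascade(sim.variants, sim.calls, sim.pedigree, sim.panels)
        assert {k.unique_id for k in report.final} == sim.expected_survivors
        # independent re-check of each survivor by direct predicates
        call_index = index_calls(sim.calls)
        for v in sim.variants:
            if v.key not in report.final:
                continue
            assert v.consequence not in ("synonymous", "other")
            assert is_protein_altering(v)
            assert is_rare(v)
            assert any(
                shared_in_family(v.key, fam, call_index)
                for fam in sim.pedigree.families)
            assert assign_candidate_category(v, sim.panels) != "none"
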