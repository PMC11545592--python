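import numpy as np
import pandas as pd
import pytest

from dietmb.examples import example_count_table, example_hits, example_survey
from dietmb.filtering import (
    BELOW_IDENTITY,
    BELOW_READ_THRESHOLD,
    HOST,
    KEPT_DEMOTED,
    KEPT_SPECIES,
    NO_MATCH_REASON,
    NONPREY,
    FilterConfig,
    TaxonAssignment,
    apply_read_threshold,
    assign_taxa,
    collapse_to_prey_table,
    harmonise_with_field_survey,
    run_filter_pipeline,
)
from dietmb.io import (
    FieldSurveyTable,
    ReadCountTable,
    TaxonomyHit,
    ValidationError,
)


def table_from(counts, samples=None, otus=None):
    arr = np.asarray(counts)
    samples = samples or [f"S{i}" for i in range(arr.shape[0])]
    otus = otus or [f"OTU{i}" for i in range(arr.shape[1])]
    return ReadCountTable(pd.DataFrame(arr, index=samples, columns=otus))


def hit(otu, taxon, identity=100.0, coverage=100.0):
    return TaxonomyHit(otu, taxon, identity, coverage, 500.0, "ACC.1")


def survey_from(rows):
    return FieldSurveyTable(
        pd.DataFrame(rows, columns=["group", "genus", "species", "count"])
    )


class TestReadThreshold:
    def test_zero_threshold_is_identity(self):
        table = table_from([[10, 0], [5, 5]])
        out, audit = apply_read_threshold(table, 0.0)
        pd.testing.assert_frame_equal(out.counts, table.counts)
        assert audit == []

    def test_boundary_is_inclusive(self):
        """At 10,000 total reads and a 0.01% threshold the cutoff is exactly
        one read: a single-read OTU is kept, a zero-read OTU removed."""
        table = table_from([[9000, 1, 0], [999, 0, 0]])
        assert table.total_reads == 10_000
        out, audit = apply_read_threshold(table, 1e-4)
        assert out.otu_ids == ["OTU0", "OTU1"]
        assert [a["otu_id"] for a in audit] == ["OTU2"]
        assert audit[0]["reason"] == BELOW_READ_THRESHOLD

    def test_just_below_cutoff_removed(self):
        # 99 of 1,000,000 reads = 0.0099% < 0.01%
        table = table_from([[999_901, 99]])
        assert table.total_reads == 1_000_000
        out, audit = apply_read_threshold(table, 1e-4)
        assert out.otu_ids == ["OTU0"]
        assert audit[0]["otu_id"] == "OTU1"

    def test_cutoff_computed_once_from_input_total(self):
        """The cutoff uses the pre-filter grand total, not a shrinking one."""
        # OTU1 has 100/1,000,000 = exactly 0.01%: kept even though removing
        # OTU2 first would not change its fate, the audit shows one pass.
        table = table_from([[999_850, 100, 50]])
        out, _ = apply_read_threshold(table, 1e-4)
        assert out.otu_ids == ["OTU0", "OTU1"]

    def test_per_sample_mode_zeroes_cells(self):
        table = table_from([[10_000, 1], [0, 5_000]])
        out, _ = apply_read_threshold(table, 1e-3, per_sample=True)
        # 1 read of 10,001 in sample S0 is below 0.1% of that sample
        assert out.counts.at["S0", "OTU1"] == 0
        assert out.counts.at["S1", "OTU1"] == 5_000


class TestAssignTaxa:
    def test_identity_below_threshold_dropped(self):
        (a,) = assign_taxa([hit("O1", "Zacco temminckii", identity=96.9)], FilterConfig())
        assert a.status == "dropped" and a.reason == BELOW_IDENTITY

    def test_identity_at_threshold_kept(self):
        (a,) = assign_taxa([hit("O1", "Zacco temminckii", identity=97.0)], FilterConfig())
        assert a.status == "kept" and a.reason == KEPT_SPECIES
        assert a.prey_group == "fish"

    def test_host_dropped(self):
        (a,) = assign_taxa([hit("O1", "Odontobutis obscurus")], FilterConfig())
        assert a.reason == HOST

    def test_no_match_dropped(self):
        (a,) = assign_taxa([hit("O1", "no match", identity=0.0)], FilterConfig())
        assert a.reason == NO_MATCH_REASON

    @pytest.mark.parametrize("taxon", ["Fungi sp.", "Chromista sp.", "Bos taurus"])
    def test_nonprey_dropped(self, taxon):
        (a,) = assign_taxa([hit("O1", taxon)], FilterConfig())
        assert a.reason == NONPREY

    def test_unmapped_genus_errors_with_taxon_name(self):
        with pytest.raises(ValidationError, match="Salmo trutta"):
            assign_taxa([hit("O1", "Salmo trutta")], FilterConfig())

    def test_duplicate_otu_rejected(self):
        hits = [hit("O1", "Zacco temminckii"), hit("O1", "Zacco temminckii")]
        with pytest.raises(ValidationError, match="duplicate"):
            assign_taxa(hits, FilterConfig())

    def test_optional_coverage_floor(self):
        cfg = FilterConfig(min_query_coverage=90.0)
        (a,) = assign_taxa([hit("O1", "Zacco temminckii", coverage=80.0)], cfg)
        assert a.status == "dropped"


class TestHarmonise:
    survey = survey_from(
        [
            ("fish", "Zacco", "Z. temminckii", 100),
            ("fish", "Micropterus", "M. salmoides", 10),
            ("benthic_invertebrate", "Radix", "R. auricularia", 30),
        ]
    )

    def kept(self, taxon, group="fish"):
        return TaxonAssignment("O1", taxon, group, "kept", KEPT_SPECIES)

    def test_species_absent_genus_present_demoted(self):
        (a,) = harmonise_with_field_survey([self.kept("Zacco platypus")], self.survey)
        assert a.final_taxon == "Zacco sp."
        assert a.reason == KEPT_DEMOTED
        assert a.note == ""

    def test_species_present_unchanged(self):
        (a,) = harmonise_with_field_survey([self.kept("Micropterus salmoides")], self.survey)
        assert a.final_taxon == "Micropterus salmoides"
        assert a.reason == KEPT_SPECIES

    def test_genus_absent_demoted_and_flagged(self):
        (a,) = harmonise_with_field_survey(
            [self.kept("Hemibarbus labeo")], self.survey
        )
        assert a.final_taxon == "Hemibarbus sp."
        assert a.reason == KEPT_DEMOTED
        assert "absent" in a.note

    def test_genus_placeholder_untouched(self):
        (a,) = harmonise_with_field_survey(
            [self.kept("Radix sp.", group="benthic_invertebrate")], self.survey
        )
        assert a.final_taxon == "Radix sp."
        assert a.reason == KEPT_SPECIES

    def test_dropped_assignments_pass_through(self):
        dropped = TaxonAssignment("O2", None, None, "dropped", HOST)
        out = harmonise_with_field_survey([dropped], self.survey)
        assert out == [dropped]


class TestCollapse:
    def test_additivity_within_item(self):
        table = table_from([[3, 4]])
        assignments = [
            TaxonAssignment("OTU0", "Zacco sp. 1", "fish", "kept", KEPT_SPECIES),
            TaxonAssignment("OTU1", "Zacco sp. 2", "fish", "kept", KEPT_SPECIES),
        ]
        prey = collapse_to_prey_table(table, assignments, rank="genus")
        assert prey.items == ["Zacco sp."]
        assert prey.counts.iat[0, 0] == 7

    def test_example_taxa_collapse_15_to_13(self):
        """Two congeneric pairs merge at genus rank: 15 taxa -> 13 items."""
        hits = example_hits()
        table = example_count_table()
        assignments = assign_taxa(hits, FilterConfig())
        genus = collapse_to_prey_table(table, assignments, rank="genus")
        species = collapse_to_prey_table(table, assignments, rank="species")
        assert genus.n_items == 13
        assert species.n_items == 15

    def test_empty_samples_dropped_with_record(self):
        table = table_from([[5, 100], [0, 7]])
        assignments = [
            TaxonAssignment("OTU0", "Zacco temminckii", "fish", "kept", KEPT_SPECIES),
            TaxonAssignment("OTU1", None, None, "dropped", HOST),
        ]
        prey = collapse_to_prey_table(table, assignments, rank="genus")
        assert prey.sample_ids == ["S0"]
        assert prey.dropped_samples == ["S1"]

    def test_all_samples_empty_errors(self):
        table = table_from([[0, 9]])
        assignments = [
            TaxonAssignment("OTU0", "Zacco temminckii", "fish", "kept", KEPT_SPECIES),
            TaxonAssignment("OTU1", None, None, "dropped", HOST),
        ]
        with pytest.raises(ValidationError):
            collapse_to_prey_table(table, assignments, rank="genus")


class TestPipeline:
    def run_example(self, **cfg):
        return run_filter_pipeline(
            example_count_table(),
            example_hits(),
            example_survey(),
            FilterConfig(**cfg),
        )

    def test_audit_complete_one_reason_per_otu(self):
        result = self.run_example()
        table = example_count_table()
        assert sorted(result.audit["otu_id"]) == sorted(table.otu_ids)
        assert not result.audit["otu_id"].duplicated().any()
        assert result.audit["reason"].notna().all()

    def test_read_conservation(self):
        """Prey-table reads equal the kept OTUs' reads post-threshold."""
        result = self.run_example()
        kept = result.audit.loc[result.audit["status"] == "kept", "otu_id"]
        kept_reads = int(result.thresholded.counts[list(kept)].to_numpy().sum())
        assert result.prey.total_reads == kept_reads

    def test_order_independence_under_permutation(self):
        table = example_count_table()
        shuffled = ReadCountTable(
            table.counts.sample(frac=1, axis=0, random_state=5).sample(
                frac=1, axis=1, random_state=6
            )
        )
        a = run_filter_pipeline(table, example_hits(), example_survey())
        b = run_filter_pipeline(shuffled, example_hits(), example_survey())
        pd.testing.assert_frame_equal(
            a.prey.counts.sort_index().sort_index(axis=1),
            b.prey.counts.sort_index().sort_index(axis=1),
        )

    def test_missing_hits_become_no_match(self):
        table = table_from([[50_000, 50_000]])
        hits = [hit("OTU0", "Zacco temminckii")]
        result = run_filter_pipeline(table, hits, None)
        row = result.audit.set_index("otu_id").loc["OTU1"]
        assert row["reason"] == NO_MATCH_REASON

    def test_threshold_before_taxonomy_matters(self):
        """Removing the host before thresholding would shrink the read total
        and rescue borderline OTUs; the implemented order must not."""
        # host 900,000 reads; prey OTU A 99,950; OTU B at 60 reads:
        # 60/1,000,010 < 0.01% (dropped) but 60/100,010 > 0.01% (kept)
        table = table_from([[900_000, 99_950, 60]], otus=["H", "A", "B"])
        hits = [
            hit("H", "Odontobutis obscurus"),
            hit("A", "Zacco temminckii"),
            hit("B", "Rhinogobius brunneus"),
        ]
        canonical = run_filter_pipeline(table, hits, None)
        assert canonical.audit.set_index("otu_id").at["B", "reason"] == BELOW_READ_THRESHOLD

        # host-first alternative, spelled out manually
        no_host = table.subset_otus(["A", "B"])
        thresholded, _ = apply_read_threshold(no_host, 1e-4)
        assert "B" in thresholded.otu_ids  # order change alters the outcome

    def test_per_sample_switch_changes_outcome(self):
        # B holds 4% of the dataset (kept outright in dataset-wide mode) but
        # only 2% of sample S1, so per-sample mode zeroes that cell.
        table = table_from([[94, 6], [98, 2]], otus=["A", "B"])
        hits = [hit("A", "Zacco temminckii"), hit("B", "Rhinogobius brunneus")]
        wide = run_filter_pipeline(table, hits, None, FilterConfig(min_relative_reads=0.04))
        per = run_filter_pipeline(
            table, hits, None, FilterConfig(min_relative_reads=0.04, per_sample_threshold=True)
        )
        assert int(wide.prey.counts["Rhinogobius sp."].sum()) == 8
        assert int(per.prey.counts["Rhinogobius sp."].sum()) == 6
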