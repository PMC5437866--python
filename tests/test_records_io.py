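"""Record classification, scoring and survey-table round trips."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surveyerr import records_io as rio
from surveyerr import synthetic_world as sw
from surveyerr.errors import DomainError, InputError, IntegrityError, ParseError

from conftest import classify_campaign, make_survey


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Carex flacca", ("Carex flacca", "species")),
            ("  CAREX   flacca  ", ("Carex flacca", "species")),
            ("Carex flacca Schreb.", ("Carex flacca", "species")),
            ("Carex flacca subsp. erythrostachys", ("Carex flacca", "species")),
            ("Carex viridula var. viridula", ("Carex viridula", "species")),
            ("Carex", ("Carex", "genus")),
            ("Carex L.", ("Carex", "genus")),
        ],
    )
    def test_normalisation(self, raw, expected):
        assert rio.normalize_name(raw) == expected

    def test_empty_name_is_an_input_error(self):
        with pytest.raises(InputError):
            rio.normalize_name("   ")


class TestClassification:
    def test_invalid_combination_is_mythical(self, mini_flora):
        # a published genus with an epithet that exists nowhere in the flora
        checklist, genera, ref = mini_flora
        obs = rio.classify_observation("Calystegia arvense", ref, checklist, genera)
        assert obs.category == "mythical"
        assert obs.matched_name is None

    def test_genus_only_record_is_cautious(self, mini_flora):
        checklist, genera, ref = mini_flora
        obs = rio.classify_observation("Carex", ref, checklist, genera)
        assert obs.category == "cautious"
        assert obs.rank == "genus"
        assert obs.matched_name == "Carex"

    def test_accepted_species_is_true_positive(self, mini_flora):
        checklist, genera, ref = mini_flora
        obs = rio.classify_observation("Carex flacca", ref, checklist, genera)
        assert obs.category == "true_positive"

    def test_valid_but_unaccepted_species_is_false_positive(self, mini_flora):
        checklist, genera, ref = mini_flora
        obs = rio.classify_observation("Carex nigra", ref, checklist, genera)
        assert obs.category == "false_positive"

    def test_synonym_table_rescues_a_name(self, mini_flora):
        checklist, genera, ref = mini_flora
        obs = rio.classify_observation(
            "Poa pratensi", ref, checklist, genera, synonyms={"Poa pratensi": "Poa annua"}
        )
        assert obs.category == "true_positive"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sampled_from(
                ["Carex flacca", "Carex nigra", "Poa annua", "Viola", "Carex",
                 "Bogus inventus", "Calystegia arvense", "Poa trivialis"]
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_classification_is_total_and_counts_conserve(self, names):
        """Every record gets exactly one category; category counts sum to
        the (deduplicated) record count."""
        checklist = {"Carex flacca", "Carex nigra", "Poa annua", "Poa trivialis",
                     "Viola odorata", "Calystegia sepium"}
        genera = {"Carex", "Poa", "Viola", "Calystegia"}
        ref = rio.SiteReference("siteX", frozenset({"Carex flacca", "Poa annua"}))
        survey = rio.Survey("s1", "siteX", "o1", "2014-07-01",
                            [rio.Observation("s1", n) for n in names])
        out = rio.classify_survey(survey, ref, checklist, genera)
        assert all(o.category in rio.CATEGORIES for o in out.observations)
        assert sum(out.category_counts().values()) == len(out.observations)

    def test_fp_pool_is_union_of_per_survey_fp_sets(self):
        world = sw.generate_world(sw.WorldConfig(seed=3, n_sites=2))
        surveys = sw.simulate_dataset(world, surveys_per_site=6, seed=4)
        classified, by_site, refs = classify_campaign(world, surveys)
        for site, svs in by_site.items():
            union = set()
            for s in svs:
                union |= s.species_set(("false_positive",))
            assert refs[site].fp_pool == union
            # accepted list and fp pool never overlap
            assert not refs[site].fp_pool & refs[site].accepted_species

    def test_accepted_and_fp_pool_overlap_rejected(self):
        with pytest.raises(IntegrityError):
            rio.SiteReference("s", frozenset({"A b"}), frozenset({"A b"}))


class TestScoring:
    def test_plain_ratio(self):
        sv = make_survey("siteX", "s1", tp=[f"Sp a{i}" for i in range(50)])
        assert rio.score_survey(sv, 100).score == pytest.approx(0.50)

    def test_cautious_genus_earns_half_marks(self):
        sv = make_survey("siteX", "s1", tp=[f"Sp a{i}" for i in range(10)], cautious=["Carex"])
        assert rio.score_survey(sv, 100).score == pytest.approx(0.105)

    def test_half_marks_only_once_per_genus(self):
        sv = make_survey(
            "siteX", "s1", tp=[f"Sp a{i}" for i in range(10)], cautious=["Carex", "Carex"]
        )
        assert rio.score_survey(sv, 100).score == pytest.approx(0.105)

    def test_fp_penalty_is_reported_but_unweighted_by_default(self):
        sv = make_survey("siteX", "s1", tp=["Sp a"], fp=["Sp b", "Sp c"])
        sc = rio.score_survey(sv, 10)
        assert sc.n_false_positive == 2
        assert sc.score == pytest.approx(0.1)
        assert rio.score_survey(sv, 10, fp_penalty=0.5).score == pytest.approx(0.0)

    def test_nonpositive_gold_total_rejected(self):
        sv = make_survey("siteX", "s1", tp=["Sp a"])
        with pytest.raises(DomainError):
            rio.score_survey(sv, 0)


class TestIO:
    def test_write_read_round_trip(self, tmp_path):
        world = sw.generate_world(sw.WorldConfig(seed=7, n_sites=1))
        surveys = sw.simulate_dataset(world, surveys_per_site=3, seed=8)
        classified, _, _ = classify_campaign(world, surveys)
        path = tmp_path / "surveys.csv"
        rio.write_surveys(classified, path)
        back = rio.read_surveys(path)
        assert rio.surveys_to_frame(back).equals(rio.surveys_to_frame(classified))

    def test_missing_site_id_is_a_parse_error_naming_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "site_id,survey_id,observer_id,date,raw_name,rank\n"
            "s1,v1,o1,2014-07-01,Carex flacca,species\n"
            ",v1,o1,2014-07-01,Poa annua,species\n"
        )
        with pytest.raises(ParseError, match="row 3"):
            rio.read_surveys(path)

    def test_missing_column_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("survey_id,raw_name\nv1,Carex flacca\n")
        with pytest.raises(ParseError, match="site_id"):
            rio.read_surveys(path)

    def test_survey_id_reuse_across_sites_is_an_integrity_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "site_id,survey_id,observer_id,date,raw_name,rank\n"
            "s1,v1,o1,2014-07-01,Carex flacca,species\n"
            "s2,v1,o1,2014-07-01,Poa annua,species\n"
        )
        with pytest.raises(IntegrityError):
            rio.read_surveys(path)

    def test_column_mapping_adapter(self, tmp_path):
        path = tmp_path / "foreign.csv"
        path.write_text("Site,Visit,Who,When,Taxon\ns1,v1,o1,2014-07-01,Carex flacca\n")
        surveys = rio.read_surveys(
            path,
            colmap={"site_id": "Site", "survey_id": "Visit", "observer_id": "Who",
                    "date": "When", "raw_name": "Taxon"},
        )
        assert surveys[0].observations[0].raw_name == "Carex flacca"
        assert surveys[0].observations[0].rank == "species"

    def test_newick_reader(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
        tree = rio.read_newick(path)
        assert tree.n_tips == 4
        assert tree.n_nodes == 7
        assert sorted(tree.tip_labels) == ["A", "B", "C", "D"]

    def test_species_attribute_validation(self, tmp_path):
        path = tmp_path / "attrs.csv"
        path.write_text("species_name,genus,genus_size,occupancy\nCarex flacca,Carex,0,0.4\n")
        with pytest.raises(ParseError, match="genus_size"):
            rio.read_species_attributes(path)
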