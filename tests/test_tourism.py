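"""Unit construction, calendar splitting and the end-to-end pipeline."""
import datetime as dt

import numpy as np
import pytest

from trapdiel import (AnalysisConfig, DielSample, TouristCalendar, TraitTable,
                      TourismStudy, build_units, generate_survey,
                      split_by_calendar)
from trapdiel.simulate import SurveyDesign, default_profiles

from conftest import make_record


@pytest.fixture(scope="module")
def survey():
    return generate_survey(design=SurveyDesign(seed=17))


@pytest.fixture(scope="module")
def report(survey):
    study = TourismStudy.from_survey(survey)
    return study.fit(seed=3, bootstrap_reps=300)


class TestSplitByCalendar:
    def test_counts_conserved(self):
        recs = [make_record(day=f"2019-02-{d:02d}") for d in range(1, 11)]
        cal = TouristCalendar({dt.date(2019, 2, d): d <= 4 for d in range(1, 11)})
        present, absent = split_by_calendar(DielSample("x", recs), cal)
        assert len(present) + len(absent) == 10
        assert len(present) == 4
        assert present.class_label == "tourists present"

    def test_missing_date_is_hard_error(self):
        recs = [make_record(day="2019-02-01")]
        cal = TouristCalendar({dt.date(2019, 3, 1): True})
        with pytest.raises(KeyError):
            split_by_calendar(DielSample("x", recs), cal)


class TestBuildUnits:
    def test_default_survey_unit_families(self, survey, report):
        rules = {u.selection_rule for u in report.units}
        assert rules == {"abundant_species", "whole_community", "diel_guild",
                         "trophic_group"}
        abundant = [u for u in report.units
                    if u.selection_rule == "abundant_species"]
        assert len(abundant) == 4  # peccary, coati, agouti, deer analogues

    def test_trophic_pooling_merges_carnivores_into_omnivores(self):
        recs = ([make_record(species="deer", time=f"{h:02d}:30")
                 for h in range(6, 18)] * 5
                + [make_record(species="coati", time=f"{h:02d}:15")
                   for h in range(6, 18)] * 5
                + [make_record(species="ocelot", time=f"{h:02d}:45")
                   for h in range(0, 10)])
        traits = TraitTable(
            activity={"deer": "mostly diurnal", "coati": "diurnal",
                      "ocelot": "nocturnal"},
            diet={"deer": "herbivore", "coati": "omnivore",
                  "ocelot": "carnivore"})
        units = build_units(recs, traits)
        trophic = {u.name for u in units if u.selection_rule == "trophic_group"}
        assert trophic == {"herbivores", "omnivores and carnivores"}

    def test_guilds_plus_cathemeral_partition_community(self, report):
        community = next(u for u in report.units
                         if u.selection_rule == "whole_community")
        guilds = [u for u in report.units if u.selection_rule == "diel_guild"]
        in_guilds = set().union(*(u.member_species for u in guilds))
        cathemeral = community.member_species - in_guilds
        assert cathemeral == {"puma"}

    def test_all_cathemeral_community_warns(self):
        recs = [make_record(species="puma", time=f"{h:02d}:00")
                for h in range(10)]
        traits = TraitTable(activity={"puma": "cathemeral"},
                            diet={"puma": "carnivore"})
        with pytest.warns(UserWarning, match="guild"):
            units = build_units(recs, traits)
        assert all(u.selection_rule != "diel_guild" for u in units)

    def test_missing_trait_names_species(self):
        recs = [make_record(species="mystery")]
        traits = TraitTable(activity={}, diet={})
        with pytest.raises(KeyError, match="mystery"):
            build_units(recs, traits)


class TestTourismReport:
    def test_unit_counts_are_consistent(self, report):
        table = report.overlap_table.set_index("unit")
        comm = table.loc["whole community"]
        per_species = table[table.index.isin(
            [u.name for u in report.units
             if u.selection_rule == "abundant_species"])]
        assert per_species["n_present"].sum() <= comm["n_present"]
        trophic_names = [u.name for u in report.units
                         if u.selection_rule == "trophic_group"]
        trophic = table[table.index.isin(trophic_names)]
        if len(trophic) == len(trophic_names):  # none skipped for small n
            assert trophic["n_present"].sum() == comm["n_present"]
            assert trophic["n_absent"].sum() == comm["n_absent"]

    def test_deterministic_given_seed(self, survey):
        a = TourismStudy.from_survey(survey).fit(seed=3, bootstrap_reps=150)
        b = TourismStudy.from_survey(survey).fit(seed=3, bootstrap_reps=150)
        assert a.overlap_table.equals(b.overlap_table)
        assert a.activity_table.equals(b.activity_table)

    def test_inputs_not_mutated(self, survey):
        before = list(survey.records)
        TourismStudy.from_survey(survey).fit(seed=1, bootstrap_reps=150,
                                             compute_ci=False)
        assert survey.records == before

    def test_classifications_assigned(self, report):
        assert set(report.overlap_table["class"]) <= {"low", "moderate", "high"}

    def test_rare_units_skipped_not_failed(self, survey):
        cfg = AnalysisConfig(min_class_n=8)
        report = TourismStudy.from_survey(survey, config=cfg).fit(
            seed=2, bootstrap_reps=150, compute_ci=False)
        skipped_names = {s[0] for s in report.skipped}
        analysed = {r.unit for r in report.results}
        assert not (skipped_names & analysed)
        for _, n_p, n_a in report.skipped:
            assert min(n_p, n_a) < cfg.min_class_n

    def test_summary_mentions_every_analysed_unit(self, report):
        text = report.summary()
        for r in report.results:
            assert r.unit in text

    def test_write_csv_outputs(self, report, tmp_path):
        report.write(tmp_path)
        assert (tmp_path / "tourism_overlap.csv").exists()
        assert (tmp_path / "activity_summary.csv").exists()
        assert (tmp_path / "manifest.json").exists()
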