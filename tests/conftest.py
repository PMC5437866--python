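"""Shared fixtures: a small classified synthetic campaign and a tiny
hand-built regional flora for classification tests."""

from __future__ import annotations

import pytest

from surveyerr import records_io as rio
from surveyerr import synthetic_world as sw


def classify_campaign(world, surveys):
    """Classify a simulated campaign and rebuild references with fp pools."""
    checklist, genus_index = world.checklist()
    classified = [
        rio.classify_survey(s, world.reference(s.site_id), checklist, genus_index)
        for s in surveys
    ]
    by_site: dict[str, list] = {}
    for s in classified:
        by_site.setdefault(s.site_id, []).append(s)
    refs = {
        site: rio.build_site_reference(site, world.sites[site], svs)
        for site, svs in by_site.items()
    }
    return classified, by_site, refs


@pytest.fixture(scope="session")
def campaign():
    """Six-site default-parameter world with 12 surveys per site."""
    world = sw.generate_world(sw.WorldConfig(seed=11))
    surveys = sw.simulate_dataset(world, surveys_per_site=12, seed=12)
    classified, by_site, refs = classify_campaign(world, surveys)
    return world, classified, by_site, refs


@pytest.fixture()
def mini_flora():
    """Tiny hand-built flora: checklist, genus index, one site reference."""
    checklist = {
        "Carex flacca", "Carex nigra", "Poa annua", "Poa trivialis",
        "Viola odorata", "Calystegia sepium",
    }
    genus_index = {"Carex", "Poa", "Viola", "Calystegia"}
    ref = rio.SiteReference("siteX", frozenset({"Carex flacca", "Poa annua"}))
    return checklist, genus_index, ref


def make_survey(site_id, survey_id, tp=(), fp=(), cautious=(), mythical=()):
    """Hand-assemble a classified survey from species/genus name lists."""
    obs = []
    for name in tp:
        obs.append(rio.Observation(survey_id, name, name, "species", "true_positive"))
    for name in fp:
        obs.append(rio.Observation(survey_id, name, name, "species", "false_positive"))
    for genus in cautious:
        obs.append(rio.Observation(survey_id, genus, genus, "genus", "cautious"))
    for name in mythical:
        obs.append(rio.Observation(survey_id, name, None, "species", "mythical"))
    return rio.Survey(survey_id, site_id, f"obs-{survey_id}", "2014-07-01", obs)
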