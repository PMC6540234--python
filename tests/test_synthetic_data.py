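import numpy as np
import pandas as pd
import pytest
from scipy import stats

import comorbnet as cn
from comorbnet import records_io
from comorbnet.synthetic_data import ConfigError, GenerationError


def test_population_counts_follow_cohort_fractions():
    cfg = cn.GeneratorConfig(n_persons=10_000, seed=3)
    persons = cn.generate_population(cfg)
    assert len(persons) == 10_000
    observed = persons["cohort"].value_counts()
    expected = [cfg.cohort_fractions[c] * len(persons) for c in records_io.COHORTS]
    chi2 = stats.chisquare([observed[c] for c in records_io.COHORTS], expected)
    assert chi2.pvalue > 1e-3


def test_empty_population_is_not_an_error():
    cfg = cn.GeneratorConfig(n_persons=0, seed=0)
    persons = cn.generate_population(cfg)
    assert len(persons) == 0
    assert len(cn.generate_events(persons, cfg)) == 0
    assert len(cn.generate_mortality(persons, cfg)) == 0


def test_determinism_same_seed_identical_tables():
    cfg = cn.GeneratorConfig(n_persons=500, seed=11)
    a = cn.generate_dataset(cfg)
    b = cn.generate_dataset(cn.GeneratorConfig(n_persons=500, seed=11))
    for ta, tb in zip(a[:3], b[:3]):
        pd.testing.assert_frame_equal(ta, tb)


def test_motif_event_fraction_matches_event_rate():
    motif = cn.PlantedMotif(
        name="metabolic", codes=("E119", "I119", "E781", "E782"),
        target_cohorts=("victim",), event_rate=0.3, within_event_draw=3,
    )
    cfg = cn.GeneratorConfig(
        n_persons=500,
        cohort_fractions={"victim": 1.0, "sisben": 0.0, "other": 0.0},
        events_per_person=("fixed", {"n": 10}),
        planted_motifs=(motif,),
        mortality_motifs=(),
        victim_overlap_rate=0.0,
        seed=5,
    )
    persons = cn.generate_population(cfg)
    events = cn.generate_events(persons, cfg)
    assert len(events) == 5000
    motif_codes = set(motif.codes)
    frac = np.mean([
        sum(c in motif_codes for c in codes) >= 2
        for codes in records_io.event_code_lists(events)
    ])
    se = np.sqrt(0.3 * 0.7 / 5000)
    assert abs(frac - 0.3) < 3 * se


def test_non_target_cohort_has_no_motif_pairs(small_dataset):
    _, persons, events, _, truth = small_dataset
    other_ids = records_io.cohort_person_ids(persons, "other")
    other_events = records_io.filter_by_persons(events, other_ids)
    coupling = {"F341", "F412"}
    for codes in records_io.event_code_lists(other_events):
        assert sum(c in coupling for c in codes) == 0


def test_all_codes_valid_and_within_dx_limit(small_dataset):
    cfg, _, events, deaths, _ = small_dataset
    for codes in records_io.event_code_lists(events):
        assert 1 <= len(codes) <= cfg.max_dx_per_event
        assert len(set(codes)) == len(codes)
        assert all(cn.validate_icd10(c) for c in codes)
    for codes in records_io.death_code_lists(deaths):
        assert 1 <= len(codes) <= 4
        assert all(cn.validate_icd10(c) for c in codes)


def test_single_diagnosis_events_give_edgeless_network():
    cfg = cn.GeneratorConfig(
        n_persons=50, max_dx_per_event=1, planted_motifs=(), mortality_motifs=(),
        events_per_person=("fixed", {"n": 4}), seed=2,
    )
    events = cn.generate_events(cn.generate_population(cfg), cfg)
    net = cn.build_network(events)
    assert net.number_of_nodes() > 0 and net.number_of_edges() == 0


def test_mortality_rate_zero_gives_empty_table():
    cfg = cn.GeneratorConfig(n_persons=100, mortality_rate=0.0, seed=0,
                             planted_motifs=(), mortality_motifs=())
    assert len(cn.generate_mortality(cn.generate_population(cfg), cfg)) == 0


def test_mortality_count_near_binomial_expectation():
    cfg = cn.GeneratorConfig(n_persons=10_000, mortality_rate=0.02, seed=9,
                             planted_motifs=())
    deaths = cn.generate_mortality(cn.generate_population(cfg), cfg)
    se = np.sqrt(10_000 * 0.02 * 0.98)
    assert abs(len(deaths) - 200) < 3 * se
    assert deaths["person_id"].is_unique


def test_planted_mortality_clique_realised(default_dataset):
    _, persons, _, deaths, truth = default_dataset
    assert truth.realized_deaths["victims_mortality_clique"]["victim"] >= 1
    victim_ids = records_io.cohort_person_ids(persons, "victim")
    clique = {"E119", "I119", "E107"}
    found = any(
        set(codes) == clique
        for codes in records_io.death_code_lists(
            records_io.filter_by_persons(deaths, victim_ids)
        )
    )
    assert found


def test_unrealised_plant_fails_loudly():
    motif = cn.PlantedMotif(
        name="ghost", codes=("E119", "I119"), target_cohorts=("victim",),
        event_rate=1e-9, within_event_draw=2,
    )
    cfg = cn.GeneratorConfig(
        n_persons=5, cohort_fractions={"victim": 1.0, "sisben": 0.0, "other": 0.0},
        events_per_person=("fixed", {"n": 1}), planted_motifs=(motif,),
        mortality_motifs=(), seed=0,
    )
    with pytest.raises(GenerationError):
        cn.generate_events(cn.generate_population(cfg), cfg)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"cohort_fractions": {"victim": 0.5, "sisben": 0.2, "other": 0.2}},
        {"mortality_rate": 1.5},
        {"max_dx_per_event": 0},
        {"n_persons": -1},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigError):
        cn.GeneratorConfig(**kwargs).validate()


def test_invalid_planted_code_rejected():
    with pytest.raises(ConfigError):
        cn.GeneratorConfig(
            planted_motifs=(
                cn.PlantedMotif(name="bad", codes=("E119", "XX!"), target_cohorts=("victim",),
                                event_rate=0.1, within_event_draw=2),
            )
        ).validate()


def test_motif_draw_must_fit_event():
    with pytest.raises(ConfigError):
        cn.GeneratorConfig(max_dx_per_event=2).validate()  # default motifs draw 3


def test_write_dataset_round_trips(tmp_path):
    cfg = cn.GeneratorConfig(n_persons=300, seed=4)
    paths = cn.synthetic_data.write_dataset(cfg, tmp_path)
    assert all(p.exists() for p in paths.values())
    persons = records_io.read_persons(paths["persons"])
    events = records_io.read_events(paths["events"])
    assert len(persons) == 300
    assert set(events["person_id"]) <= set(persons["person_id"])
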