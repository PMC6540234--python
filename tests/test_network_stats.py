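import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import comorbnet as cn
from comorbnet import network_stats, records_io
from helpers import make_events, random_weighted_graph


def _graph(edges):
    g = nx.Graph(source="morbidity", mode="complete", cohort=None, n_events=0)
    g.add_weighted_edges_from(edges)
    return g


class TestDegreeStrength:
    def test_uniform_triangle(self):
        ds = cn.degree_strength(_graph([("A", "B", 2), ("B", "C", 2), ("A", "C", 2)]))
        assert (ds["degree"] == 2).all() and (ds["strength"] == 4.0).all()

    def test_star(self):
        ds = cn.degree_strength(
            _graph([("HUB", "A", 1), ("HUB", "B", 1), ("HUB", "C", 1)])
        ).set_index("node")
        assert ds.loc["HUB", "degree"] == 3 and ds.loc["HUB", "strength"] == 3.0
        assert (ds.drop("HUB")["degree"] == 1).all()

    def test_matches_weight_matrix_row_sums(self):
        rng = np.random.default_rng(3)
        g = random_weighted_graph(rng, n_nodes=15, p=0.4)
        nodes = sorted(g.nodes)
        w = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        ds = cn.degree_strength(g).set_index("node")
        assert np.allclose([ds.loc[n, "strength"] for n in nodes], w.sum(axis=1))
        assert [ds.loc[n, "degree"] for n in nodes] == list((w > 0).sum(axis=1))


class TestCCDF:
    def test_counting_example(self):
        c = cn.empirical_ccdf([1, 1, 2, 3])
        assert c.values == (1.0, 2.0, 3.0)
        assert c.survival == (1.0, 0.5, 0.25)

    def test_constant_list_single_point(self):
        c = cn.empirical_ccdf([5, 5, 5])
        assert c.values == (5.0,) and c.survival == (1.0,)

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            cn.empirical_ccdf([])

    def test_evaluate_between_support_points(self):
        c = cn.empirical_ccdf([1, 1, 2, 3])
        assert c.evaluate(0.5) == 1.0
        assert c.evaluate(1.5) == 0.5
        assert c.evaluate(99) == 0.0

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=1, max_size=60))
    def test_survival_non_increasing_and_starts_at_one(self, values):
        c = cn.empirical_ccdf(values)
        assert c.survival[0] == 1.0
        assert all(a >= b for a, b in zip(c.survival, c.survival[1:]))
        assert all(0 < s <= 1 for s in c.survival)

    def test_strength_ccdf_dominates_degree_ccdf(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            g = random_weighted_graph(rng, n_nodes=int(rng.integers(5, 25)), p=0.4)
            ds = cn.degree_strength(g)
            if len(ds) == 0:
                continue
            cd = cn.empirical_ccdf(ds["degree"])
            cf = cn.empirical_ccdf(ds["strength"])
            for x in set(cd.values) | set(cf.values):
                assert cf.evaluate(x) >= cd.evaluate(x)


class TestStrengthFilter:
    def test_hand_enumeration(self):
        # strengths: A=12, B=9, C=15, D=12 -> cut at 10 keeps A, C, D
        g = _graph([("A", "B", 9), ("A", "C", 3), ("C", "D", 12)])
        out = cn.strength_filter(g, 10)
        assert set(out.nodes) == {"A", "C", "D"}
        assert {tuple(sorted(e)) for e in out.edges} == {("A", "C"), ("C", "D")}

    def test_threshold_zero_drops_isolated_nodes(self):
        g = _graph([("A", "B", 1)])
        g.add_node("LONER")
        assert set(cn.strength_filter(g, 0).nodes) == {"A", "B"}

    def test_threshold_above_max_strength_empties_network(self):
        g = _graph([("A", "B", 5)])
        assert cn.strength_filter(g, 100).number_of_nodes() == 0

    def test_one_pass_cut_is_not_idempotent_but_iterative_is(self):
        # after the one-pass cut A keeps only the A-C edge (weight 3 <= 10)
        g = _graph([("A", "B", 9), ("A", "C", 3), ("C", "D", 12)])
        once = cn.strength_filter(g, 10)
        twice = cn.strength_filter(once, 10)
        assert set(twice.nodes) < set(once.nodes)
        fixed = cn.strength_filter(g, 10, iterative=True)
        again = cn.strength_filter(fixed, 10, iterative=True)
        assert set(fixed.nodes) == set(again.nodes) == {"C", "D"}

    def test_metadata_preserved(self):
        g = _graph([("A", "B", 20)])
        g.graph["cohort"] = "victim"
        assert cn.strength_filter(g, 10).graph["cohort"] == "victim"


class TestCrudeRates:
    def _persons(self, n, cohort="other"):
        return pd.DataFrame(
            {
                "person_id": [f"P{i}" for i in range(n)],
                "sex": ["F"] * n,
                "age": [30] * n,
                "cohort": [cohort] * n,
                "victim_flag": [cohort == "victim"] * n,
            }
        )

    def test_rate_arithmetic(self):
        persons = self._persons(1000)
        events = make_events([["I10X"], ["I251"]], person_ids=["P0", "P1"])
        rates = cn.crude_rates(persons, events).set_index(["cohort", "sex", "group"])
        assert rates.loc[("other", "F", "cardiovascular"), "rate"] == 200.0

    def test_no_cases_is_zero_not_missing(self):
        rates = cn.crude_rates(self._persons(10), make_events([["J00X"]], person_ids=["P0"]))
        row = rates.set_index(["cohort", "sex", "group"]).loc[("other", "F", "metabolic")]
        assert row["rate"] == 0.0

    def test_zero_denominator_is_missing(self):
        rates = cn.crude_rates(self._persons(5), make_events([["I10X"]], person_ids=["P0"]))
        row = rates.set_index(["cohort", "sex", "group"]).loc[("victim", "F", "cardiovascular")]
        assert np.isnan(row["rate"])

    def test_person_counted_once_per_group(self):
        persons = self._persons(100)
        events = make_events([["I10X"], ["I119"], ["I251"]], person_ids=["P0", "P0", "P0"])
        rates = cn.crude_rates(persons, events).set_index(["cohort", "sex", "group"])
        assert rates.loc[("other", "F", "cardiovascular"), "cases"] == 1

    def test_scale_invariance_under_duplication(self):
        persons = self._persons(50)
        events = make_events([["I10X", "E119"], ["F412"]], person_ids=["P0", "P1"])
        base = cn.crude_rates(persons, events)
        persons2 = pd.concat(
            [persons, persons.assign(person_id=persons["person_id"] + "b")],
            ignore_index=True,
        )
        events2 = pd.concat(
            [events, events.assign(person_id=events["person_id"] + "b",
                                   event_id=events["event_id"] + "b")],
            ignore_index=True,
        )
        doubled = cn.crude_rates(persons2, events2)
        merged = base.merge(doubled, on=["cohort", "sex", "group"], suffixes=("_1", "_2"))
        assert np.allclose(merged["rate_1"], merged["rate_2"], equal_nan=True)

    def test_victims_mental_health_rate_exceeds_others(self, default_dataset):
        _, persons, events, _, _ = default_dataset
        rates = cn.crude_rates(persons, events)
        mental = rates[rates["group"] == "mental_behavioral"]
        by_cohort = mental.groupby("cohort").apply(
            lambda d: d["cases"].sum() / d["population"].sum() * 1e5,
            include_groups=False,
        )
        assert by_cohort["victim"] > by_cohort["other"]
        assert by_cohort["victim"] > by_cohort["sisben"]


def test_ccdf_csv_round_trip(tmp_path):
    c = cn.empirical_ccdf([1, 2, 2, 5])
    c.to_csv(tmp_path / "ccdf.csv")
    back = pd.read_csv(tmp_path / "ccdf.csv")
    assert list(back["value"]) == list(c.values)
    assert np.allclose(back["survival"], c.survival)


def test_plot_ccdf_writes_file(tmp_path):
    c = cn.empirical_ccdf([1, 2, 3, 10, 50])
    network_stats.plot_ccdf({"degree": c}, tmp_path / "ccdf.png")
    assert (tmp_path / "ccdf.png").stat().st_size > 0
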