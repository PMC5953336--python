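"""Reading, recoding, and tabulating categorical panel data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import panelmix as pm
from panelmix.panel import MISSING

LAYOUT6 = {
    "items": ["Physical", "Talking", "Cultural", "Belief", "Spread", "Verbal"],
    "n_occasions": 3,
    "categories": 2,
    "id": "id",
}


def test_minimal_one_row_panel(tmp_path):
    f = tmp_path / "tiny.csv"
    f.write_text("a_t1,b_t1\n1,2\n")
    panel = pm.read_panel(f, {"items": ["a", "b"], "n_occasions": 1,
                              "categories": 2})
    assert panel.responses.shape == (1, 1, 2)
    assert panel.responses.tolist() == [[[1, 2]]]


def test_write_read_roundtrip_byte_identical(tmp_path):
    truth = pm.make_paper_like_truth(4, n_respondents=20)
    panel, _ = pm.simulate_panel(truth, seed=4)
    f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
    pm.write_panel(panel, f1)
    again = pm.read_panel(f1, LAYOUT6)
    pm.write_panel(again, f2)
    assert f1.read_bytes() == f2.read_bytes()
    assert np.array_equal(panel.responses, again.responses)


def test_out_of_range_code_names_cell(tmp_path):
    f = tmp_path / "bad.csv"
    f.write_text("a_t1,b_t1\n1,2\n5,1\n")
    with pytest.raises(pm.ValidationError, match=r"row 3.*'a'|'a'.*row 3"):
        pm.read_panel(f, {"items": ["a", "b"], "n_occasions": 1,
                          "categories": 4})


def test_unknown_column_is_configuration_error():
    df = pd.DataFrame({"a_t1": [1]})
    with pytest.raises(pm.ConfigurationError, match="b_t1"):
        pm.read_panel(df, {"items": ["a", "b"], "n_occasions": 1})


def test_long_format_reader_pivots_to_wide():
    df = pd.DataFrame({
        "id": [1, 1, 1, 1, 2, 2, 2, 2],
        "occasion": [1, 1, 2, 2, 1, 1, 2, 2],
        "item": ["a", "b"] * 4,
        "value": [1, 2, 2, 2, 1, 1, 2, 1],
    })
    panel = pm.read_panel(df, {"format": "long", "items": ["a", "b"],
                               "n_occasions": 2, "categories": 2})
    assert panel.responses.shape == (2, 2, 2)
    assert panel.responses[0].tolist() == [[1, 2], [2, 2]]


class TestCollapse:
    DICHOT = {1: 1, 2: 1, 3: 2, 4: 2}

    def make_panel(self, codes):
        resp = np.asarray(codes).reshape(1, 1, -1)
        return pm.ResponsePanel(resp, np.full(resp.shape[2], 4),
                                [f"i{k}" for k in range(resp.shape[2])])

    def test_four_point_merges_into_concern_bucket(self):
        panel = self.make_panel([4, 1, 2, 3])
        out = pm.collapse_categories(panel, self.DICHOT)
        assert out.responses[0, 0].tolist() == [2, 1, 1, 2]
        assert out.n_categories.tolist() == [2, 2, 2, 2]

    def test_identity_mapping_is_noop(self):
        panel = self.make_panel([1, 2, 3, 4])
        out = pm.collapse_categories(panel, {c: c for c in range(1, 5)})
        assert np.array_equal(out.responses, panel.responses)

    def test_missing_stays_missing(self):
        panel = self.make_panel([1, 2, 3, 4])
        panel.responses[0, 0, 1] = MISSING
        out = pm.collapse_categories(panel, self.DICHOT)
        assert out.responses[0, 0, 1] == MISSING

    def test_dichotomizing_shrinks_cell_count(self):
        rng = np.random.default_rng(0)
        resp = rng.integers(1, 5, size=(30, 3, 6))
        panel = pm.ResponsePanel(resp, np.full(6, 4),
                                 [f"i{k}" for k in range(6)])
        assert pm.pattern_frequencies(panel).W == (4 ** 6) ** 3
        out = pm.collapse_categories(panel, self.DICHOT)
        assert pm.pattern_frequencies(out).W == (2 ** 6) ** 3 == 262144

    def test_non_surjective_mapping_rejected(self):
        panel = self.make_panel([1, 2, 3, 4])
        with pytest.raises(pm.ConfigurationError):
            pm.collapse_categories(panel, {1: 1, 2: 1, 3: 3, 4: 3})
        with pytest.raises(pm.ConfigurationError):
            pm.collapse_categories(panel, {1: 1, 2: 2})


class TestMarginals:
    def test_degenerate_and_counting(self):
        resp = np.array([[[1, 1]], [[1, 1]], [[1, 2]], [[1, 2]]])
        panel = pm.ResponsePanel(resp, np.array([2, 2]), ["a", "b"])
        props = pm.marginal_proportions(panel)
        assert props.loc[("a", 1), "cat1"] == 1.0
        assert props.loc[("b", 1), "cat2"] == 0.5

    def test_three_of_four_yes(self):
        resp = np.array([[[2]], [[2]], [[2]], [[1]]])
        panel = pm.ResponsePanel(resp, np.array([2]), ["a"])
        props = pm.marginal_proportions(panel)
        assert props.loc[("a", 1), "cat2"] == 0.75

    def test_all_missing_occasion_flagged_not_zero(self):
        resp = np.array([[[1], [MISSING]], [[2], [MISSING]]])
        panel = pm.ResponsePanel(resp, np.array([2]), ["a"])
        with pytest.warns(UserWarning, match="undefined"):
            props = pm.marginal_proportions(panel)
        assert np.isnan(props.loc[("a", 2), "cat1"])

    def test_converges_to_mixture_marginals(self, paper_truth):
        # law of large numbers: observed proportions ~ sum_s delta_s rho_s
        truth = pm.make_paper_like_truth(4, n_respondents=20000,
                                         attrition=(0.0, 0.0, 0.0))
        panel, _ = pm.simulate_panel(truth, seed=77)
        props = pm.marginal_proportions(panel)
        expected = truth.delta @ truth.rho[:, :, 1]   # P(yes) per item, occ 1
        for j, item in enumerate(truth.items):
            p = expected[j]
            se = np.sqrt(p * (1 - p) / truth.n_respondents)
            assert abs(props.loc[(item, 1), "cat2"] - p) < 3 * se + 1e-9


class TestPatternFrequencies:
    def test_identical_rows_collapse_to_one_pattern(self):
        resp = np.tile([[1, 2]], (7, 1)).reshape(7, 1, 2)
        panel = pm.ResponsePanel(resp, np.array([2, 2]), ["a", "b"])
        table = pm.pattern_frequencies(panel)
        assert table.n_patterns == 1
        assert table.frequencies.tolist() == [7]

    def test_cell_count_six_binary_items_three_occasions(self, paper_panel):
        panel, _ = paper_panel
        assert pm.pattern_frequencies(panel).W == 262144

    def test_matches_naive_tally(self, rng):
        resp = rng.integers(0, 3, size=(50, 2, 3))
        panel = pm.ResponsePanel(resp, np.full(3, 2), ["a", "b", "c"])
        table = pm.pattern_frequencies(panel, drop_empty=False)
        tally = {}
        for row in resp.reshape(50, -1):
            tally[tuple(row)] = tally.get(tuple(row), 0) + 1
        got = {tuple(p.ravel()): int(f)
               for p, f in zip(table.patterns, table.frequencies)}
        assert got == tally

    def test_frequencies_sum_to_n(self, crisp_panel):
        panel, _ = crisp_panel
        table = pm.pattern_frequencies(panel)
        assert table.n + table.n_dropped == panel.n_respondents


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 4))
def test_collapse_commutes_with_tabulation(seed, c_new):
    """Merging categories then tabulating equals tabulating then merging
    patterns (complete data)."""
    rng = np.random.default_rng(seed)
    resp = rng.integers(1, 5, size=(25, 2, 2))
    panel = pm.ResponsePanel(resp, np.full(2, 4), ["a", "b"])
    mapping = {old: int(rng.integers(1, c_new + 1)) for old in range(1, 5)}
    # force surjectivity
    for target, old in zip(range(1, c_new + 1), range(1, 5)):
        mapping[old] = target
    collapsed_first = pm.pattern_frequencies(pm.collapse_categories(panel,
                                                                    mapping))
    table = pm.pattern_frequencies(panel)
    lut = np.zeros(5, dtype=int)
    for old, new in mapping.items():
        lut[old] = new
    merged = {}
    for p, f in zip(table.patterns, table.frequencies):
        key = tuple(lut[p].ravel())
        merged[key] = merged.get(key, 0) + int(f)
    got = {tuple(p.ravel()): int(f) for p, f in
           zip(collapsed_first.patterns, collapsed_first.frequencies)}
    assert got == merged
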