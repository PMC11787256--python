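"""Association stages: strata, multiple testing, model plumbing, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from evpdiet.associations import (
    ModelSpec,
    SECONDARY_COMPONENTS,
    adjust_pvalues,
    assign_modeling_stratum,
    fit_robust_linear,
    overrepresentation_test,
    read_gmt,
    run_component_analysis,
    run_posthoc_mirna,
    run_primary_analysis,
    run_sensitivity,
    screen_composition_associated,
)


@pytest.mark.parametrize("rate,expected", [
    (0.0, "excluded"), (0.10, "excluded"), (0.1999, "excluded"),
    (0.20, "binary"), (0.50, "binary"), (0.60, "binary"),
    (0.6001, "continuous"), (0.75, "continuous"), (1.0, "continuous"),
])
def test_stratum_partition(rate, expected):
    assert assign_modeling_stratum(rate) == expected


def test_stratum_rejects_out_of_range():
    with pytest.raises(ValueError):
        assign_modeling_stratum(1.2)


def test_bh_hand_stepup_and_bonferroni():
    q = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert adjust_pvalues([0.002] * 5, "bonferroni") == pytest.approx([0.01] * 5)
    assert adjust_pvalues([0.3], "BH") == pytest.approx([0.3])


def test_bh_matches_statsmodels_and_is_order_invariant():
    rng = np.random.default_rng(8)
    p = rng.uniform(0, 1, 40)
    mine = adjust_pvalues(p, "BH")
    _, ref, *_ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(mine, ref)
    perm = rng.permutation(40)
    np.testing.assert_allclose(adjust_pvalues(p[perm], "BH"), mine[perm])
    # monotone in p
    order = np.argsort(p)
    assert (np.diff(mine[order]) >= -1e-12).all()


def test_adjust_pvalues_validates_and_propagates_nan():
    with pytest.raises(ValueError):
        adjust_pvalues([0.5, 1.2])
    out = adjust_pvalues([0.02, np.nan, 0.04], "bonferroni")
    assert np.isnan(out[1]) and out[0] == pytest.approx(0.04)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(outcome="richness", exposure="richness")
    with pytest.raises(ValueError):
        ModelSpec(outcome="richness", exposure="ahei_total", family="anova")


def test_primary_analysis_shape_and_null_behaviour(small_study):
    res = run_primary_analysis(small_study["comp"], small_study["scores"],
                               small_study["cov"])
    assert list(res["outcome"]) == ["log2_total", "richness", "evenness"]
    assert (res["n"] == 60).all()
    assert ((res["ci_low"] <= res["estimate"]) & (res["estimate"] <= res["ci_high"])).all()


def test_primary_analysis_refuses_tiny_samples(small_study):
    with pytest.raises(ValueError, match="complete rows"):
        run_primary_analysis(small_study["comp"].iloc[:5],
                             small_study["scores"], small_study["cov"])


def test_component_analysis_covers_ten_components_with_kcal(small_study):
    cov = small_study["cov"].copy()
    cov["kcal_per_day"] = small_study["intakes"]["kcal_per_day"]
    res = run_component_analysis(small_study["comp"], small_study["scores"], cov)
    assert sorted(res["exposure"]) == sorted(SECONDARY_COMPONENTS)
    assert "alcohol" not in set(res["exposure"])
    with pytest.raises(ValueError, match="kcal_per_day"):
        run_component_analysis(small_study["comp"], small_study["scores"],
                               small_study["cov"])


def test_fit_robust_linear_drops_incomplete_rows(small_study):
    data = small_study["data"].copy()
    data.loc[data.index[:4], "vigorous_activity_hrs_wk"] = np.nan
    row = fit_robust_linear(data, "richness", "ahei_total")
    assert row["n"] == 56


def test_posthoc_respects_strata_and_exclusions(small_study):
    rates = small_study["rates"]
    data = small_study["data"]
    excluded = rates[rates < 0.20].index[:1].tolist()
    binary = rates[(rates >= 0.20) & (rates <= 0.60)].index[:2].tolist()
    continuous = rates[rates > 0.60].index[:2].tolist()
    table, skips = run_posthoc_mirna(
        "red_processed_meat", excluded + binary + continuous,
        small_study["normalized"], small_study["calls"], rates, data)
    assert len(table) == len(binary) + len(continuous)
    assert set(table.loc[table["stratum"] == "binary", "outcome"]) == set(binary)
    assert any(excluded[0] in s for s in skips)
    assert (table["q"] >= table["p"] - 1e-12).all()
    assert (table["p_bonf"] >= table["p"] - 1e-12).all()


def test_posthoc_empty_candidates_logged(small_study):
    table, skips = run_posthoc_mirna(
        "red_processed_meat", [], small_study["normalized"],
        small_study["calls"], small_study["rates"], small_study["data"])
    assert table.empty and "empty candidate set" in skips


def test_screen_returns_bonferroni_candidates(small_study):
    candidates, table = screen_composition_associated(
        small_study["normalized"], small_study["calls"], small_study["rates"],
        small_study["comp"], measure="richness")
    assert set(candidates) <= set(table["outcome"])
    flagged = table.loc[table["p_bonf"] < 0.05, "outcome"]
    assert sorted(candidates) == sorted(flagged)


def test_sensitivity_bookkeeping(small_study):
    data = small_study["data"]
    res = run_sensitivity(data, "richness", "ahei_total")
    res = res.set_index("variant")
    n_main = res.loc["main", "n"]
    assert res.loc["excl_gdm", "n"] == n_main - data["gdm"].sum()
    assert res.loc["never_smokers", "n"] == n_main - data["ever_smoker"].sum()
    assert res.loc["adj_bmi", "n"] == n_main  # same rows, extra covariate
    # no-smoker cohort: variant n equals main n
    data0 = data.assign(ever_smoker=0)
    res0 = run_sensitivity(data0, "richness", "ahei_total").set_index("variant")
    assert res0.loc["never_smokers", "n"] == res0.loc["main", "n"]


def test_sensitivity_skips_tiny_subsets(small_study):
    data = small_study["data"].assign(multivitamin=0)
    data.loc[data.index[:3], "multivitamin"] = 1
    with pytest.warns(UserWarning, match="multivitamin_only"):
        res = run_sensitivity(data, "richness", "ahei_total")
    assert "multivitamin_only" not in set(res["variant"])


def test_overrepresentation_hand_cases():
    bg = {f"g{i}" for i in range(1000)}
    hits = {f"g{i}" for i in range(10)}
    pathways = {
        "disjoint": {f"g{i}" for i in range(500, 600)},
        "exact": set(hits),
        "partial": {f"g{i}" for i in range(5, 105)},
    }
    res = overrepresentation_test(hits, pathways, bg).set_index("pathway")
    assert res.loc["disjoint", "p"] == pytest.approx(1.0)
    # hits identical to the pathway: p = 1 / C(1000, 10) ... via pmf at k=10
    assert res.loc["exact", "p"] == pytest.approx(
        hypergeom.pmf(10, 1000, 10, 10))
    # overlap 5 with a 100-gene pathway: brute-force tail sum oracle
    brute = sum(hypergeom.pmf(k, 1000, 100, 10) for k in range(5, 11))
    assert res.loc["partial", "p"] == pytest.approx(brute, rel=1e-10)
    assert (res["p_bh"] >= res["p"] - 1e-15).all()


def test_overrepresentation_input_validation():
    with pytest.raises(ValueError, match="background"):
        overrepresentation_test({"a"}, {"p": {"a"}}, set())
    with pytest.raises(ValueError, match="outside"):
        overrepresentation_test({"zz"}, {"p": {"a"}}, {"a", "b"})


def test_read_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("WNT\tdesc\tg1\tg2\tg3\nEMPTY\tdesc\n"
                    "INTEGRIN\thttp://x\tg2\tg4\n")
    sets = read_gmt(path)
    assert sets == {"WNT": {"g1", "g2", "g3"}, "INTEGRIN": {"g2", "g4"}}
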