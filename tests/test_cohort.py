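"""Cohort data model: derived variables, descriptives, screening, CSV I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pedfl.cohort import (CohortTable, derive_homa_ir, derive_map, describe,
                          quantile_summary, read_cohort, spearman_screen,
                          validate_cohort, write_cohort)


@pytest.mark.parametrize("ins, glu, expected", [
    (13, 79, 13 * 79 / 405),   # 2.5358
    (0, 90, 0.0),
    (9, 74, 9 * 74 / 405),     # 1.6444
])
def test_homa_ir_values(ins, glu, expected):
    assert derive_homa_ir(ins, glu) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("sbp, dbp, expected", [
    (120, 80, 280 / 3),        # 93.33
    (130, 70, 90.0),
    (95, 95, 95.0),
])
def test_map_values(sbp, dbp, expected):
    assert derive_map(sbp, dbp) == pytest.approx(expected, abs=1e-12)


def test_derivation_domain_errors():
    with pytest.raises(ValueError):
        derive_homa_ir(-1, 80)
    with pytest.raises(ValueError):
        derive_homa_ir(10, 0)
    with pytest.raises(ValueError):
        derive_map(80, 120)   # diastolic above systolic
    with pytest.raises(ValueError):
        derive_map(120, 0)


@given(ins=st.floats(0, 200), glu=st.floats(1, 500),
       sbp=st.floats(50, 250), frac=st.floats(0.1, 1.0))
def test_derivations_are_exact_closed_forms(ins, glu, sbp, frac):
    assert derive_homa_ir(ins, glu) == ins * glu / 405.0
    dbp = sbp * frac
    assert derive_map(sbp, dbp) == sbp / 3.0 + 2.0 * dbp / 3.0


# ---------------------------------------------------------------------------
# describe


def test_describe_single_record_collapses_quantiles():
    df = pd.DataFrame({"fl": [1], "age": [12.0], "alt": [30.0]})
    out = describe(CohortTable(df))
    assert out.loc["age", "total"] == "12 (12-12)"
    assert out.loc["fl=1", "total"] == "1 (100.0%)"


def test_quantile_rule_is_linear_interpolation():
    # {1..5}: median 3, IQR (2, 4) under type-7 quantiles
    df = pd.DataFrame({"v": [1.0, 2, 3, 4, 5]})
    q = quantile_summary(df, ["v"])
    assert q.loc["v"].tolist() == [2.0, 3.0, 4.0]


def test_describe_generator_calibration(cohort_1672):
    q = quantile_summary(cohort_1672.data, ["alt"])
    assert q.loc["alt", "p50"] == pytest.approx(23.0, rel=0.10)


def test_describe_group_by_and_empty_error():
    df = pd.DataFrame({"fl": [0, 1, 0], "male": [0, 1, 1],
                       "alt": [20.0, 30, 25]})
    out = describe(CohortTable(df), group_by="male")
    assert set(out.columns) == {"total", "male=0", "male=1"}
    with pytest.raises(ValueError):
        describe(pd.DataFrame(columns=["fl"]))


# ---------------------------------------------------------------------------
# spearman screening


def _brute_clusters(df, variables, threshold):
    """Independent oracle: all-pairs correlations + BFS components."""
    edges = {v: set() for v in variables}
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            rho = stats.spearmanr(df[a], df[b]).statistic
            if abs(rho) > threshold:
                edges[a].add(b)
                edges[b].add(a)
    seen, comps = set(), []
    for v in variables:
        if v in seen or not edges[v]:
            continue
        comp, queue = set(), [v]
        while queue:
            u = queue.pop()
            if u in comp:
                continue
            comp.add(u)
            queue.extend(edges[u] - comp)
        seen |= comp
        comps.append(comp)
    return sorted(comps, key=lambda c: sorted(c)[0])


def test_screen_flags_published_collinear_pairs(cohort_1672):
    res = spearman_screen(cohort_1672, ["age", "pub", "bmi", "wc", "alt",
                                        "ast", "ggt", "ins", "homa"],
                          priority=["age", "alt", "homa", "bmi"])
    flagged = {frozenset((a, b)) for a, b, _ in res.flagged_pairs()}
    for pair in [("age", "pub"), ("bmi", "wc"), ("alt", "ast"),
                 ("ins", "homa")]:
        assert frozenset(pair) in flagged
    # ALT-AST and ALT-GGT merge into a single liver-enzyme cluster
    enzyme = next(c for c in res.clusters if "alt" in c)
    assert enzyme >= {"alt", "ast", "ggt"}
    assert res.kept[frozenset(enzyme)] == "alt"


def test_screen_matches_brute_force_components(cohort_1672):
    variables = ["age", "pub", "bmi", "wc", "alt", "ast", "ggt", "tg",
                 "ins", "homa"]
    res = spearman_screen(cohort_1672, variables, threshold=0.6)
    assert sorted(map(sorted, res.clusters)) == sorted(
        map(sorted, _brute_clusters(cohort_1672.data, variables, 0.6)))


def test_screen_trivial_cases(rng):
    n = 300
    df = pd.DataFrame({"fl": rng.integers(0, 2, n).astype(int),
                       "a": rng.normal(size=n), "b": rng.normal(size=n),
                       "c": rng.normal(size=n)})
    df["a"] += 10.0  # keep validator-friendly? not required: screen takes df
    res = spearman_screen(df, ["a", "b", "c"])
    assert res.clusters == []
    df["d"] = -df["a"]
    res2 = spearman_screen(df, ["a", "d"])
    assert res2.clusters == [{"a", "d"}]
    assert res2.spearman_matrix.loc["a", "d"] == pytest.approx(-1.0)


def test_screen_monotone_transform_invariance(rng):
    n = 250
    x = rng.lognormal(1, 0.4, n)
    y = x + rng.normal(0, 0.5, n)
    df = pd.DataFrame({"x": x, "y": y, "xe": np.exp(x / x.max() * 3)})
    r1 = spearman_screen(df, ["x", "y"]).spearman_matrix.loc["x", "y"]
    r2 = spearman_screen(df, ["xe", "y"]).spearman_matrix.loc["xe", "y"]
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_screen_errors(rng):
    df = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50)})
    with pytest.raises(ValueError, match="constant"):
        spearman_screen(df, ["a", "b"])
    with pytest.raises(ValueError):
        spearman_screen(df, ["b"])
    with pytest.raises(ValueError):
        spearman_screen(df, ["a", "b"], threshold=1.5)


# ---------------------------------------------------------------------------
# validation and CSV round trip


def test_validator_enforces_derivation_consistency():
    base = {"fl": [0], "ins": [10.0], "glu": [81.0]}
    validate_cohort(pd.DataFrame({**base, "homa": [10 * 81 / 405]}))
    with pytest.raises(ValueError, match="homa"):
        validate_cohort(pd.DataFrame({**base, "homa": [2.1]}))
    with pytest.raises(ValueError, match="fl_grade|fl "):
        validate_cohort(pd.DataFrame({"fl": [0], "fl_grade": [2]}))


def test_csv_round_trip_is_bit_exact(tmp_path, small_cohort):
    path = tmp_path / "cohort.csv"
    write_cohort(small_cohort, path)
    back = read_cohort(path)
    assert back.provenance == "synthetic"
    assert back.seed == small_cohort.seed
    cols = [c for c in small_cohort.data.columns]
    pd.testing.assert_frame_equal(
        back.data[sorted(cols)], small_cohort.data[sorted(cols)],
        check_exact=True)


def test_read_cohort_three_row_fixture(tmp_path):
    p = tmp_path / "mini.csv"
    p.write_text("fl,age,alt\n0,10,20\n1,12,45\n0,14.5,18\n")
    c = read_cohort(p, required=["fl", "age", "alt"])
    assert c.n == 3
    assert c.data["age"].tolist() == [10.0, 12.0, 14.5]


def test_read_cohort_missing_cell_cites_completeness(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("fl,age,ins\n0,10,12\n1,12,\n")
    with pytest.raises(ValueError, match="complete data"):
        read_cohort(p)


def test_read_cohort_nonnumeric_and_missing_column(tmp_path):
    p = tmp_path / "bad2.csv"
    p.write_text("fl,age\n0,ten\n")
    with pytest.raises(ValueError, match="row 0, column 'age'"):
        read_cohort(p)
    p2 = tmp_path / "bad3.csv"
    p2.write_text("fl,age\n0,10\n")
    with pytest.raises(ValueError, match="alt"):
        read_cohort(p2, required=["alt"])
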