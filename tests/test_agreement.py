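"""Interobserver agreement statistics and area concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elastocad import (
    agreement_band,
    agreement_report,
    cohen_kappa,
    compare_areas,
    concordance_table,
    icc,
    lin_ccc,
)
from oracles import ccc_bruteforce, icc_bruteforce, kappa_bruteforce

# -------------------------------------------------------------------- kappa


def test_kappa_perfect_agreement():
    assert cohen_kappa([1, 2, 3, 1, 2], [1, 2, 3, 1, 2]) == 1.0


def test_kappa_chance_example():
    # p_o = 0.5 and p_e = 0.5 by construction → κ = 0
    assert cohen_kappa([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0, abs=1e-12)


def test_kappa_matches_direct_formula(rng):
    for _ in range(30):
        x = rng.integers(1, 4, size=20)
        y = rng.integers(1, 4, size=20)
        if np.array_equal(x, y) and len(set(x)) == 1:
            continue
        assert cohen_kappa(x, y) == pytest.approx(kappa_bruteforce(x, y), abs=1e-12)


def test_kappa_degenerate_identical_constant():
    assert cohen_kappa([2, 2, 2], [2, 2, 2]) == 1.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(1, 3), st.integers(1, 3)), min_size=2, max_size=30))
def test_kappa_symmetric_and_relabel_invariant(pairs):
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    px = np.array([(x == c).mean() for c in np.union1d(x, y)])
    py = np.array([(y == c).mean() for c in np.union1d(x, y)])
    if px @ py >= 1 - 1e-12 and not np.array_equal(x, y):
        return  # undefined case
    k = cohen_kappa(x, y)
    assert cohen_kappa(y, x) == pytest.approx(k, abs=1e-12)
    relabel = {1: 3, 2: 1, 3: 2}
    xr = np.array([relabel[v] for v in x])
    yr = np.array([relabel[v] for v in y])
    assert cohen_kappa(xr, yr) == pytest.approx(k, abs=1e-12)


# ---------------------------------------------------------------------- icc


def test_icc_identical_columns_is_one(rng):
    col = rng.uniform(0, 1, size=8)
    m = np.column_stack([col, col, col])
    single, average = icc(m)
    assert single == pytest.approx(1.0, abs=1e-9)
    assert average == pytest.approx(1.0, abs=1e-9)


def test_icc_matches_anova_mean_squares(rng):
    truth = rng.uniform(0, 1, size=6)
    m = truth[:, None] + rng.normal(0, 0.08, size=(6, 3))
    single, average = icc(m)
    ref_single, ref_average = icc_bruteforce(m)
    assert single == pytest.approx(ref_single, abs=1e-9)
    assert average == pytest.approx(ref_average, abs=1e-9)


def test_icc_independent_columns_near_zero(rng):
    m = rng.uniform(0, 1, size=(500, 3))
    single, _ = icc(m)
    assert abs(single) < 0.1


def test_icc_average_at_least_single(rng):
    for _ in range(10):
        m = rng.uniform(0, 1, size=(10, 4)) + rng.uniform(0, 1, size=(10, 1))
        single, average = icc(m)
        if single >= 0:
            assert average >= single - 1e-12


def test_icc_constant_matrix_rejected():
    with pytest.raises(ValueError, match="variance"):
        icc(np.full((5, 3), 0.7))


# ---------------------------------------------------------------------- ccc


def test_ccc_identity_is_one(rng):
    x = rng.uniform(0, 1, size=12)
    assert lin_ccc(x, x) == pytest.approx(1.0, abs=1e-12)


def test_ccc_shift_penalized(rng):
    x = rng.uniform(0, 1, size=12)
    y = x + 0.2
    assert lin_ccc(x, y) < 1.0
    assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_ccc_hand_example():
    x = (0.1, 0.5, 0.9)
    y = (0.2, 0.4, 1.0)
    expect = ccc_bruteforce(x, y)
    assert lin_ccc(x, y) == pytest.approx(expect, abs=1e-12)
    assert lin_ccc(x, y) == pytest.approx(0.955224, abs=1e-6)


def test_ccc_constant_inputs_rejected():
    with pytest.raises(ValueError, match="constant"):
        lin_ccc([0.5, 0.5], [0.5, 0.5])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            st.floats(min_value=0, max_value=1, allow_nan=False),
        ),
        min_size=3,
        max_size=25,
    )
)
def test_ccc_bounded_by_pearson(pairs):
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if x.var() == 0 or y.var() == 0:
        return
    ccc = lin_ccc(x, y)
    pearson = np.corrcoef(x, y)[0, 1]
    assert abs(ccc) <= abs(pearson) + 1e-10


# -------------------------------------------------------------------- bands


@pytest.mark.parametrize(
    "v,band",
    [
        (0.85, "excellent"),
        (0.50, "moderate"),
        (0.80, "excellent"),
        (0.20, "fair"),
        (1.0, "excellent"),
        (0.0, "slight"),
        (-0.3, "slight"),
        (0.65, "substantial"),
    ],
)
def test_agreement_band(v, band):
    assert agreement_band(v) == band


def test_agreement_band_above_one_rejected():
    with pytest.raises(ValueError):
        agreement_band(1.05)


# ------------------------------------------------------------------- areas


@pytest.mark.parametrize(
    "ax,ay,cat,ratio",
    [
        (100, 100, "equal", 1.0),
        (70, 100, "smaller", 0.7),
        (130, 100, "larger", 1.3),
        (80, 100, "equal", 0.8),   # boundary
        (120, 100, "equal", 1.2),  # boundary
    ],
)
def test_compare_areas(ax, ay, cat, ratio):
    res = compare_areas(ax, ay)
    assert res.category == cat
    assert res.ratio == pytest.approx(ratio)


def test_compare_areas_rejects_nonpositive():
    with pytest.raises(ValueError):
        compare_areas(0, 10)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.floats(min_value=1, max_value=1e4), st.floats(min_value=1, max_value=1e4))
def test_smaller_larger_antisymmetry(a, b):
    if compare_areas(a, b).category == "smaller":
        assert compare_areas(b, a).category == "larger"


# -------------------------------------------------------- concordance table


def _pair_table(counts, n=83, rx="R1", ry="R2"):
    """Two-reader table engineered to the given (equal, smaller, larger) counts."""
    n_eq, n_sm, n_lg = counts
    assert n_eq + n_sm + n_lg == n
    areas_x = [1000] * n_eq + [700] * n_sm + [1300] * n_lg
    rows = []
    for i, ax in enumerate(areas_x):
        for reader, area in ((rx, ax), (ry, 1000)):
            rows.append(
                {"lesion_id": i, "reader_id": reader, "label": 1,
                 "hard_fraction": 0.1, "area_px": area}
            )
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "counts,pcts",
    [
        ((69, 5, 9), (83.1, 6.0, 10.8)),
        ((65, 7, 11), (78.3, 8.4, 13.3)),
        ((60, 9, 14), (72.3, 10.8, 16.9)),
    ],
)
def test_concordance_percentages(counts, pcts):
    out = concordance_table(_pair_table(counts))
    row = out.iloc[0]
    assert row["n_lesions"] == 83
    assert (row["n_equal"], row["n_smaller"], row["n_larger"]) == counts
    assert (row["pct_equal"], row["pct_smaller"], row["pct_larger"]) == pcts


def test_concordance_all_equal():
    out = concordance_table(_pair_table((10, 0, 0), n=10))
    row = out.iloc[0]
    assert (row["pct_equal"], row["pct_smaller"], row["pct_larger"]) == (100.0, 0.0, 0.0)


def test_concordance_percentages_sum_to_100(rng):
    for _ in range(10):
        n_sm = int(rng.integers(0, 20))
        n_lg = int(rng.integers(0, 20))
        out = concordance_table(_pair_table((83 - n_sm - n_lg, n_sm, n_lg)))
        row = out.iloc[0]
        assert abs(row["pct_equal"] + row["pct_smaller"] + row["pct_larger"] - 100.0) <= 0.1


def test_concordance_missing_lesion_listed():
    df = _pair_table((3, 1, 1), n=5)
    df = df.drop(df[(df.lesion_id == 2) & (df.reader_id == "R2")].index)
    with pytest.raises(ValueError, match="2"):
        concordance_table(df)


# ------------------------------------------------------------------ report


def test_agreement_report_identical_readers(rng):
    q = rng.uniform(0, 1, size=10)
    labels = rng.integers(1, 4, size=10)
    rows = []
    for reader in ("R1", "R2", "R3"):
        for i in range(10):
            rows.append(
                {"lesion_id": i, "reader_id": reader, "label": labels[i],
                 "hard_fraction": q[i], "area_px": 500}
            )
    report = agreement_report(pd.DataFrame(rows))
    for p in report["pairwise"]:
        assert p["kappa"] == 1.0 and p["kappa_band"] == "excellent"
        assert p["ccc"] == pytest.approx(1.0, abs=1e-12)
    assert report["icc_single"] == pytest.approx(1.0, abs=1e-9)
    for block in report["area_concordance"]:
        assert block["pct_equal"] == 100.0


def test_agreement_report_rejects_single_reader():
    df = _pair_table((3, 1, 1), n=5)
    df = df[df.reader_id == "R1"]
    with pytest.raises(ValueError):
        agreement_report(df)


def test_reader_table_validation():
    df = _pair_table((3, 1, 1), n=5)
    dup = pd.concat([df, df.iloc[[0]]])
    with pytest.raises(ValueError, match="duplicate"):
        concordance_table(dup)
    bad = df.copy()
    bad.loc[bad.index[0], "label"] = 7
    with pytest.raises(ValueError, match="label"):
        concordance_table(bad)
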