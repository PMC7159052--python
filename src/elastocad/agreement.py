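"""Interobserver agreement statistics.

Readers score each lesion 1 (soft), 2 (intermediate) or 3 (hard) and
segment its area by hand. Agreement between readers is summarised by:

- Cohen's unweighted kappa on the 3-point scores, per reader pair;
- Lin's concordance correlation coefficient (CCC) on the continuous hard
  fractions q, per reader pair;
- the intraclass correlation coefficient (ICC) over all readers jointly,
  in the two-way random-effects, absolute-agreement form — Shrout–Fleiss
  ICC(2,1) for single measures and ICC(2,k) for average measures;
- a size-concordance table of the segmented areas: two areas are "equal"
  when they differ by less than 20% (ratio in [0.8, 1.2]), otherwise the
  first is "smaller" (ratio < 0.8) or "larger" (ratio > 1.2).

Agreement values are banded as slight [0, 0.2), fair [0.2, 0.4), moderate
[0.4, 0.6), substantial [0.6, 0.8) or excellent [0.8, 1.0]; a boundary
value belongs to the upper band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "READER_TABLE_COLUMNS",
    "AreaComparison",
    "validate_reader_table",
    "cohen_kappa",
    "icc",
    "lin_ccc",
    "agreement_band",
    "compare_areas",
    "concordance_table",
    "agreement_report",
]

READER_TABLE_COLUMNS = ("lesion_id", "reader_id", "label", "hard_fraction", "area_px")

_BANDS = (
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0 + 1e-12, "excellent"),
)


def validate_reader_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a reader table for the expected columns and value ranges.

    One row per (lesion, reader): 3-point label in {1,2,3}, hard fraction
    in [0,1], positive segmented area in pixels. Duplicated (lesion,
    reader) pairs are rejected.
    """
    missing = [c for c in READER_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reader table is missing columns: {missing}")
    if df.duplicated(subset=["lesion_id", "reader_id"]).any():
        dupes = df[df.duplicated(subset=["lesion_id", "reader_id"], keep=False)]
        raise ValueError(
            "duplicate (lesion_id, reader_id) rows: "
            f"{sorted(set(map(tuple, dupes[['lesion_id', 'reader_id']].values)))}"
        )
    if not df["label"].isin([1, 2, 3]).all():
        raise ValueError("labels must be 1 (soft), 2 (intermediate) or 3 (hard)")
    if ((df["hard_fraction"] < 0) | (df["hard_fraction"] > 1)).any():
        raise ValueError("hard_fraction values must lie in [0, 1]")
    if (df["area_px"] <= 0).any():
        raise ValueError("area_px values must be positive")
    return df


def cohen_kappa(x, y) -> float:
    """Cohen's unweighted kappa between two raters' 3-point scores.

    κ = (p_o − p_e) / (1 − p_e) with chance agreement p_e from the product
    of the marginal score distributions. When both raters are constant
    with identical marginals (p_e = 1), κ is defined as 1.0 if the ratings
    agree elementwise; otherwise no chance-corrected value exists.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("cohen_kappa: inputs must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("cohen_kappa: need at least two rated items")
    cats = np.union1d(x, y)
    px = np.array([(x == c).mean() for c in cats])
    py = np.array([(y == c).mean() for c in cats])
    p_e = float(px @ py)
    if p_e >= 1.0 - 1e-15:
        if np.array_equal(x, y):
            return 1.0
        raise ValueError("cohen_kappa: undefined (chance agreement is 1)")
    return float(cohen_kappa_score(x, y))


def icc(matrix) -> tuple[float, float]:
    """Single- and average-measures ICC of a lesions × readers matrix.

    Two-way random-effects, absolute agreement: ICC(2,1) and ICC(2,k) of
    Shrout & Fleiss, computed from the two-way ANOVA mean squares.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("icc: need a 2-D matrix with >= 2 lesions and >= 2 readers")
    if np.isnan(m).any():
        raise ValueError("icc: missing cells are not supported")
    if np.ptp(m) == 0:
        raise ValueError("icc: no between-lesion variance (constant matrix)")
    n, k = m.shape
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "rating": m.ravel(),
        }
    )
    with warnings.catch_warnings():
        # zero residual variance (perfect agreement) is a legitimate input;
        # only the confidence-interval arithmetic divides by zero
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            long, targets="target", raters="rater", ratings="rating"
        )
    table = table.set_index("Type")
    single = float(table.loc["ICC2", "ICC"]) if "ICC2" in table.index else float(
        table.loc["ICC(A,1)", "ICC"]
    )
    average = float(table.loc["ICC2k", "ICC"]) if "ICC2k" in table.index else float(
        table.loc["ICC(A,k)", "ICC"]
    )
    return single, average


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient between two raters.

    ρc = 2·cov(x,y) / (var(x) + var(y) + (mean(x) − mean(y))²), with
    population (1/n) moments. Penalises both decorrelation and
    location/scale shift; equals the Pearson correlation only when means
    and variances match.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("lin_ccc: inputs must be equal-length 1-D with n >= 2")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        raise ValueError("lin_ccc: both inputs are constant")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def agreement_band(v: float) -> str:
    """Verbal band of an agreement statistic.

    Half-open bins [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1.0];
    boundary values go to the upper band; negative values (below-chance
    agreement) are "slight". Values above 1 are invalid.
    """
    if v > 1.0:
        raise ValueError(f"agreement statistic cannot exceed 1, got {v}")
    for upper, name in _BANDS:
        if v < upper:
            return name
    return "excellent"


@dataclass(frozen=True)
class AreaComparison:
    """Size comparison of two segmented areas, by their ratio."""

    category: str  # equal | smaller | larger
    ratio: float


def compare_areas(area_x: float, area_y: float) -> AreaComparison:
    """Categorize area_x against area_y by their ratio.

    smaller iff area_x/area_y < 0.8, larger iff > 1.2, equal otherwise
    (variation below 20%; the boundaries 0.8 and 1.2 count as equal).
    """
    if area_x <= 0 or area_y <= 0:
        raise ValueError(f"areas must be positive, got ({area_x}, {area_y})")
    ratio = area_x / area_y
    if ratio < 0.8:
        category = "smaller"
    elif ratio > 1.2:
        category = "larger"
    else:
        category = "equal"
    return AreaComparison(category=category, ratio=float(ratio))


def concordance_table(
    rt: pd.DataFrame, pairs: list[tuple] | None = None
) -> pd.DataFrame:
    """Per-pair counts and percentages of equal/smaller/larger areas.

    For every reader pair (x, y), each lesion's areas are compared as
    area_x/area_y; counts over lesions are reported with percentages to
    one decimal. Percentages use the pair's lesion count as denominator.
    """
    validate_reader_table(rt)
    readers = sorted(rt["reader_id"].unique())
    if pairs is None:
        pairs = list(combinations(readers, 2))
    wide = rt.pivot(index="lesion_id", columns="reader_id", values="area_px")
    rows = []
    for rx, ry in pairs:
        for r in (rx, ry):
            if r not in wide.columns:
                raise ValueError(f"no records for reader {r!r}")
        sub = wide[[rx, ry]]
        missing = sub.index[sub.isna().any(axis=1)].tolist()
        if missing:
            raise ValueError(
                f"pair ({rx}, {ry}) is missing areas for lesions: {missing}"
            )
        cats = [compare_areas(a, b).category for a, b in sub.values]
        n = len(cats)
        counts = {c: cats.count(c) for c in ("equal", "smaller", "larger")}
        rows.append(
            {
                "reader_x": rx,
                "reader_y": ry,
                "n_lesions": n,
                **{f"n_{c}": counts[c] for c in counts},
                **{f"pct_{c}": round(counts[c] / n * 100, 1) for c in counts},
            }
        )
    return pd.DataFrame(rows)


def agreement_report(rt: pd.DataFrame) -> dict:
    """Full interobserver agreement report from a reader table.

    Returns pairwise kappa (on 3-point labels) and CCC (on hard fractions)
    with verbal bands, the ICC single/average over all readers, and the
    area size-concordance block.
    """
    validate_reader_table(rt)
    readers = sorted(rt["reader_id"].unique())
    if len(readers) < 2:
        raise ValueError("agreement requires at least two readers")
    labels = rt.pivot(index="lesion_id", columns="reader_id", values="label")
    qs = rt.pivot(index="lesion_id", columns="reader_id", values="hard_fraction")
    if labels.isna().any().any():
        missing = labels.index[labels.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete reader records for lesions: {missing}")
    pairwise = []
    for rx, ry in combinations(readers, 2):
        k = cohen_kappa(labels[rx].to_numpy(int), labels[ry].to_numpy(int))
        c = lin_ccc(qs[rx].to_numpy(), qs[ry].to_numpy())
        pairwise.append(
            {
                "reader_x": rx,
                "reader_y": ry,
                "kappa": k,
                "kappa_band": agreement_band(k),
                "ccc": c,
                "ccc_band": agreement_band(c),
            }
        )
    single, average = icc(qs[readers].to_numpy())
    return {
        "pairwise": pairwise,
        "icc_single": single,
        "icc_average": average,
        "icc_single_band": agreement_band(single),
        "icc_average_band": agreement_band(average),
        "area_concordance": concordance_table(rt).to_dict(orient="records"),
    }
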