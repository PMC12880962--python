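"""Histopathology rubric for acute liver preservation injury.

Four features are scored 0–3 from the most severe observation in the
examined field — neutrophil infiltration, hepatocyte necrosis, sinusoidal
congestion and sinusoidal oedema — and summed into a 0–12 composite score.
Necrosis is graded by the percentage of hepatocytes affected: none -> 0,
under 10% -> 1, 10–30% -> 2, over 30% -> 3 (a percentage exactly on a
boundary takes the higher grade).  The qualitative features use a four-level
severity ladder (none / mild / moderate / severe).

Group summaries average category scores per (group, timepoint) cell; since
the composite is the category sum, the mean composite equals the sum of the
category means exactly.  `compare_groups` reports an independent two-sample
t-test on composites with Shapiro–Wilk and Levene diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORIES",
    "HistologyScore",
    "score_category",
    "composite_score",
    "summarize_groups",
    "compare_groups",
    "load_scores",
]

CATEGORIES = (
    "neutrophil_infiltration",
    "hepatocyte_necrosis",
    "sinusoidal_congestion",
    "sinusoidal_oedema",
)

# severity ladders for the qualitative features
_SEVERITY_LEVELS = {
    "none": 0,
    "mild": 1,
    "sparse-focal": 1,
    "slight": 1,
    "moderate": 2,
    "widespread-focal": 2,
    "pronounced": 2,
    "severe": 3,
    "diffuse": 3,
    "widespread": 3,
}


@dataclass
class HistologyScore:
    """One biopsy's category scores and composite."""

    neutrophil_infiltration: int
    hepatocyte_necrosis: int
    sinusoidal_congestion: int
    sinusoidal_oedema: int
    group: str = ""
    timepoint: str = ""
    biopsy_id: str = ""

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            v = getattr(self, cat)
            if v not in (0, 1, 2, 3):
                raise ValueError(f"{cat} score must be an integer in 0..3, got {v!r}")

    @property
    def composite(self) -> int:
        return sum(getattr(self, cat) for cat in CATEGORIES)


def _score_necrosis(percent) -> int:
    pct = float(percent)
    if not (0 <= pct <= 100):
        raise ValueError(f"percent hepatocytes affected must be in [0, 100], got {pct}")
    if pct == 0:
        return 0
    if pct < 10:
        return 1
    if pct <= 30:
        return 2
    return 3


def score_category(feature: str, observation) -> int:
    """Grade one feature from a raw observation.

    For necrosis a numeric observation is the percentage of hepatocytes
    affected; for the qualitative features it is a severity keyword or an
    already-graded integer 0..3.  A list of observations (multiple examined
    fields) is graded by the most severe.
    """
    if feature not in CATEGORIES:
        raise ValueError(f"unknown histological feature {feature!r}; expected one of {CATEGORIES}")
    if isinstance(observation, (list, tuple)):
        if not observation:
            raise ValueError("empty observation list")
        return max(score_category(feature, obs) for obs in observation)
    if isinstance(observation, str):
        key = observation.strip().lower()
        if key not in _SEVERITY_LEVELS:
            raise ValueError(
                f"unknown severity {observation!r}; expected one of {sorted(set(_SEVERITY_LEVELS))}"
            )
        return _SEVERITY_LEVELS[key]
    if feature == "hepatocyte_necrosis":
        # numeric necrosis observations are percentages of hepatocytes affected
        return _score_necrosis(observation)
    v = int(observation)
    if v != observation or not (0 <= v <= 3):
        raise ValueError(f"{feature}: score {observation!r} outside 0..3")
    return v


def composite_score(scores) -> int:
    """Sum of the four category scores (0..12)."""
    scores = tuple(scores)
    if len(scores) != 4:
        raise ValueError("composite_score expects four category scores")
    for s in scores:
        if s not in (0, 1, 2, 3):
            raise ValueError(f"category score {s!r} outside 0..3")
    return int(sum(scores))


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("group", "timepoint", *CATEGORIES) if c not in table.columns]
    if missing:
        raise ValueError(f"score table is missing columns: {missing}")
    if table.empty:
        raise ValueError("score table is empty")
    df = table.copy()
    if "composite" in df.columns:
        bad = df["composite"] != df[list(CATEGORIES)].sum(axis=1)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} records violate composite = sum of categories"
            )
    else:
        df["composite"] = df[list(CATEGORIES)].sum(axis=1)
    return df


def summarize_groups(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per group x timepoint category means and mean composite.

    Full precision is retained in the returned frame; ``round(decimals)`` is
    what a report would print.  The composite mean is computed both as the
    mean of per-record composites and as the sum of category means — these
    are equal by linearity and asserted to match.
    """
    df = _check_table(table)
    grouped = df.groupby(["group", "timepoint"], sort=True)[list(CATEGORIES) + ["composite"]].mean()
    cat_sum = grouped[list(CATEGORIES)].sum(axis=1)
    if not np.allclose(cat_sum, grouped["composite"]):
        raise AssertionError("mean composite must equal the sum of category means")
    return grouped.reset_index()


def compare_groups(table: pd.DataFrame, timepoint: str) -> dict:
    """Two-sample t-test on composites between the two groups at a timepoint.

    Also reports Shapiro–Wilk normality per group and Levene's test of
    variance homogeneity.  This is a reporting convenience over simulated or
    user-supplied biopsy-level scores.
    """
    df = _check_table(table)
    at = df[df["timepoint"] == timepoint]
    groups = sorted(at["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups at timepoint {timepoint!r}, got {groups}")
    a = at[at["group"] == groups[0]]["composite"].to_numpy(dtype=float)
    b = at[at["group"] == groups[1]]["composite"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two records per group for a t-test")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = stats.ttest_ind(a, b)
    report = {
        "timepoint": timepoint,
        "groups": groups,
        "n": [int(len(a)), int(len(b))],
        "means": [float(a.mean()), float(b.mean())],
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
        "levene_p": float(stats.levene(a, b).pvalue) if np.ptp(a) or np.ptp(b) else 1.0,
    }
    for label, sample in zip(groups, (a, b)):
        if np.ptp(sample) > 0:
            report[f"shapiro_p_{label}"] = float(stats.shapiro(sample).pvalue)
        else:
            report[f"shapiro_p_{label}"] = float("nan")  # degenerate: constant sample
    return report


def load_scores(path) -> pd.DataFrame:
    """Read a biopsy score CSV (group, timepoint, biopsy_id, four categories)."""
    return _check_table(pd.read_csv(path))
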