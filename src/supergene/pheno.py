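"""Statistics of the hormone-supplementation experiment.

Style/stamen lengths are modeled with a two-way fixed-effects ANOVA
(morph, treatment, morph×treatment) using sequential Type-I sums of squares
with morph entered first; a morph-specific hormone response appears as a
significant interaction.  Post hoc cell comparisons use the Tukey HSD
method (studentized-range reference distribution, Tukey–Kramer SE for
unequal cell sizes) with 95% confidence intervals.  Style-cell lengths are
averaged per style section and log-transformed before modeling, with style
section as an additional predictor.

Repeated flowers per individual are treated as independent observations
(fixed-effects models only) — a deliberate simplification that slightly
understates residual correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MEASUREMENT_COLUMNS = [
    "individual_id",
    "morph",
    "treatment",
    "organ",
    "section",
    "length",
]


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if (df["length"] <= 0).any():
        raise ValueError("lengths must be positive")
    return df


def average_cell_lengths(df: pd.DataFrame) -> pd.DataFrame:
    """Average replicate cell measurements per flower × style section.

    Rows with organ == 'cell' are collapsed to one mean length per
    (individual, flower if present, morph, treatment, section) before any
    modeling; other organs pass through unchanged.
    """
    cells = df[df["organ"] == "cell"]
    rest = df[df["organ"] != "cell"]
    if cells.empty:
        return df.copy()
    keys = ["individual_id", "morph", "treatment", "organ", "section"]
    if "flower" in cells.columns:
        keys.insert(1, "flower")
    agg = cells.groupby(keys, as_index=False, sort=False)["length"].mean()
    return pd.concat([rest, agg], ignore_index=True)


def _format_anova(aov, response: pd.Series) -> pd.DataFrame:
    """Shape a statsmodels Type-I table; a constant response makes every F
    ratio meaningless, so F and p are reported as NA in that case."""
    out = pd.DataFrame(
        {
            "df": aov["df"].astype(int),
            "SS": aov["sum_sq"],
            "MS": aov["sum_sq"] / aov["df"],
            "F": aov["F"],
            "p": aov["PR(>F)"],
        }
    )
    if np.isclose(response.var(ddof=0), 0.0):
        out.loc[:, ["F", "p"]] = np.nan
    return out


@dataclass
class AnovaTable:
    """Sequential (Type-I) ANOVA summary: df, SS, MS, F, p per term."""

    table: pd.DataFrame  # index: term; columns: df, SS, MS, F, p

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def two_way_anova(
    data: pd.DataFrame,
    response: str = "length",
    factor_a: str = "morph",
    factor_b: str = "treatment",
    interaction: bool = True,
) -> AnovaTable:
    """Two-way fixed-effects ANOVA with sequential Type-I sums of squares.

    Terms enter in the order A, B, A×B and are tested against the residual
    mean square.  Every factor combination must be observed (an empty cell
    makes the interaction inestimable and raises, naming the cell).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = data.groupby([factor_a, factor_b]).size()
    for a in data[factor_a].unique():
        for b in data[factor_b].unique():
            if (a, b) not in counts.index:
                raise ValueError(f"empty design cell: {factor_a}={a}, {factor_b}={b}")
    terms = f"C({factor_a}) * C({factor_b})" if interaction else f"C({factor_a}) + C({factor_b})"
    model = smf.ols(f"{response} ~ {terms}", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    rename = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
        "Residual": "Residuals",
    }
    return AnovaTable(_format_anova(aov.rename(index=rename), data[response]))


def f_from_table(
    ss_term: float, df_term: int, ss_res: float, df_res: int, decimals: int | None = None
) -> float:
    """F statistic from printed sums of squares: (SS_t/df_t) / (SS_r/df_r).

    Useful to verify published ANOVA tables; ``decimals`` rounds to the
    table's printed precision.
    """
    if df_term <= 0 or df_res <= 0:
        raise ValueError("degrees of freedom must be positive")
    f = (ss_term / df_term) / (ss_res / df_res)
    return round(f, decimals) if decimals is not None else f


def tukey_hsd(
    data: pd.DataFrame,
    response: str = "length",
    factors: tuple[str, str] = ("morph", "treatment"),
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Tukey HSD all-pairs comparison of factor-combination cell means.

    The residual mean square comes from the full-interaction (cell-means)
    model; intervals use the studentized-range quantile q(conf; k, df_res)
    and the Tukey–Kramer standard error for unequal cell sizes.  Returns
    one row per cell pair with the mean difference, adjusted p and CI.
    """
    cells = data.assign(
        _cell=data[list(factors)].astype(str).agg(":".join, axis=1)
    )
    groups = cells.groupby("_cell")[response]
    means = groups.mean()
    ns = groups.size()
    k = len(means)
    if k < 2:
        raise ValueError("need at least two cells for Tukey HSD")
    n_total = int(ns.sum())
    df_res = n_total - k
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    sse = float(((cells[response] - cells["_cell"].map(means)) ** 2).sum())
    mse = sse / df_res
    q_crit = stats.studentized_range.ppf(conf_level, k, df_res)

    rows = []
    for a, b in itertools.combinations(sorted(means.index), 2):
        diff = means[b] - means[a]
        # Tukey–Kramer: half-width q * sqrt(MSE/2 * (1/na + 1/nb))
        se_q = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        half = q_crit * se_q
        q_obs = abs(diff) / se_q
        p_adj = float(stats.studentized_range.sf(q_obs, k, df_res))
        rows.append((b, a, float(diff), float(diff - half), float(diff + half), p_adj))
    return pd.DataFrame(
        rows, columns=["group1", "group2", "diff", "ci_low", "ci_high", "p_adj"]
    )


def cell_length_model(
    data: pd.DataFrame,
    include_interaction: bool = True,
) -> AnovaTable:
    """Sequential ANOVA of log-transformed mean style-cell length.

    Predictors: morph, style section (bottom/middle/top), treatment and —
    by default — the morph×treatment interaction.  Replicate cell rows
    must be averaged per section first (see :func:`average_cell_lengths`).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data.copy()
    if (df["length"] <= 0).any():
        raise ValueError("lengths must be positive for log transform")
    if df["section"].nunique() < 3:
        raise ValueError("section factor must have 3 levels (bottom, middle, top)")
    df["log_length"] = np.log(df["length"])
    terms = "C(morph) + C(section) + C(treatment)"
    if include_interaction:
        terms += " + C(morph):C(treatment)"
    model = smf.ols(f"log_length ~ {terms}", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    rename = {
        "C(morph)": "morph",
        "C(section)": "section",
        "C(treatment)": "treatment",
        "C(morph):C(treatment)": "morph:treatment",
        "Residual": "Residuals",
    }
    return AnovaTable(_format_anova(aov.rename(index=rename), df["log_length"]))
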