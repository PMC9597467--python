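"""Classical statistics for the split-plot trial.

Four ingredients: per-genotype non-F vs +F contrasts (two-sample t-test,
Welch by default), Tukey HSD comparisons among genotypes within a
treatment with a compact letter display, Pearson correlation, and a
classical split-plot ANOVA with two error strata (main-plot error for the
fertility treatment, subplot error for genotype and the interaction).

The ANOVA is computed on subplot means (plants within a subplot are
subsamples, not independent replicates).  With balanced data its F-test
conclusions coincide with those of a REML mixed model on the same strata,
while being fully specifiable in closed form.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastResult",
    "LetterDisplay",
    "treatment_contrast",
    "tukey_letters",
    "compact_letter_display",
    "pearson_r",
    "split_plot_anova",
]


@dataclass(frozen=True)
class ContrastResult:
    genotype: str
    trait: str
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float
    n_non_f: int
    n_plus_f: int


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display plus the p-matrix it was derived from.

    Genotypes sharing no letter differ at level alpha; genotypes sharing
    a letter do not.
    """

    letters: dict[str, str]
    means: dict[str, float]
    p_matrix: pd.DataFrame
    alpha: float

    def frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "mean": self.means[g], "letters": self.letters[g]}
            for g in sorted(self.means, key=lambda g: (-self.means[g], g))
        ]
        return pd.DataFrame(rows)


def treatment_contrast(
    plant_frame: pd.DataFrame,
    genotype: str,
    trait: str,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> ContrastResult:
    """Two-sample t-test of non-F vs +F plant values for one genotype.

    ``plant_frame`` is a per-plant table with columns genotype, treatment
    and the trait.  Welch's unequal-variance test by default
    (``equal_var=True`` for the pooled-variance variant).  Two arms with
    completely identical values give t = 0, p = 1.
    """
    sub = plant_frame[plant_frame["genotype"] == genotype]
    a = sub[sub["treatment"] == "non-F"][trait].to_numpy(dtype=float)
    b = sub[sub["treatment"] == "+F"][trait].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"genotype {genotype}: need >= 2 plants per treatment arm, got {len(a)} and {len(b)}"
        )
    if np.ptp(np.concatenate([a, b])) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return ContrastResult(
        genotype=genotype,
        trait=trait,
        t_statistic=t,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
        n_non_f=len(a),
        n_plus_f=len(b),
    )


def compact_letter_display(
    means: dict[str, float], p_matrix: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a pairwise p-matrix.

    Starts with all groups in one letter column; each significant pair
    splits every column containing both (one copy drops each member);
    columns that become subsets of another are absorbed.  Ties in means
    are broken by group label so the output is deterministic.
    """
    order = sorted(means, key=lambda g: (-means[g], g))
    columns: list[set[str]] = [set(order)]
    sig_pairs = [
        (a, b)
        for a, b in itertools.combinations(order, 2)
        if float(p_matrix.loc[a, b]) < alpha
    ]
    for a, b in sig_pairs:
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = [
            col
            for i, col in enumerate(new_columns)
            if col and not any(i != j and col < other or (col == other and i > j)
                               for j, other in enumerate(new_columns))
        ]
    # letter columns ordered by the best-ranked member they contain
    columns.sort(key=lambda col: min(order.index(g) for g in col))
    alphabet = string.ascii_lowercase
    letters = {g: "" for g in order}
    for i, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def tukey_letters(
    plant_frame: pd.DataFrame,
    trait: str,
    treatment: str,
    alpha: float = 0.05,
    group: str = "genotype",
) -> LetterDisplay:
    """Tukey HSD comparisons among genotypes within one treatment.

    Pairwise studentized-range tests on the group means (scipy's
    ``tukey_hsd``), summarized as a compact letter display.  If every
    observation is identical the p-matrix is all ones (nothing can be
    separated) and all groups share one letter.
    """
    sub = plant_frame[plant_frame["treatment"] == treatment]
    groups = sorted(sub[group].unique())
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups within treatment {treatment!r}, got {len(groups)}")
    samples = []
    for g in groups:
        vals = sub[sub[group] == g][trait].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {g}: need >= 2 observations, got {len(vals)}")
        samples.append(vals)
    means = {g: float(np.mean(v)) for g, v in zip(groups, samples)}
    if np.ptp(np.concatenate(samples)) == 0:
        pmat = pd.DataFrame(np.ones((len(groups), len(groups))), index=groups, columns=groups)
    else:
        res = stats.tukey_hsd(*samples)
        pmat = pd.DataFrame(res.pvalue, index=groups, columns=groups)
    letters = compact_letter_display(means, pmat, alpha=alpha)
    return LetterDisplay(letters=letters, means=means, p_matrix=pmat, alpha=alpha)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def split_plot_anova(plant_frame: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Split-plot ANOVA: fertility on main plots, genotype on subplots.

    Expects a per-plant (or per-subplot) table with columns block,
    treatment, genotype and the trait; plants are first averaged to
    subplot means.  Requires the complete block x treatment x genotype
    cross (no imputation).  Returns the effect table with rows block,
    treatment, main-plot error, genotype, interaction, subplot error and
    total, carrying df, sum of squares, mean square, F and p.

    F for the treatment uses the main-plot error (block x treatment);
    F for genotype and the interaction uses the subplot residual.
    """
    cell = (
        plant_frame.groupby(["block", "treatment", "genotype"], sort=True)[trait]
        .mean()
        .reset_index()
    )
    blocks = sorted(cell["block"].unique())
    treatments = sorted(cell["treatment"].unique())
    genotypes = sorted(cell["genotype"].unique())
    r, a, b = len(blocks), len(treatments), len(genotypes)
    if r < 2 or a < 2 or b < 2:
        raise ValueError("split-plot ANOVA needs >= 2 blocks, treatments and genotypes")
    if len(cell) != r * a * b:
        counts = cell.groupby(["treatment", "genotype"]).size()
        missing = r * a * b - len(cell)
        raise ValueError(
            f"incomplete design: expected {r * a * b} subplot cells, found {len(cell)} "
            f"({missing} missing); cell counts:\n{counts}"
        )

    y = cell.set_index(["block", "treatment", "genotype"])[trait]
    gm = y.mean()
    m_block = y.groupby("block").mean()
    m_trt = y.groupby("treatment").mean()
    m_gen = y.groupby("genotype").mean()
    m_main = y.groupby(["block", "treatment"]).mean()
    m_tg = y.groupby(["treatment", "genotype"]).mean()

    ss_block = a * b * ((m_block - gm) ** 2).sum()
    ss_trt = r * b * ((m_trt - gm) ** 2).sum()
    ss_main = b * ((m_main - gm) ** 2).sum()
    ss_main_err = ss_main - ss_block - ss_trt
    ss_gen = r * a * ((m_gen - gm) ** 2).sum()
    inter = m_tg.copy()
    for (t, g), v in m_tg.items():
        inter.loc[(t, g)] = v - m_trt[t] - m_gen[g] + gm
    ss_int = r * (inter**2).sum()
    ss_total = ((y - gm) ** 2).sum()
    ss_sub_err = ss_total - ss_main - ss_gen - ss_int

    df_block = r - 1
    df_trt = a - 1
    df_main_err = (r - 1) * (a - 1)
    df_gen = b - 1
    df_int = (a - 1) * (b - 1)
    df_sub_err = a * (r - 1) * (b - 1)
    df_total = r * a * b - 1

    ms_main_err = ss_main_err / df_main_err
    ms_sub_err = ss_sub_err / df_sub_err

    def _row(effect, df, ss, ms_err=None, df_err=None):
        ms = ss / df if df > 0 else np.nan
        if ms_err is None:
            return {"effect": effect, "df": df, "ss": ss, "ms": ms, "F": np.nan, "p": np.nan}
        F = ms / ms_err
        return {
            "effect": effect,
            "df": df,
            "ss": ss,
            "ms": ms,
            "F": F,
            "p": float(stats.f.sf(F, df, df_err)),
        }

    table = pd.DataFrame(
        [
            _row("block", df_block, ss_block),
            _row("treatment", df_trt, ss_trt, ms_main_err, df_main_err),
            _row("main_plot_error", df_main_err, ss_main_err),
            _row("genotype", df_gen, ss_gen, ms_sub_err, df_sub_err),
            _row("genotype_x_treatment", df_int, ss_int, ms_sub_err, df_sub_err),
            _row("subplot_error", df_sub_err, ss_sub_err),
            {"effect": "total", "df": df_total, "ss": ss_total, "ms": np.nan, "F": np.nan, "p": np.nan},
        ]
    )
    return table
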