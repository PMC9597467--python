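"""Stress-response and nutrient-use-efficiency indices.

For a trait measured under a low-input (non-F) and a high-input (+F)
environment with genotype means ``x_lf``, ``x_hf`` and trial grand means
``Y_lf``, ``Y_hf``:

* percent difference       PD   = (x_hf - x_lf) / x_hf * 100
* fertility intensity      FII  = 1 - Y_lf / Y_hf
* susceptibility index     SFSI = (1 - x_lf / x_hf) / FII

so that SFSI * FII == PD / 100 identically.  SFSI > 1 marks a genotype
losing proportionally more than the trial average under low fertility
(susceptible); SFSI <= 1 marks a tolerant genotype.

For a nutrient with per-plant supply F (g plant^-1) and mean whole-plant
uptakes ``Ut_F``/``Ut_N`` under +F/non-F:

* apparent recovery efficiency  ANR = (Ut_F - Ut_N) / F * 100      [%]
* physiological efficiency      PE  = (Tw_F - Tw_N) / (Ut_F - Ut_N)

with Tw the mean dry tuber weight; PE is undefined (flagged, not raised)
when the uptake difference is below a small threshold ``eps``.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import biomass, uptake as uptake_mod
from .trial_data import Nutrient, PlantRecord, Treatment, TrialConfig

__all__ = [
    "UndefinedIndexError",
    "percent_difference",
    "fertility_intensity_index",
    "sfsi",
    "apparent_recovery_efficiency",
    "physiological_efficiency",
    "classify_susceptibility",
    "nue_from_means",
    "nue_table",
    "bootstrap_anr_pe",
    "SUSCEPTIBLE",
    "TOLERANT",
    "DEFAULT_PE_EPS",
]

SUSCEPTIBLE = "susceptible"
TOLERANT = "tolerant"

#: Uptake differences (g plant^-1) below this make PE undefined.
DEFAULT_PE_EPS = 1e-6


class UndefinedIndexError(ValueError):
    """An index is undefined for the given inputs (e.g. zero denominator)."""


def percent_difference(x_lf: float, x_hf: float) -> float:
    """Relative trait reduction under non-F, in percent of the +F mean."""
    if x_hf <= 0:
        raise UndefinedIndexError(f"percent difference undefined for +F mean {x_hf}")
    return (x_hf - x_lf) / x_hf * 100.0


def fertility_intensity_index(y_lf: float, y_hf: float) -> float:
    """Trial-wide stress severity 1 - Y_lf / Y_hf from the grand means."""
    if y_hf <= 0:
        raise UndefinedIndexError(f"fertility intensity index undefined for +F grand mean {y_hf}")
    return 1.0 - y_lf / y_hf


def sfsi(x_lf: float, x_hf: float, y_lf: float, y_hf: float) -> float:
    """Soil fertility susceptibility index of one genotype for one trait."""
    fii = fertility_intensity_index(y_lf, y_hf)
    if fii == 0:
        raise UndefinedIndexError("SFSI undefined: zero fertility intensity (no stress differential)")
    if x_hf <= 0:
        raise UndefinedIndexError(f"SFSI undefined for +F genotype mean {x_hf}")
    return (1.0 - x_lf / x_hf) / fii


def apparent_recovery_efficiency(ut_f: float, ut_n: float, f_supply: float) -> float:
    """Percent of the applied nutrient recovered as extra uptake."""
    if f_supply <= 0:
        raise UndefinedIndexError(f"recovery efficiency undefined for supply {f_supply} g/plant")
    return (ut_f - ut_n) / f_supply * 100.0


def physiological_efficiency(
    tw_f: float,
    tw_n: float,
    ut_f: float,
    ut_n: float,
    eps: float = DEFAULT_PE_EPS,
) -> Optional[float]:
    """Extra dry tuber yield per unit extra nutrient uptake (g g^-1).

    Returns ``None`` when |ut_f - ut_n| <= eps: a vanishing uptake
    difference makes the ratio numerically meaningless, and the undefined
    result is propagated as a flagged missing value rather than an
    exception or a silent zero.
    """
    du = ut_f - ut_n
    if abs(du) <= eps:
        return None
    return (tw_f - tw_n) / du


def classify_susceptibility(sfsi_value: float) -> str:
    """``susceptible`` iff SFSI > 1; exactly 1 counts as tolerant."""
    if not math.isfinite(sfsi_value):
        raise UndefinedIndexError(f"cannot classify non-finite SFSI {sfsi_value}")
    return SUSCEPTIBLE if sfsi_value > 1.0 else TOLERANT


def _cell(means: pd.DataFrame, genotype: str, treatment: str, trait: str) -> float:
    sel = means[
        (means["genotype"] == genotype)
        & (means["treatment"] == treatment)
        & (means["trait"] == trait)
    ]["mean"]
    if len(sel) != 1:
        raise ValueError(f"expected one mean for ({genotype}, {treatment}, {trait}), got {len(sel)}")
    return float(sel.iloc[0])


def nue_from_means(
    means: pd.DataFrame,
    supply_g_per_plant: Mapping[str, float],
    eps: float = DEFAULT_PE_EPS,
    grand_mean_convention: str = "genotype_means",
) -> pd.DataFrame:
    """Compute the full index table from genotype x treatment trait means.

    Parameters
    ----------
    means :
        Long frame with columns genotype, treatment, trait, mean, holding
        the weight traits and (optionally) uptake traits.  This may come
        from :func:`yamnue.biomass.summarize` or from a published summary
        table.
    supply_g_per_plant :
        Per-plant nutrient supply, e.g. ``{"N": 4.5, "P": 2.5, "K": 3.75}``.

    Returns
    -------
    Long report with one row per genotype x metric.  Weight-trait rows
    carry pd_pct, sfsi and susceptibility; uptake rows carry anr_pct and
    pe_g_per_g (PE relative to dry tuber weight).  All indices are
    computed at full precision; rounding is left to report time.
    """
    genotypes = sorted(means["genotype"].unique())
    nf, pf = Treatment.NON_F.value, Treatment.PLUS_F.value

    rows = []
    grand: dict[str, dict[str, float]] = {}
    for trait in biomass.WEIGHT_TRAITS:
        if trait not in set(means["trait"]):
            continue
        grand[trait] = biomass.grand_means(means, trait, convention=grand_mean_convention)
        for g in genotypes:
            x_lf, x_hf = _cell(means, g, nf, trait), _cell(means, g, pf, trait)
            s = sfsi(x_lf, x_hf, grand[trait][nf], grand[trait][pf])
            rows.append(
                {
                    "genotype": g,
                    "metric": trait,
                    "non_F_mean": x_lf,
                    "plus_F_mean": x_hf,
                    "pd_pct": percent_difference(x_lf, x_hf),
                    "sfsi": s,
                    "anr_pct": np.nan,
                    "pe_g_per_g": np.nan,
                    "susceptibility": classify_susceptibility(s),
                }
            )

    tuber = biomass.WEIGHT_TRAITS[1]
    have_tuber = tuber in set(means["trait"])
    for nutrient in Nutrient:
        trait = f"uptake_{nutrient.value}_g"
        if trait not in set(means["trait"]):
            continue
        supply = supply_g_per_plant.get(nutrient.value)
        for g in genotypes:
            ut_n, ut_f = _cell(means, g, nf, trait), _cell(means, g, pf, trait)
            anr = (
                apparent_recovery_efficiency(ut_f, ut_n, supply)
                if supply is not None and supply > 0
                else np.nan
            )
            pe = np.nan
            if have_tuber:
                tw_n, tw_f = _cell(means, g, nf, tuber), _cell(means, g, pf, tuber)
                pe_val = physiological_efficiency(tw_f, tw_n, ut_f, ut_n, eps=eps)
                pe = np.nan if pe_val is None else pe_val
            rows.append(
                {
                    "genotype": g,
                    "metric": trait,
                    "non_F_mean": ut_n,
                    "plus_F_mean": ut_f,
                    "pd_pct": np.nan,
                    "sfsi": np.nan,
                    "anr_pct": anr,
                    "pe_g_per_g": pe,
                    "susceptibility": None,
                }
            )
    return pd.DataFrame(rows)


def nue_table(
    records: Sequence[PlantRecord],
    config: TrialConfig,
    policy: uptake_mod.AbsentOrganPolicy = "zero",
    eps: float = DEFAULT_PE_EPS,
    grand_mean_convention: str = "genotype_means",
) -> pd.DataFrame:
    """End-to-end index table from plant-level records.

    Convenience wrapper: summarize the records, then apply
    :func:`nue_from_means` with per-plant supplies from ``config``.
    """
    summary = biomass.summarize(records, include_uptake=True, policy=policy)
    supply = {n.value: config.per_plant_supply(n) for n in Nutrient}
    return nue_from_means(
        summary[["genotype", "treatment", "trait", "mean"]],
        supply,
        eps=eps,
        grand_mean_convention=grand_mean_convention,
    )


def bootstrap_anr_pe(
    records: Sequence[PlantRecord],
    config: TrialConfig,
    n_boot: int = 1000,
    seed: int = 0,
    policy: uptake_mod.AbsentOrganPolicy = "zero",
    eps: float = DEFAULT_PE_EPS,
) -> pd.DataFrame:
    """Block-level bootstrap uncertainty for ANR and PE.

    Blocks (the replicate unit of the design) are resampled with
    replacement; both treatment arms of a resampled block enter together,
    preserving the paired-environment structure of the indices.  Returns
    per genotype x nutrient the point estimate and a percentile 95% CI.
    ``None``/undefined PE draws are dropped from the percentiles and
    counted in ``n_undefined``.
    """
    records = list(records)
    rng = np.random.default_rng(seed)
    blocks = sorted({r.block for r in records})
    by_block: dict[int, list[PlantRecord]] = {b: [] for b in blocks}
    for r in records:
        by_block[r.block].append(r)

    point = nue_table(records, config, policy=policy, eps=eps)
    point = point[point["metric"].str.startswith("uptake_")]

    draws: dict[tuple[str, str], list[dict[str, float]]] = {}
    for _ in range(n_boot):
        chosen = rng.choice(blocks, size=len(blocks), replace=True)
        resample: list[PlantRecord] = []
        for new_block, b in enumerate(chosen, start=1):
            for r in by_block[b]:
                resample.append(r.model_copy(update={"block": new_block}))
        tab = nue_table(resample, config, policy=policy, eps=eps)
        for _, row in tab[tab["metric"].str.startswith("uptake_")].iterrows():
            draws.setdefault((row["genotype"], row["metric"]), []).append(
                {"anr_pct": row["anr_pct"], "pe_g_per_g": row["pe_g_per_g"]}
            )

    rows = []
    for _, prow in point.iterrows():
        key = (prow["genotype"], prow["metric"])
        sample = pd.DataFrame(draws[key])
        row = {"genotype": key[0], "metric": key[1]}
        for col in ("anr_pct", "pe_g_per_g"):
            values = sample[col].dropna().to_numpy()
            row[f"{col}"] = prow[col]
            row[f"{col}_ci_low"] = float(np.percentile(values, 2.5)) if values.size else np.nan
            row[f"{col}_ci_high"] = float(np.percentile(values, 97.5)) if values.size else np.nan
        row["n_undefined"] = int(sample["pe_g_per_g"].isna().sum())
        rows.append(row)
    return pd.DataFrame(rows)
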