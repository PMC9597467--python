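"""Per-plant N/P/K uptake from organ dry weights and tissue concentrations.

Uptake of a nutrient is the sum over plant parts of organ dry weight (g)
times organ tissue concentration (mg g^-1 dry matter), divided by 1000 to
express it in grams per plant.  Organs without assayed concentrations
(stems, in the reference trial design) contribute zero under the default
policy; a strict policy turns them into errors instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .trial_data import Nutrient, PlantRecord

__all__ = ["NutrientUptake", "AbsentOrganPolicy", "plant_uptake", "uptake_frame", "uptake_ratio"]

AbsentOrganPolicy = Literal["zero", "strict"]


@dataclass(frozen=True)
class NutrientUptake:
    """Whole-plant nutrient uptake in g plant^-1."""

    uptake_N_g: float
    uptake_P_g: float
    uptake_K_g: float

    def get(self, nutrient: Nutrient | str) -> float:
        return getattr(self, f"uptake_{Nutrient(nutrient).value}_g")


def plant_uptake(record: PlantRecord, policy: AbsentOrganPolicy = "zero") -> NutrientUptake:
    """Compute whole-plant N, P and K uptake for one sampled plant.

    Parameters
    ----------
    record :
        Plant with organ dry weights; at least one organ must carry tissue
        concentrations.
    policy :
        ``"zero"`` (default): an organ with no concentration for a nutrient
        contributes nothing to that nutrient's uptake.  ``"strict"``: any
        organ missing a concentration raises ``ValueError``.

    Notes
    -----
    Uptake is linear in the organ dry weights and invariant to the order
    in which organs are stored.
    """
    if not any(o.has_concentrations() for o in record.organs):
        raise ValueError(
            f"plant {record.key}: no organ carries tissue concentrations; uptake undefined"
        )
    totals = {n: 0.0 for n in Nutrient}
    for organ in record.organs:
        for nutrient in Nutrient:
            conc = organ.concentration(nutrient)
            if conc is None:
                if policy == "strict":
                    raise ValueError(
                        f"plant {record.key}: organ {organ.organ.value} has no "
                        f"{nutrient.value} concentration (strict policy)"
                    )
                continue
            totals[nutrient] += organ.dry_weight_g * conc / 1000.0
    return NutrientUptake(
        uptake_N_g=totals[Nutrient.N],
        uptake_P_g=totals[Nutrient.P],
        uptake_K_g=totals[Nutrient.K],
    )


def uptake_frame(records: Iterable[PlantRecord], policy: AbsentOrganPolicy = "zero") -> pd.DataFrame:
    """Per-plant uptake table.

    Columns: genotype, block, treatment, plant_id, uptake_N_g, uptake_P_g,
    uptake_K_g.
    """
    rows = []
    for rec in records:
        up = plant_uptake(rec, policy=policy)
        rows.append(
            {
                "genotype": rec.genotype,
                "block": rec.block,
                "treatment": rec.treatment.value,
                "plant_id": rec.plant_id,
                "uptake_N_g": up.uptake_N_g,
                "uptake_P_g": up.uptake_P_g,
                "uptake_K_g": up.uptake_K_g,
            }
        )
    return pd.DataFrame(rows)


def uptake_ratio(
    summary: pd.DataFrame,
    genotype: str,
    treatment: str,
    num: Nutrient | str,
    den: Nutrient | str,
) -> float:
    """Ratio of two mean nutrient uptakes for one genotype x treatment cell.

    ``summary`` is a long mean table with columns genotype, treatment,
    trait, mean (e.g. from :func:`yamnue.biomass.summarize` or the packaged
    reference means).
    """
    num_trait = f"uptake_{Nutrient(num).value}_g"
    den_trait = f"uptake_{Nutrient(den).value}_g"

    def _cell(trait: str) -> float:
        sel = summary[
            (summary["genotype"] == genotype)
            & (summary["treatment"] == treatment)
            & (summary["trait"] == trait)
        ]["mean"]
        if len(sel) != 1:
            raise ValueError(f"expected one mean for ({genotype}, {treatment}, {trait}), got {len(sel)}")
        return float(sel.iloc[0])

    denominator = _cell(den_trait)
    if denominator <= 0:
        raise ZeroDivisionError(
            f"undefined uptake ratio for ({genotype}, {treatment}): denominator mean is {denominator}"
        )
    return _cell(num_trait) / denominator
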