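"""Derived biomass traits and genotype x treatment aggregation.

Per plant: dry shoot weight (leaf dry + stem dry), percent tuber dry
matter (100 x dry/fresh) and total dry tuber weight.  Plants are pooled
across blocks into genotype x treatment cells (the reference design
samples 3 plants x 4 blocks = 12 plants per cell); block identity is kept
only by the split-plot statistics in :mod:`yamnue.trial_stats`.

Grand means per treatment are, by default, unweighted means of the
genotype means.  With balanced data this equals the plant-level mean; the
convention only matters when cells are unbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from . import uptake as uptake_mod
from .trial_data import Organ, PlantRecord, Treatment

__all__ = [
    "DerivedTraits",
    "tuber_dm_percent",
    "total_dry_tuber_weight",
    "dry_shoot_weight",
    "derived_traits",
    "plant_traits",
    "summarize",
    "grand_means",
    "WEIGHT_TRAITS",
]

#: Traits to which the stress indices (percent difference, SFSI) apply.
WEIGHT_TRAITS = ("dry_shoot_weight_g", "dry_tuber_weight_g")


def tuber_dm_percent(sample_fresh_g: float, sample_dry_g: float) -> float:
    """Percent dry matter of the tuber: 100 x sample dry / sample fresh."""
    if sample_fresh_g <= 0:
        raise ValueError(f"sample fresh weight must be > 0, got {sample_fresh_g}")
    if not 0 <= sample_dry_g <= sample_fresh_g:
        raise ValueError(
            f"sample dry weight {sample_dry_g} g outside [0, fresh={sample_fresh_g}] g"
        )
    return 100.0 * sample_dry_g / sample_fresh_g


def total_dry_tuber_weight(total_fresh_g: float, dm_percent: float) -> float:
    """Total dry tuber weight: total fresh weight x percent dry matter / 100."""
    if total_fresh_g < 0:
        raise ValueError(f"total fresh weight must be >= 0, got {total_fresh_g}")
    if not 0 <= dm_percent <= 100:
        raise ValueError(f"dm_percent must be within [0, 100], got {dm_percent}")
    return total_fresh_g * dm_percent / 100.0


def dry_shoot_weight(leaf_dry_g: float, stem_dry_g: float) -> float:
    """Dry shoot weight: leaf dry weight + stem dry weight."""
    if leaf_dry_g < 0 or stem_dry_g < 0:
        raise ValueError(f"dry weights must be >= 0, got ({leaf_dry_g}, {stem_dry_g})")
    return leaf_dry_g + stem_dry_g


@dataclass(frozen=True)
class DerivedTraits:
    dry_shoot_weight_g: float
    dry_tuber_weight_g: float
    tuber_dm_percent: float


def derived_traits(record: PlantRecord) -> DerivedTraits:
    """Derive the biomass traits of one plant.

    The tuber organ is required (its fresh and dry weights give the dry
    matter percentage directly); a missing leaf or stem contributes zero
    to the shoot.
    """
    tuber = record.organ(Organ.TUBER)
    if tuber is None or tuber.fresh_weight_g is None:
        raise ValueError(f"plant {record.key}: tuber with fresh weight required for yield traits")
    leaf = record.organ(Organ.LEAF)
    stem = record.organ(Organ.STEM)
    dm = tuber_dm_percent(tuber.fresh_weight_g, tuber.dry_weight_g)
    return DerivedTraits(
        dry_shoot_weight_g=dry_shoot_weight(
            leaf.dry_weight_g if leaf else 0.0, stem.dry_weight_g if stem else 0.0
        ),
        dry_tuber_weight_g=tuber.dry_weight_g,
        tuber_dm_percent=dm,
    )


def plant_traits(records: Iterable[PlantRecord]) -> pd.DataFrame:
    """Per-plant trait table: one row per plant, one column per trait."""
    rows = []
    for rec in records:
        tr = derived_traits(rec)
        rows.append(
            {
                "genotype": rec.genotype,
                "block": rec.block,
                "treatment": rec.treatment.value,
                "plant_id": rec.plant_id,
                "dry_shoot_weight_g": tr.dry_shoot_weight_g,
                "dry_tuber_weight_g": tr.dry_tuber_weight_g,
                "tuber_dm_percent": tr.tuber_dm_percent,
            }
        )
    return pd.DataFrame(rows)


def summarize(
    records: Sequence[PlantRecord],
    include_uptake: bool = True,
    policy: uptake_mod.AbsentOrganPolicy = "zero",
) -> pd.DataFrame:
    """Genotype x treatment summary of derived traits (and uptakes).

    Returns a long frame with columns genotype, treatment, trait, n, mean,
    sd.  ``sd`` is the sample standard deviation (ddof=1; 0 for singleton
    cells).  Every genotype must appear under both treatments.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    frame = plant_traits(records)
    if include_uptake:
        up = uptake_mod.uptake_frame(records, policy=policy)
        frame = frame.merge(up, on=["genotype", "block", "treatment", "plant_id"])
    # canonical plant order so aggregation is exactly permutation-invariant
    frame = frame.sort_values(["genotype", "treatment", "block", "plant_id"], ignore_index=True)

    trait_cols = [c for c in frame.columns if c not in ("genotype", "block", "treatment", "plant_id")]
    long = frame.melt(
        id_vars=["genotype", "treatment"],
        value_vars=trait_cols,
        var_name="trait",
        value_name="value",
    )
    out = (
        long.groupby(["genotype", "treatment", "trait"], sort=True)["value"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )

    genotypes = sorted(frame["genotype"].unique())
    for g in genotypes:
        for t in Treatment:
            if out[(out["genotype"] == g) & (out["treatment"] == t.value)].empty:
                raise ValueError(f"empty cell: genotype {g}, treatment {t.value}")
    return out


def grand_means(
    summary: pd.DataFrame,
    trait: str,
    convention: Literal["genotype_means", "plants"] = "genotype_means",
) -> dict[str, float]:
    """Per-treatment grand means of a trait.

    ``genotype_means`` (default) averages the genotype means without
    weighting; ``plants`` weights each genotype mean by its plant count
    (requires an ``n`` column).
    """
    sel = summary[summary["trait"] == trait]
    if sel.empty:
        raise ValueError(f"trait {trait!r} not present in summary")
    out: dict[str, float] = {}
    for t in (Treatment.NON_F.value, Treatment.PLUS_F.value):
        cells = sel[sel["treatment"] == t]
        if cells.empty:
            raise ValueError(f"no cells for treatment {t!r} and trait {trait!r}")
        if convention == "genotype_means":
            out[t] = float(cells["mean"].mean())
        elif convention == "plants":
            if "n" not in cells.columns:
                raise ValueError("plant-weighted grand mean requires an 'n' column")
            out[t] = float((cells["mean"] * cells["n"]).sum() / cells["n"].sum())
        else:
            raise ValueError(f"unknown convention {convention!r}")
    return out
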