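"""Reference genotype x treatment means from a two-fertility-level yam trial.

These are the published summary statistics of a split-plot field trial of
six white Guinea yam (*Dioscorea rotundata*) genotypes grown with and
without NPK fertilizer (90/50/75 kg ha^-1 N/P/K, 20,000 plants ha^-1,
four blocks, three sampled plants per subplot).  They serve two roles:

* calibration targets for the synthetic trial generator
  (:mod:`yamnue.synthetic_trial`), so that simulated data reproduce the
  magnitude and genotype ranking of a real trial; and
* a desk-scale input table from which the derived indices (percent
  difference, SFSI, ANR, uptake ratios, correlations) can be recomputed
  and checked against their published counterparts.

They are genotype x treatment *means* (n = 12 plants per cell), printed
at 1 decimal (weights, uptakes) or as shown; they are not plant-level raw
data, which were never deposited.
"""

from __future__ import annotations

import pandas as pd

from .trial_data import TrialConfig, Treatment

__all__ = [
    "GENOTYPES",
    "DEFAULT_TRIAL_CONFIG",
    "reference_means",
    "reference_indices",
    "TRAIT_DRY_SHOOT",
    "TRAIT_DRY_TUBER",
    "TRAIT_DM_PCT",
    "UPTAKE_TRAITS",
]

GENOTYPES = ["TDr1499", "TDr1649", "TDr1899", "TDr2029", "TDr2484", "TDr2948"]

TRAIT_DRY_SHOOT = "dry_shoot_weight_g"
TRAIT_DRY_TUBER = "dry_tuber_weight_g"
TRAIT_DM_PCT = "tuber_dm_percent"
UPTAKE_TRAITS = {"N": "uptake_N_g", "P": "uptake_P_g", "K": "uptake_K_g"}

DEFAULT_TRIAL_CONFIG = TrialConfig(
    rate_N_kg_ha=90.0,
    rate_P_kg_ha=50.0,
    rate_K_kg_ha=75.0,
    plant_density_ha=20000.0,
    n_blocks=4,
)

# genotype -> trait -> (non-F mean, +F mean)
_MEANS: dict[str, dict[str, tuple[float, float]]] = {
    "TDr1499": {
        TRAIT_DRY_SHOOT: (76.9, 130.5),
        TRAIT_DRY_TUBER: (235.5, 489.9),
        TRAIT_DM_PCT: (27.8, 28.6),
        "uptake_N_g": (2.6, 4.7),
        "uptake_P_g": (0.3, 0.8),
        "uptake_K_g": (2.2, 3.9),
    },
    "TDr1649": {
        TRAIT_DRY_SHOOT: (64.5, 108.1),
        TRAIT_DRY_TUBER: (235.8, 433.3),
        TRAIT_DM_PCT: (31.2, 34.1),
        "uptake_N_g": (2.2, 3.7),
        "uptake_P_g": (0.3, 0.6),
        "uptake_K_g": (2.0, 2.8),
    },
    "TDr1899": {
        TRAIT_DRY_SHOOT: (45.3, 60.7),
        TRAIT_DRY_TUBER: (155.8, 239.0),
        TRAIT_DM_PCT: (32.5, 33.1),
        "uptake_N_g": (1.5, 2.3),
        "uptake_P_g": (0.2, 0.3),
        "uptake_K_g": (1.4, 1.9),
    },
    "TDr2029": {
        TRAIT_DRY_SHOOT: (48.3, 56.4),
        TRAIT_DRY_TUBER: (260.0, 313.8),
        TRAIT_DM_PCT: (31.0, 29.3),
        "uptake_N_g": (2.1, 2.9),
        "uptake_P_g": (0.3, 0.4),
        "uptake_K_g": (1.7, 2.1),
    },
    "TDr2484": {
        TRAIT_DRY_SHOOT: (48.6, 63.7),
        TRAIT_DRY_TUBER: (200.0, 262.5),
        TRAIT_DM_PCT: (25.5, 27.0),
        "uptake_N_g": (1.9, 2.6),
        "uptake_P_g": (0.2, 0.4),
        "uptake_K_g": (1.7, 2.1),
    },
    "TDr2948": {
        TRAIT_DRY_SHOOT: (57.8, 78.3),
        TRAIT_DRY_TUBER: (260.7, 370.3),
        TRAIT_DM_PCT: (28.2, 28.7),
        "uptake_N_g": (2.9, 3.5),
        "uptake_P_g": (0.3, 0.6),
        "uptake_K_g": (2.1, 2.9),
    },
}

# genotype -> trait -> (published percent difference, published SFSI)
_PUBLISHED_INDICES: dict[str, dict[str, tuple[float, float]]] = {
    "TDr1499": {TRAIT_DRY_SHOOT: (41.1, 1.31), TRAIT_DRY_TUBER: (51.9, 1.44)},
    "TDr1649": {TRAIT_DRY_SHOOT: (40.3, 1.28), TRAIT_DRY_TUBER: (45.6, 1.26)},
    "TDr1899": {TRAIT_DRY_SHOOT: (25.5, 0.81), TRAIT_DRY_TUBER: (34.8, 0.96)},
    "TDr2029": {TRAIT_DRY_SHOOT: (14.3, 0.46), TRAIT_DRY_TUBER: (17.2, 0.48)},
    "TDr2484": {TRAIT_DRY_SHOOT: (23.7, 0.75), TRAIT_DRY_TUBER: (23.8, 0.66)},
    "TDr2948": {TRAIT_DRY_SHOOT: (26.2, 0.83), TRAIT_DRY_TUBER: (29.6, 0.82)},
}


def reference_means() -> pd.DataFrame:
    """Published trait means as a long frame.

    Columns: genotype, treatment, trait, mean — the same layout produced by
    :func:`yamnue.biomass.summarize` (without n/sd, which were not
    published at plant level).
    """
    rows = []
    for genotype, traits in _MEANS.items():
        for trait, (non_f, plus_f) in traits.items():
            rows.append((genotype, Treatment.NON_F.value, trait, non_f))
            rows.append((genotype, Treatment.PLUS_F.value, trait, plus_f))
    return pd.DataFrame(rows, columns=["genotype", "treatment", "trait", "mean"])


def reference_indices() -> pd.DataFrame:
    """Published percent-difference and SFSI values for the weight traits."""
    rows = []
    for genotype, traits in _PUBLISHED_INDICES.items():
        for trait, (pd_pct, sfsi) in traits.items():
            rows.append((genotype, trait, pd_pct, sfsi))
    return pd.DataFrame(rows, columns=["genotype", "trait", "pd_pct", "sfsi"])
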