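"""Synthetic split-plot trial generator.

Emulates the reference design — a split-plot randomized block trial with
the fertility treatment on main plots, genotypes on subplots, four blocks
and three destructively sampled plants per subplot — and produces
plant-level records that satisfy every :mod:`yamnue.trial_data`
invariant.

Mean structure per genotype: the +F dry tuber weight is a base parameter
and the non-F mean is base x (1 - responsiveness), so ``responsiveness``
is exactly the target percent difference / 100.  Dry shoot weight is
parameterized the same way.  Noise is multiplicative lognormal (weights
are positive and right-skewed) at three levels — main plot (block x
treatment), subplot (block x treatment x genotype) and plant — each
scaled by a coefficient of variation and mean-corrected so expectations
stay at the configured targets.  Fresh tuber weight is derived from the
dry weight and the genotype's percent dry matter; the shoot is split
into leaf and stem by a fixed fraction (0.55:0.45 by default — the
reference trial reports no split, so this is a documented free
parameter).  Tissue concentrations are drawn around organ x nutrient
means with a multiplicative +F response; stems carry no concentrations,
matching a design in which only leaf and tuber tissue were assayed.

The packaged default configuration is calibrated so that genotype x
treatment means of dry weights, dry matter content and N/P/K uptake
reproduce the published reference means of :mod:`yamnue.calibration`
(approximately under noise, exactly in the zero-noise limit).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import calibration, nue_indices
from .trial_data import (
    Nutrient,
    Organ,
    OrganMeasurement,
    PlantRecord,
    Treatment,
    TrialConfig,
)

__all__ = [
    "GenotypeParams",
    "VarianceComponents",
    "SimConfig",
    "default_sim_config",
    "simulate_trial",
    "true_indices",
    "recovery_experiment",
    "RecoveryReport",
]

#: Leaf tissue N/P/K concentrations (mg g^-1 dry matter) shared by the
#: default genotypes under non-F; within the range reported for yam leaf
#: tissue.  Tuber concentrations and +F multipliers are solved per
#: genotype from the uptake calibration targets.
_DEFAULT_LEAF_CONC = {"N": 25.0, "P": 2.5, "K": 20.0}


class GenotypeParams(BaseModel):
    """Mean-structure parameters of one simulated genotype."""

    model_config = ConfigDict(frozen=True)

    name: str
    tuber_dry_plus_f_g: float = Field(gt=0)
    tuber_responsiveness: float = Field(gt=-1, lt=1)
    shoot_dry_plus_f_g: float = Field(gt=0)
    shoot_responsiveness: float = Field(gt=-1, lt=1)
    dm_percent_non_f: float = Field(gt=0, lt=100)
    dm_percent_plus_f: float = Field(gt=0, lt=100)
    leaf_conc_mg_g: dict[str, float]
    tuber_conc_mg_g: dict[str, float]
    conc_plus_f_multiplier: dict[str, float]

    @model_validator(mode="after")
    def _conc_keys(self):
        for field in ("leaf_conc_mg_g", "tuber_conc_mg_g", "conc_plus_f_multiplier"):
            d = getattr(self, field)
            if set(d) != {"N", "P", "K"}:
                raise ValueError(f"{field} must have exactly the keys N, P, K")
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{field} must be non-negative")
        return self


class VarianceComponents(BaseModel):
    """Coefficients of variation of the three lognormal noise levels.

    Defaults (0.10 main plot, 0.10 subplot, 0.20 plant) give per-cell
    dispersions comparable to field variability in tuber crops, where
    plant-to-plant variation dominates.
    """

    model_config = ConfigDict(frozen=True)

    main_plot_cv: float = Field(default=0.10, ge=0)
    subplot_cv: float = Field(default=0.10, ge=0)
    plant_cv: float = Field(default=0.20, ge=0)
    conc_cv: float = Field(default=0.05, ge=0)
    dm_sd_pct: float = Field(default=1.0, ge=0)


class SimConfig(BaseModel):
    """Full configuration of a simulated trial."""

    model_config = ConfigDict(frozen=True)

    seed: int
    n_blocks: int = Field(default=4, ge=2)
    n_plants_per_subplot: int = Field(default=3, ge=1)
    genotypes: tuple[GenotypeParams, ...]
    variance: VarianceComponents = VarianceComponents()
    leaf_fraction_of_shoot: float = Field(default=0.55, gt=0, lt=1)
    shoot_dm_fraction: float = Field(default=0.25, gt=0, lt=1)

    @model_validator(mode="after")
    def _unique_names(self):
        names = [g.name for g in self.genotypes]
        if len(names) != len(set(names)):
            raise ValueError("genotype names must be unique")
        if not names:
            raise ValueError("at least one genotype required")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"simulation config {path} must be a YAML mapping")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def _calibrated_genotype(name: str, means: pd.DataFrame) -> GenotypeParams:
    """Solve generator parameters from one genotype's reference means."""

    def cell(trait: str, treatment: str) -> float:
        sel = means[
            (means["genotype"] == name)
            & (means["treatment"] == treatment)
            & (means["trait"] == trait)
        ]["mean"]
        return float(sel.iloc[0])

    nf, pf = Treatment.NON_F.value, Treatment.PLUS_F.value
    tuber_f = cell(calibration.TRAIT_DRY_TUBER, pf)
    tuber_n = cell(calibration.TRAIT_DRY_TUBER, nf)
    shoot_f = cell(calibration.TRAIT_DRY_SHOOT, pf)
    shoot_n = cell(calibration.TRAIT_DRY_SHOOT, nf)
    leaf_frac = 0.55

    tuber_conc: dict[str, float] = {}
    multiplier: dict[str, float] = {}
    for nutrient, trait in calibration.UPTAKE_TRAITS.items():
        target_n = cell(trait, nf) * 1000.0  # mg
        target_f = cell(trait, pf) * 1000.0
        leaf_dry_n = leaf_frac * shoot_n
        leaf_dry_f = leaf_frac * shoot_f
        leaf_conc = _DEFAULT_LEAF_CONC[nutrient]
        tc = (target_n - leaf_dry_n * leaf_conc) / tuber_n
        if tc < 0:
            raise ValueError(f"{name}/{nutrient}: calibration yields negative tuber concentration")
        base_f = leaf_dry_f * leaf_conc + tuber_f * tc
        tuber_conc[nutrient] = tc
        multiplier[nutrient] = target_f / base_f

    return GenotypeParams(
        name=name,
        tuber_dry_plus_f_g=tuber_f,
        tuber_responsiveness=1.0 - tuber_n / tuber_f,
        shoot_dry_plus_f_g=shoot_f,
        shoot_responsiveness=1.0 - shoot_n / shoot_f,
        dm_percent_non_f=cell(calibration.TRAIT_DM_PCT, nf),
        dm_percent_plus_f=cell(calibration.TRAIT_DM_PCT, pf),
        leaf_conc_mg_g=dict(_DEFAULT_LEAF_CONC),
        tuber_conc_mg_g=tuber_conc,
        conc_plus_f_multiplier=multiplier,
    )


def default_sim_config(seed: int = 42, **overrides) -> SimConfig:
    """Packaged default configuration, calibrated to the reference means.

    The six genotypes reproduce the published genotype x treatment means
    of dry shoot weight, dry tuber weight, tuber dry matter content and
    N/P/K uptake in expectation.
    """
    means = calibration.reference_means()
    genotypes = tuple(_calibrated_genotype(g, means) for g in calibration.GENOTYPES)
    return SimConfig(seed=seed, genotypes=genotypes, **overrides)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Mean-1 lognormal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


def simulate_trial(config: SimConfig, rng: Optional[np.random.Generator] = None) -> list[PlantRecord]:
    """Generate one realization of the trial as plant-level records.

    Deterministic given ``config.seed`` (or an explicitly supplied
    generator).  Iteration order — treatment, block, genotype, plant —
    is fixed, so identical configurations give byte-identical CSVs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    v = config.variance
    records: list[PlantRecord] = []
    for treatment in (Treatment.NON_F, Treatment.PLUS_F):
        fert = treatment is Treatment.PLUS_F
        for block in range(1, config.n_blocks + 1):
            main_factor = _lognormal_factor(rng, v.main_plot_cv)
            for geno in config.genotypes:
                sub_factor = _lognormal_factor(rng, v.subplot_cv)
                stress_t = 1.0 if fert else 1.0 - geno.tuber_responsiveness
                stress_s = 1.0 if fert else 1.0 - geno.shoot_responsiveness
                mu_tuber = geno.tuber_dry_plus_f_g * stress_t * main_factor * sub_factor
                mu_shoot = geno.shoot_dry_plus_f_g * stress_s * main_factor * sub_factor
                dm_target = geno.dm_percent_plus_f if fert else geno.dm_percent_non_f
                for plant in range(1, config.n_plants_per_subplot + 1):
                    tuber_dry = mu_tuber * _lognormal_factor(rng, v.plant_cv)
                    shoot_dry = mu_shoot * _lognormal_factor(rng, v.plant_cv)
                    dm = dm_target + (rng.standard_normal() * v.dm_sd_pct if v.dm_sd_pct else 0.0)
                    dm = float(np.clip(dm, 5.0, 65.0))
                    leaf_dry = config.leaf_fraction_of_shoot * shoot_dry
                    stem_dry = shoot_dry - leaf_dry

                    conc = {}
                    for organ_name, base in (("leaf", geno.leaf_conc_mg_g), ("tuber", geno.tuber_conc_mg_g)):
                        conc[organ_name] = {}
                        for n in ("N", "P", "K"):
                            c = base[n] * (geno.conc_plus_f_multiplier[n] if fert else 1.0)
                            conc[organ_name][n] = c * _lognormal_factor(rng, v.conc_cv)

                    organs = (
                        OrganMeasurement(
                            organ=Organ.LEAF,
                            fresh_weight_g=leaf_dry / config.shoot_dm_fraction,
                            dry_weight_g=leaf_dry,
                            conc_N_mg_g=conc["leaf"]["N"],
                            conc_P_mg_g=conc["leaf"]["P"],
                            conc_K_mg_g=conc["leaf"]["K"],
                        ),
                        OrganMeasurement(
                            organ=Organ.STEM,
                            fresh_weight_g=stem_dry / config.shoot_dm_fraction,
                            dry_weight_g=stem_dry,
                        ),
                        OrganMeasurement(
                            organ=Organ.TUBER,
                            fresh_weight_g=tuber_dry / (dm / 100.0),
                            dry_weight_g=tuber_dry,
                            conc_N_mg_g=conc["tuber"]["N"],
                            conc_P_mg_g=conc["tuber"]["P"],
                            conc_K_mg_g=conc["tuber"]["K"],
                        ),
                    )
                    records.append(
                        PlantRecord(
                            genotype=geno.name,
                            block=block,
                            treatment=treatment,
                            plant_id=f"p{plant}",
                            organs=organs,
                        )
                    )
    return records


def _zero_noise(config: SimConfig) -> SimConfig:
    return config.model_copy(
        update={
            "variance": VarianceComponents(
                main_plot_cv=0.0, subplot_cv=0.0, plant_cv=0.0, conc_cv=0.0, dm_sd_pct=0.0
            )
        }
    )


def true_indices(config: SimConfig, trial_config: TrialConfig | None = None) -> pd.DataFrame:
    """Index values implied by the configured means (noise-free pipeline).

    Runs the full analysis on a zero-noise realization, so 'truth' is
    defined by the same estimators the pipeline applies to data.
    """
    if trial_config is None:
        trial_config = calibration.DEFAULT_TRIAL_CONFIG
    records = simulate_trial(_zero_noise(config))
    return nue_indices.nue_table(records, trial_config)


@dataclass(frozen=True)
class RecoveryReport:
    """Output of :func:`recovery_experiment`.

    ``summary`` has one row per genotype x metric with the configured
    truth, mean estimate, bias and RMSE over replicates;
    ``spearman_sfsi`` holds the per-replicate Spearman rank correlation
    between estimated and true dry-tuber SFSI across genotypes.
    """

    summary: pd.DataFrame
    spearman_sfsi: np.ndarray
    n_reps: int

    def sfsi_rank_spearman(self) -> float:
        """Spearman correlation of the replicate-averaged SFSI vs truth."""
        sub = self.summary[self.summary["metric"] == "sfsi_dry_tuber"]
        from scipy import stats as _stats

        return float(_stats.spearmanr(sub["mean_estimate"], sub["truth"]).statistic)


def _extract_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Pull the recovery metrics (SFSI, ANR, PE) out of a nue_table."""
    rows = []
    tuber = table[table["metric"] == calibration.TRAIT_DRY_TUBER]
    for _, r in tuber.iterrows():
        rows.append({"genotype": r["genotype"], "metric": "sfsi_dry_tuber", "value": r["sfsi"]})
    for n in Nutrient:
        up = table[table["metric"] == f"uptake_{n.value}_g"]
        for _, r in up.iterrows():
            rows.append({"genotype": r["genotype"], "metric": f"anr_{n.value}", "value": r["anr_pct"]})
            rows.append({"genotype": r["genotype"], "metric": f"pe_{n.value}", "value": r["pe_g_per_g"]})
    return pd.DataFrame(rows)


def recovery_experiment(
    config: SimConfig,
    n_reps: int,
    trial_config: TrialConfig | None = None,
) -> RecoveryReport:
    """Simulate-and-reanalyse experiment: how well does the pipeline
    recover the configured SFSI, ANR and PE?

    Each replicate draws a fresh trial (independent substreams spawned
    from ``config.seed``), runs the full analysis, and records the
    estimates; the report aggregates bias and RMSE against the
    noise-free truth and keeps the per-replicate SFSI rank correlation.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if trial_config is None:
        trial_config = calibration.DEFAULT_TRIAL_CONFIG
    truth = _extract_metrics(true_indices(config, trial_config))
    truth = truth.rename(columns={"value": "truth"})

    from scipy import stats as _stats

    streams = np.random.SeedSequence(config.seed).spawn(n_reps)
    estimates = []
    spearman = np.empty(n_reps)
    true_sfsi = truth[truth["metric"] == "sfsi_dry_tuber"].set_index("genotype")["truth"]
    for i, ss in enumerate(streams):
        records = simulate_trial(config, rng=np.random.default_rng(ss))
        table = nue_indices.nue_table(records, trial_config)
        met = _extract_metrics(table)
        met["rep"] = i
        estimates.append(met)
        est_sfsi = met[met["metric"] == "sfsi_dry_tuber"].set_index("genotype")["value"]
        spearman[i] = _stats.spearmanr(
            est_sfsi.reindex(true_sfsi.index), true_sfsi
        ).statistic

    allest = pd.concat(estimates, ignore_index=True)
    merged = allest.merge(truth, on=["genotype", "metric"])
    merged["err"] = merged["value"] - merged["truth"]
    summary = (
        merged.groupby(["genotype", "metric"])
        .agg(
            truth=("truth", "first"),
            mean_estimate=("value", "mean"),
            bias=("err", "mean"),
            rmse=("err", lambda e: float(np.sqrt(np.nanmean(np.square(e)))) if e.notna().any() else np.nan),
            n_defined=("value", lambda v: int(v.notna().sum())),
        )
        .reset_index()
    )
    return RecoveryReport(summary=summary, spearman_sfsi=spearman, n_reps=n_reps)
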