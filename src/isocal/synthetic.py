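"""Synthetic isolator-calorimetry studies.

Generates complete studies — body-composition profiles, raw cage traces,
fecal output, cytometry assays, cecal metabolite tables — for germ-free
(GF), gnotobiotic (OLIGO, a defined 12-strain community) and conventionally
raised (SPF) mice, with the statistical structure the analysis assumes and
a ground-truth sidecar for parameter-recovery tests.

Defaults encode the study conditions this pipeline targets: cecal mass
about 0.5 / 1.5 / 3 g for SPF / OLIGO / GF, GF food intake 10-20 % above
colonized mice, fecal energy density 3.7 (GF) vs 4.0 (colonized) kcal/g,
all groups absorbing close to 9 kcal/day, colonized cecal densities near
1.1e11 (OLIGO) and 1.6e11 (SPF) cells/g, a 24-min cadence at 0.4 L/min
flow, and a ~10 % overall fault rate split across the fault taxonomy the
QC rules target (balance noise sentinel, negative differentials, leaky
bottles / dropped pellets, depressed gas differentials from unsealed cages
or clogged filters).

Traces are emitted in raw gas-differential space by inverting the Haldane
mass balance from the latent energy-expenditure and RER curves, so the
pipeline's forward computation is exercised nontrivially.  Energy
expenditure varies sinusoidally over the day around a lean-mass-driven
daily total (the modulation integrates to zero over 24 h); RER and
hydrogen follow smooth light/dark profiles; feeding happens in discrete
bouts concentrated in the dark phase.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iio
from .gas import DEFAULT_CONSTANTS, GasConstants, invert_haldane
from .qc import RULE_FOOD_SENTINEL, RULE_GAS_OUTLIER, RULE_INTAKE_OUTLIER, RULE_NEGATIVE

GROUPS = ("GF", "OLIGO", "SPF")


def _phase_blend(zt: np.ndarray) -> np.ndarray:
    """0 at mid-light (ZT 6), 1 at mid-dark (ZT 18), smooth and 24h-periodic."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (np.asarray(zt) - 6.0) / 24.0))


@dataclass(frozen=True)
class FaultSpec:
    """Per-record probabilities of each injected fault type."""

    food_sentinel: float = 0.03
    negative_value: float = 0.03
    intake_outlier: float = 0.02
    gas_outlier: float = 0.015

    def total(self) -> float:
        return self.food_sentinel + self.negative_value + self.intake_outlier + self.gas_outlier


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic GF / OLIGO / SPF study."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"GF": 10, "OLIGO": 10, "SPF": 10}
    )
    days: int = 10
    cadence_min: float = 24.0
    flow_lpm: float = 0.4
    lights_on: dt.time = dt.time(7, 0)
    start: dt.datetime = dt.datetime(2022, 3, 1, 7, 0)
    pre_zt0_records: int = 0  # lead-in records before the first lights-on

    # body composition (grams)
    lean_mean: dict[str, float] = field(
        default_factory=lambda: {"GF": 19.5, "OLIGO": 20.0, "SPF": 20.5}
    )
    lean_sd: float = 1.5
    fat_depot_mean: dict[str, float] = field(
        default_factory=lambda: {"fat_ibat_g": 0.15, "fat_iwat_g": 0.45, "fat_vwat_g": 0.55}
    )
    fat_depot_sd: dict[str, float] = field(
        default_factory=lambda: {"fat_ibat_g": 0.03, "fat_iwat_g": 0.10, "fat_vwat_g": 0.12}
    )
    fat_group_multiplier: dict[str, float] = field(
        default_factory=lambda: {"GF": 1.0, "OLIGO": 1.4, "SPF": 1.0}
    )
    cecal_mass: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"GF": (3.0, 0.4), "OLIGO": (1.5, 0.2), "SPF": (0.5, 0.1)}
    )
    other_mass_mean: float = 5.0
    other_mass_sd: float = 0.5

    # energy expenditure model (kcal/day): intercept + slope*lean + group effect
    ee_intercept: float = 3.0
    ee_slope_per_g_lean: float = 0.30
    ee_group_effect: dict[str, float] = field(
        default_factory=lambda: {"GF": 0.0, "OLIGO": 0.0, "SPF": 0.0}
    )
    ee_mouse_sd: float = 0.25
    ee_amplitude: float = 0.30  # relative circadian modulation
    ee_peak_zt: float = 18.0

    # RER per group x phase (dimensionless)
    rer_light: dict[str, float] = field(
        default_factory=lambda: {"GF": 0.80, "OLIGO": 0.84, "SPF": 0.90}
    )
    rer_dark: dict[str, float] = field(
        default_factory=lambda: {"GF": 0.88, "OLIGO": 0.97, "SPF": 0.98}
    )

    # hydrogen: dark-phase peak scaled by cecal mass; GF is blank noise
    h2_peak_ppm_per_g_cecal: dict[str, float] = field(
        default_factory=lambda: {"GF": 0.0, "OLIGO": 9.0, "SPF": 4.0}
    )
    h2_blank_sd_ppm: float = 0.3

    # sensor noise on gas differentials (volume fraction)
    gas_noise_sd: float = 4e-5

    # intake (grams/day); GF eat 10-20 % more than colonized mice
    intake_g_day: dict[str, float] = field(
        default_factory=lambda: {"GF": 4.0, "OLIGO": 3.5, "SPF": 3.5}
    )
    intake_mouse_sd: float = 0.25
    dark_intake_fraction: float = 0.75
    bout_prob_light: float = 0.50
    bout_prob_dark: float = 0.90
    water_g_day: float = 4.5

    # fecal model: dry mass set so extraction is near absorbed_kcal_day
    absorbed_kcal_day: float = 9.0
    fecal_energy: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"GF": (3.7, 0.1), "OLIGO": (4.0, 0.1), "SPF": (4.0, 0.1)}
    )
    fecal_mass_sd: float = 0.05

    # cytometry
    cecal_density_per_g: dict[str, float] = field(
        default_factory=lambda: {"GF": 0.0, "OLIGO": 1.1e11, "SPF": 1.6e11}
    )
    cecal_density_cv: float = 0.15
    blank_events: int = 30

    # cecal metabolites, umol per g content: group -> (mean, sd)
    metabolites: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "acetate": {"GF": (0.2, 0.1), "OLIGO": (25.0, 6.0), "SPF": (60.0, 12.0)},
            "propionate": {"GF": (0.1, 0.05), "OLIGO": (5.0, 2.0), "SPF": (12.0, 3.0)},
            "butyrate": {"GF": (0.05, 0.05), "OLIGO": (2.0, 1.0), "SPF": (8.0, 2.0)},
            "lactate": {"GF": (8.0, 3.0), "OLIGO": (15.0, 5.0), "SPF": (5.0, 2.0)},
            "succinate": {"GF": (1.0, 0.5), "OLIGO": (8.0, 3.0), "SPF": (3.0, 1.0)},
        }
    )

    faults: FaultSpec = FaultSpec()
    seed: int = 0

    def dialect(self) -> iio.StudyDialect:
        return iio.StudyDialect(lights_on=self.lights_on, cadence_min=self.cadence_min)

    def noiseless(self) -> "CohortConfig":
        """Copy with all measurement noise and faults switched off."""
        return dataclasses.replace(
            self,
            gas_noise_sd=0.0,
            h2_blank_sd_ppm=0.0,
            ee_mouse_sd=0.0,
            fecal_mass_sd=0.0,
            faults=FaultSpec(0.0, 0.0, 0.0, 0.0),
        )


@dataclass
class SyntheticStudy:
    """A generated study plus its ground truth."""

    profiles: pd.DataFrame
    traces: pd.DataFrame
    fecal: pd.DataFrame
    intake_daily: pd.DataFrame
    assays: pd.DataFrame
    metabolites: pd.DataFrame
    truth: dict
    fault_log: pd.DataFrame
    config: CohortConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dialect = self.config.dialect()
        iio.write_traces(self.traces, outdir / "traces.csv", dialect)
        iio.write_profiles(self.profiles, outdir / "profiles.csv")
        self.fecal.to_csv(outdir / "fecal.csv", index=False)
        self.intake_daily.to_csv(outdir / "intake_daily.csv", index=False)
        self.assays.to_csv(outdir / "cytometry.csv", index=False)
        self.metabolites.to_csv(outdir / "metabolites.csv", index=False)
        self.truth["per_mouse"].to_csv(outdir / "truth_per_mouse.csv", index=False)
        self.fault_log.to_csv(outdir / "truth_faults.csv", index=False)


def _make_profiles(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group in GROUPS:
        for i in range(cfg.n_per_group.get(group, 0)):
            lean = rng.normal(cfg.lean_mean[group], cfg.lean_sd)
            mult = cfg.fat_group_multiplier[group]
            fats = {
                d: max(0.01, rng.normal(cfg.fat_depot_mean[d] * mult, cfg.fat_depot_sd[d]))
                for d in cfg.fat_depot_mean
            }
            cec_mu, cec_sd = cfg.cecal_mass[group]
            cecal = max(0.05, rng.normal(cec_mu, cec_sd))
            other = rng.normal(cfg.other_mass_mean, cfg.other_mass_sd)
            nocecum = lean + sum(fats.values()) + other
            rows.append(
                {
                    "mouse_id": f"{group}{i + 1:02d}",
                    "group": group,
                    "total_mass_g": nocecum + cecal,
                    "total_mass_nocecum_g": nocecum,
                    "lean_mass_g": lean,
                    **fats,
                    "cecal_mass_g": cecal,
                }
            )
    return pd.DataFrame(rows)


def _mouse_trace(
    cfg: CohortConfig,
    rng: np.random.Generator,
    mouse: pd.Series,
    ee_daily: float,
    constants: GasConstants,
    cage_index: int = 0,
) -> pd.DataFrame:
    slots_per_day = int(round(24.0 * 60.0 / cfg.cadence_min))
    n = cfg.days * slots_per_day
    idx = np.arange(-cfg.pre_zt0_records, n)
    t_h = idx * cfg.cadence_min / 60.0
    zt = t_h % 24.0
    timestamps = pd.Timestamp(cfg.start) + pd.to_timedelta(t_h, unit="h")

    blend = _phase_blend(zt)
    group = mouse["group"]

    ee_rate = (ee_daily / 1440.0) * (
        1.0 + cfg.ee_amplitude * np.cos(2.0 * np.pi * (zt - cfg.ee_peak_zt) / 24.0)
    )
    rer = cfg.rer_light[group] + (cfg.rer_dark[group] - cfg.rer_light[group]) * blend
    vo2 = ee_rate / (constants.weir_o2 + constants.weir_co2 * rer)
    vco2 = rer * vo2
    d_o2, d_co2 = invert_haldane(vo2, vco2, cfg.flow_lpm, constants)
    if cfg.gas_noise_sd > 0:
        d_o2 = d_o2 + rng.normal(0.0, cfg.gas_noise_sd, n + cfg.pre_zt0_records)
        d_co2 = d_co2 + rng.normal(0.0, cfg.gas_noise_sd, n + cfg.pre_zt0_records)

    h2 = cfg.h2_peak_ppm_per_g_cecal[group] * mouse["cecal_mass_g"] * blend
    if cfg.h2_blank_sd_ppm > 0:
        h2 = h2 + rng.normal(0.0, cfg.h2_blank_sd_ppm, n + cfg.pre_zt0_records)

    # feeding bouts: Bernoulli per slot, gamma-distributed amounts, dark-heavy
    daily = max(0.2, rng.normal(cfg.intake_g_day[group], cfg.intake_mouse_sd))
    dark = zt >= 12.0
    p = np.where(dark, cfg.bout_prob_dark, cfg.bout_prob_light)
    share = np.where(dark, cfg.dark_intake_fraction, 1.0 - cfg.dark_intake_fraction)
    mean_bout = share * daily / (p * slots_per_day / 2.0)
    eating = rng.random(len(zt)) < p
    shape = 4.0
    food = np.where(eating, rng.gamma(shape, np.maximum(mean_bout, 1e-6) / shape), 0.0)
    food = np.round(food, 2)
    water_bout = share * cfg.water_g_day / (p * slots_per_day / 2.0)
    drinking = rng.random(len(zt)) < p
    water = np.where(drinking, rng.gamma(shape, water_bout / shape), 0.0)
    water = np.round(water, 2)

    return pd.DataFrame(
        {
            "mouse_id": mouse["mouse_id"],
            "cage_id": f"cage{(cage_index % 8) + 1}",
            "timestamp": timestamps,
            "d_o2": d_o2,
            "d_co2": d_co2,
            "d_h2": h2,
            "food_g": food,
            "water_g": water,
            "flow_lpm": cfg.flow_lpm,
            "zt": zt,
        }
    )


def inject_faults(
    traces: pd.DataFrame, spec: FaultSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a trace frame with the faults the QC rules target.

    Each record independently receives at most one fault.  Returns the
    corrupted frame and a ground-truth log with the QC rule expected to
    catch each fault.
    """
    rng = np.random.default_rng(seed)
    df = traces.reset_index(drop=True).copy()
    u = rng.random(len(df))
    log_rows = []
    edges = np.cumsum(
        [spec.food_sentinel, spec.negative_value, spec.intake_outlier, spec.gas_outlier]
    )
    kind = np.full(len(df), "", dtype=object)
    kind[u < edges[0]] = RULE_FOOD_SENTINEL
    kind[(u >= edges[0]) & (u < edges[1])] = RULE_NEGATIVE
    kind[(u >= edges[1]) & (u < edges[2])] = RULE_INTAKE_OUTLIER
    kind[(u >= edges[2]) & (u < edges[3])] = RULE_GAS_OUTLIER

    for i in np.flatnonzero(kind == RULE_FOOD_SENTINEL):
        df.at[i, "food_g"] = 0.01
    for i in np.flatnonzero(kind == RULE_NEGATIVE):
        col = rng.choice(["food_g", "water_g", "d_o2", "d_co2"])
        scale = {"food_g": 0.05, "water_g": 0.2, "d_o2": 1e-3, "d_co2": 1e-3}[col]
        df.at[i, col] = -abs(rng.normal(scale, scale / 4))
    for i in np.flatnonzero(kind == RULE_INTAKE_OUTLIER):
        col = rng.choice(["food_g", "water_g"])
        df.at[i, col] = df.at[i, col] + rng.uniform(2.0, 5.0)  # spilled pellet / leak
    for i in np.flatnonzero(kind == RULE_GAS_OUTLIER):
        # unsealed cage or clogged filter: differential collapses toward zero
        df.at[i, "d_o2"] = df.at[i, "d_o2"] * 0.05
        df.at[i, "d_co2"] = df.at[i, "d_co2"] * 0.05

    for i in np.flatnonzero(kind != ""):
        log_rows.append(
            {
                "mouse_id": df.at[i, "mouse_id"],
                "timestamp": df.at[i, "timestamp"],
                "expected_rule": kind[i],
            }
        )
    log = pd.DataFrame(log_rows, columns=["mouse_id", "timestamp", "expected_rule"])
    return df, log


def generate_cohort(cfg: CohortConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate a full synthetic study; bitwise-reproducible given a seed."""
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    constants = DEFAULT_CONSTANTS

    profiles = _make_profiles(cfg, rng)

    traces = []
    truth_rows = []
    intake_rows = []
    fecal_rows = []
    slots_per_day = int(round(24.0 * 60.0 / cfg.cadence_min))
    for m_idx, (_, mouse) in enumerate(profiles.iterrows()):
        group = mouse["group"]
        ee_daily = (
            cfg.ee_intercept
            + cfg.ee_slope_per_g_lean * mouse["lean_mass_g"]
            + cfg.ee_group_effect[group]
            + (rng.normal(0.0, cfg.ee_mouse_sd) if cfg.ee_mouse_sd > 0 else 0.0)
        )
        tr = _mouse_trace(cfg, rng, mouse, ee_daily, constants, cage_index=m_idx)
        traces.append(tr)
        truth_rows.append(
            {
                "mouse_id": mouse["mouse_id"],
                "group": group,
                "latent_ee_kcal_day": ee_daily,
                "lean_mass_g": mouse["lean_mass_g"],
                "cecal_mass_g": mouse["cecal_mass_g"],
            }
        )
        tmask = np.arange(len(tr)) >= cfg.pre_zt0_records
        t_h = (np.arange(len(tr)) - cfg.pre_zt0_records) * cfg.cadence_min / 60.0
        days = np.floor(t_h / 24.0).astype(int)
        ed_mu, ed_sd = cfg.fecal_energy[group]
        for d in range(cfg.days):
            sel = tmask & (days == d)
            intake = float(tr.loc[sel, "food_g"].sum())
            intake_rows.append({"mouse_id": mouse["mouse_id"], "day": d, "intake_g": intake})
            energy_density = max(0.5, rng.normal(ed_mu, ed_sd))
            dry = (intake * 3.94 - cfg.absorbed_kcal_day) / energy_density
            if cfg.fecal_mass_sd > 0:
                dry += rng.normal(0.0, cfg.fecal_mass_sd)
            fecal_rows.append(
                {
                    "mouse_id": mouse["mouse_id"],
                    "day": d,
                    "fecal_dry_g": max(0.05, dry),
                    "fecal_energy_kcal_per_g": energy_density,
                }
            )
    traces = pd.concat(traces, ignore_index=True)
    traces, fault_log = inject_faults(traces, cfg.faults, seed=int(rng.integers(2**31)))

    assay_rows = []
    for _, mouse in profiles.iterrows():
        group = mouse["group"]
        mass = rng.uniform(0.02, 0.05)
        bead_events = int(rng.poisson(5000))
        dens = cfg.cecal_density_per_g[group]
        if dens > 0:
            d_m = dens * max(0.2, rng.normal(1.0, cfg.cecal_density_cv))
            expected = (
                d_m
                * mass
                / 1000.0  # cells per uL homogenate
                * 2.0
                / 200.0  # cells per uL in the stained mix (2 uL into 200 uL)
                / 4.55e3  # per bead
                * bead_events
            )
            bac_events = int(rng.poisson(expected))
        else:
            d_m = 0.0
            bac_events = int(rng.poisson(cfg.blank_events))
        assay_rows.append(
            {
                "mouse_id": mouse["mouse_id"],
                "group": group,
                "bacterial_events": bac_events,
                "bead_events": bead_events,
                "sample_mass_g": mass,
                "bead_conc_per_ul": 4.55e3,
                "mix_volume_ul": 200.0,
                "sample_volume_ul": 2.0,
                "homogenate_volume_ul": 1000.0,
                "true_density_per_g": d_m,
            }
        )

    met_rows = []
    for _, mouse in profiles.iterrows():
        group = mouse["group"]
        for phase, zt_label in (("light", 5), ("dark", 16)):
            for met, per_group in cfg.metabolites.items():
                mu, sd = per_group[group]
                met_rows.append(
                    {
                        "mouse_id": mouse["mouse_id"],
                        "group": group,
                        "phase": phase,
                        "zt": zt_label,
                        "metabolite": met,
                        "conc_umol_per_g": max(0.0, rng.normal(mu, sd)),
                    }
                )

    truth = {
        "per_mouse": pd.DataFrame(truth_rows),
        "ee_group_effect": dict(cfg.ee_group_effect),
        "absorbed_kcal_day": cfg.absorbed_kcal_day,
    }
    return SyntheticStudy(
        profiles=profiles,
        traces=traces,
        fecal=pd.DataFrame(fecal_rows),
        intake_daily=pd.DataFrame(intake_rows),
        assays=pd.DataFrame(assay_rows),
        metabolites=pd.DataFrame(met_rows),
        truth=truth,
        fault_log=fault_log,
        config=cfg,
    )
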