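"""Synthetic cohorts and lipidome/biomarker datasets.

The generator reproduces the statistical structure the analysis assumes so
that every stage is testable without access to patient data:

* a clinical roster engineered to the study's stratification table
  (92 male patients: 24 CALD / 68 noCALD with 21 over 55, 50 AI / 42 noAI
  with 20 over 55, 17 mild over 55 / 15 severe; 54 stratified women:
  28 mild / 26 severe) plus healthy controls;
* per-class lipid abundances with a chain-length hinge effect,
  log2FC(n, d) = beta * max(0, n - n0) * s(d), damped in the double-bond
  count — VLCFA incorporation raises long-chain species most, saturated
  species more than polyunsaturated ones;
* a female XCI -> LPC(26:0) linear coupling with noise calibrated so the
  population Pearson correlation equals a configured target;
* post-transplant exponential decay C(t) = P + (C0 - P) exp(-k t) with a
  plateau strictly above the healthy upper reference limit (72 nmol/L);
* targeted LPC(26:0) / C26:0 group samples around configured per-stratum
  means with a Gaussian-copula coupling calibrated to a target pooled
  Spearman correlation.

All randomness flows from one seed through deterministically spawned
per-stage generators; regeneration from (config, seed) is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ClassGrid",
    "SimulationConfig",
    "SyntheticDataset",
    "table1_male_roster",
    "table1_female_roster",
    "control_roster",
    "simulate",
    "simulate_features",
    "simulate_xci",
    "simulate_hct",
    "simulate_targeted",
    "study_scale_config",
    "TABLE2_GROUP_MEANS",
    "CONTROL_UPPER_LIMIT_NMOL_L",
]

#: healthy-control upper reference limit for plasma LPC(26:0), nmol/L
CONTROL_UPPER_LIMIT_NMOL_L = 72.0

#: per-stratum (LPC(26:0) nmol/L, C26:0 umol/L) group means used as the
#: targeted-assay simulation defaults
TABLE2_GROUP_MEANS: dict[str, tuple[float, float]] = {
    "CALD": (601.0, 5.0),
    "noCALD_all": (395.0, 4.2),
    "noCALD_gt55": (269.0, 3.5),
    "AI": (536.0, 4.6),
    "noAI_all": (341.0, 4.0),
    "noAI_gt55": (267.0, 3.5),
    "mild_males": (259.0, 3.4),
    "severe_males": (472.0, 4.8),
    "severe_females": (337.0, 4.1),
    "mild_females": (235.0, 3.2),
}


@dataclass(frozen=True)
class ClassGrid:
    """Sum-composition grid and effect rule for one simulated class."""

    class_code: str
    radyl_count: int
    carbons: tuple[int, ...]
    double_bonds: tuple[int, ...]
    hinge_carbons: float  # n0: chain length beyond which the effect grows
    db_damping: float  # d_max: s(d) = max(0, 1 - d / d_max)
    base_log2_mean: float = 6.0
    base_log2_sd: float = 1.0

    def effect_scale(self, n: int, d: int) -> float:
        s = max(0.0, 1.0 - d / self.db_damping) if self.db_damping > 0 else 0.0
        return max(0.0, n - self.hinge_carbons) * s


def _default_classes() -> tuple[ClassGrid, ...]:
    return (
        ClassGrid("LPC", 1, tuple(range(14, 31)), (0, 1, 2), 20.0, 3.0, 5.0),
        ClassGrid("PC", 2, tuple(range(28, 49)), tuple(range(0, 8)), 40.0, 8.0, 7.0),
        ClassGrid("TG", 3, tuple(range(40, 73)), tuple(range(0, 9)), 60.0, 9.0, 8.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic lipidome generator."""

    seed: int = 0
    classes: tuple[ClassGrid, ...] = field(default_factory=_default_classes)
    n_controls: int = 12
    beta: float = 0.15  # log2FC per carbon beyond the hinge, ALD group
    noise_cv: float = 0.2  # multiplicative measurement noise
    ppm_jitter: float = 1.0  # m/z jitter sd for feature-level simulation
    planted_log2fc: Mapping[str, float] | None = None  # per-lipid override
    lipids: tuple[str, ...] | None = None  # explicit subset of the class grids
    # XCI -> LPC(26:0) coupling
    xci_intercept: float = 85.0
    xci_slope: float = 400.0
    xci_target_r: float = 0.79
    # post-HCT decay, solved so the population means run 435 -> 219 -> 190
    hct_baseline_mean: float = 435.0
    hct_baseline_sd: float = 85.0
    hct_plateau: float = 185.5
    hct_decay_rate: float = 0.16729  # per month
    hct_patient_sd: float = 0.15  # lognormal sd of per-patient k and plateau
    hct_noise_cv: float = 0.08
    # targeted assays
    targeted_group_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE2_GROUP_MEANS)
    )
    targeted_log_sd: float = 0.32
    targeted_spearman: float = 0.7

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be > 0")
        if self.hct_plateau <= 0:
            raise ValueError("HCT plateau must be > 0")
        if self.hct_decay_rate <= 0:
            raise ValueError("HCT decay rate must be > 0")


@dataclass
class SyntheticDataset:
    """Simulated cohort with its generating ground truth."""

    metadata: pd.DataFrame
    abundance: pd.DataFrame  # lipid rows x sample columns
    ground_truth: dict
    targeted: pd.DataFrame | None = None


def _sigma_log2(cv: float) -> float:
    # lognormal: CV^2 = exp(sigma_ln^2) - 1
    return float(np.sqrt(np.log1p(cv**2)) / np.log(2))


# ---------------------------------------------------------------------------
# Rosters


def table1_male_roster() -> list[PatientRecord]:
    """92 male patients engineered to the study's stratification counts.

    22 patients are over 55 (of whom 1 CALD, 2 AI, 5 with EDSS > 6) so the
    age-restricted strata come out at noCALD>55 = 21, noAI>55 = 20,
    mild>55 = 17; the under-55 block carries 23 CALD, 48 AI and 10 severe
    for totals CALD 24 / noCALD 68, AI 50 / noAI 42, severe 15.
    """
    records: list[PatientRecord] = []
    idx = 0

    def add(age, cald, ai, edss):
        nonlocal idx
        idx += 1
        records.append(
            PatientRecord(f"M{idx:03d}", "male", float(age), cald, ai, float(edss))
        )

    # over-55 block (ages 56..74, cycled)
    for i in range(22):
        age = 56 + (i % 19)
        cald = i == 0
        ai = i in (0, 1)
        edss = 7.0 if i < 5 else float(i % 7)  # 5 severe, 17 mild
        add(age, cald, ai, edss)
    # under-55 block (ages 6..55, cycled)
    for i in range(70):
        age = 6 + (i * 7) % 50
        cald = i < 23
        ai = i < 48
        edss = 7.5 if i >= 60 else float(i % 6)  # 10 severe
        add(age, cald, ai, edss)
    return records


def table1_female_roster() -> list[PatientRecord]:
    """65 female patients: 54 over 40 (28 mild / 26 severe by EDSS), 11
    younger, one with cerebral ALD."""
    records: list[PatientRecord] = []
    idx = 0

    def add(age, cald, edss):
        nonlocal idx
        idx += 1
        records.append(
            PatientRecord(f"F{idx:03d}", "female", float(age), cald, False, edss)
        )

    for i in range(28):  # mild, over 40
        add(41 + (i * 3) % 38, False, float(i % 7))
    for i in range(26):  # severe, over 40
        add(41 + (i * 5) % 34, i == 0, 6.5 + (i % 4))
    for i in range(11):  # under 40, outside the contrast
        add(18 + 2 * i, False, float(i % 3))
    return records


def control_roster(n: int = 12, sex: str = "male") -> list[PatientRecord]:
    prefix = "CM" if sex == "male" else "CF"
    return [
        PatientRecord(f"{prefix}{i + 1:02d}", sex, 30.0 + 2 * i, False, False, 0.0)
        for i in range(n)
    ]


def _metadata_frame(records: Sequence[PatientRecord], groups: Mapping[str, str]):
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in records],
            "sample_id": [f"S_{p.patient_id}" for p in records],
            "sex": [p.sex for p in records],
            "age": [p.age for p in records],
            "cald": [p.cald for p in records],
            "adrenal_insufficiency": [p.adrenal_insufficiency for p in records],
            "edss": [p.edss for p in records],
            "group": [groups[p.patient_id] for p in records],
        }
    )


# ---------------------------------------------------------------------------
# Lipidome simulation


def _lipid_grid(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for grid in config.classes:
        for n in grid.carbons:
            for d in grid.double_bonds:
                rows.append(
                    {
                        "lipid": f"{grid.class_code}({n}:{d})",
                        "class_code": grid.class_code,
                        "total_carbons": n,
                        "double_bonds": d,
                        "effect_scale": grid.effect_scale(n, d),
                        "base_log2_mean": grid.base_log2_mean,
                        "base_log2_sd": grid.base_log2_sd,
                    }
                )
    frame = pd.DataFrame(rows)
    if frame["lipid"].duplicated().any():
        raise ValueError("duplicate lipids across class grids")
    frame = frame.set_index("lipid")
    if config.lipids is not None:
        unknown = set(config.lipids) - set(frame.index)
        if unknown:
            raise ValueError(
                f"configured lipids absent from the class grids: "
                f"{sorted(unknown)[:5]}"
            )
        frame = frame.loc[list(config.lipids)]
    return frame


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate the male-cohort lipidome dataset with planted effects.

    Patients follow the stratification roster; controls carry no effect.
    Planted per-lipid log2 fold changes (ALD vs control) follow the
    chain-length hinge rule, or ``config.planted_log2fc`` verbatim when
    provided. Ground truth is stored alongside the data.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_base = np.random.default_rng(seeds[0])
    rng_noise = np.random.default_rng(seeds[1])

    grid = _lipid_grid(config)
    planted = config.beta * grid["effect_scale"]
    if config.planted_log2fc is not None:
        unknown = set(config.planted_log2fc) - set(grid.index)
        if unknown:
            raise ValueError(
                f"planted_log2fc names absent from the class grids: "
                f"{sorted(unknown)[:5]}"
            )
        planted = planted * 0.0
        override = pd.Series(dict(config.planted_log2fc), dtype=float)
        planted.loc[override.index] = override

    patients = table1_male_roster()
    controls = control_roster(config.n_controls, "male")
    groups = {p.patient_id: "ALD" for p in patients}
    groups.update({p.patient_id: "control" for p in controls})
    metadata = _metadata_frame(patients + controls, groups)

    base = rng_base.normal(
        grid["base_log2_mean"].to_numpy(), grid["base_log2_sd"].to_numpy()
    )
    is_ald = (metadata["group"] == "ALD").to_numpy(dtype=float)
    sigma = _sigma_log2(config.noise_cv)
    log2_vals = (
        base[:, None]
        + planted.to_numpy()[:, None] * is_ald[None, :]
        + rng_noise.normal(0.0, sigma, size=(len(grid), len(metadata)))
    )
    abundance = pd.DataFrame(
        np.exp2(log2_vals), index=grid.index, columns=metadata["sample_id"].to_numpy()
    )
    truth = {
        "beta": config.beta,
        "noise_cv": config.noise_cv,
        "planted_log2fc": planted.to_dict(),
        "effect_scale": grid["effect_scale"].to_dict(),
        "groups": groups,
    }
    return SyntheticDataset(metadata, abundance, truth)


def simulate_features(
    dataset: SyntheticDataset,
    config: SimulationConfig,
    templates: Mapping | None = None,
):
    """Feature-level view of a simulated dataset: m/z + peak areas.

    Each lipid becomes one LC-MS feature at the theoretical m/z of its
    class's first adduct, jittered by ``ppm_jitter``; peak areas are the
    abundances rescaled by a per-sample instrument response factor, and
    internal-standard areas carry the same factor so semi-quantification
    recovers the A.U. abundances exactly (up to the IS scale).

    Returns (features, is_areas, catalog, is_specs).
    """
    from .annotate import Feature
    from .chem import adduct_mz, build_catalog, default_templates, make_species

    if templates is None:
        templates = default_templates()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    class_codes = sorted({g.class_code for g in config.classes})
    used = []
    for code in class_codes:
        tpl = templates[code]
        cgrid = next(g for g in config.classes if g.class_code == code)
        used.append(
            replace_ranges(tpl, cgrid)
            if hasattr(tpl, "carbon_range")
            else tpl
        )
    catalog = build_catalog(used)
    samples = dataset.abundance.columns
    response = rng.lognormal(0.0, 0.2, size=len(samples))  # instrument drift

    is_specs = {
        code: templates[code].internal_standard
        for code in class_codes
        if templates[code].internal_standard is not None
    }
    is_areas = pd.DataFrame(
        {s: {code: 1e6 * response[j] for code in class_codes}
         for j, s in enumerate(samples)}
    )

    features = []
    for lipid in dataset.abundance.index:
        from .chem import parse_lipid_name

        parsed = parse_lipid_name(lipid)
        tpl = templates[parsed.class_code]
        sp = make_species(tpl, parsed.total_carbons, parsed.total_double_bonds)
        adduct = tpl.adducts[0]
        mz = adduct_mz(sp.mass, adduct)
        mz_obs = mz * (1.0 + rng.normal(0.0, config.ppm_jitter) * 1e-6)
        conc = is_specs[parsed.class_code].concentration
        areas = {
            s: float(dataset.abundance.loc[lipid, s] / conc * 1e6 * response[j])
            for j, s in enumerate(samples)
        }
        features.append(
            Feature(f"feat_{lipid}", mz_obs, adduct.polarity, areas=areas)
        )
    return features, is_areas, catalog, is_specs


def replace_ranges(template, cgrid: ClassGrid):
    """Shrink a class template to a simulation grid's (n, d) extent."""
    from dataclasses import replace as dc_replace

    return dc_replace(
        template,
        carbon_range=(min(cgrid.carbons), max(cgrid.carbons)),
        db_range=(min(cgrid.double_bonds), max(cgrid.double_bonds)),
    )


# ---------------------------------------------------------------------------
# XCI coupling


def simulate_xci(
    config: SimulationConfig, n: int = 28, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """XCI fractions and coupled LPC(26:0) values for ``n`` women.

    XCI fractions (toward the variant allele) are uniform on [0, 1];
    LPC(26:0) = intercept + slope * xci + noise, the noise sd solved so
    the *population* Pearson correlation equals ``xci_target_r``:
    sd = slope * sd(x) * sqrt(1 / r^2 - 1).
    """
    if config.xci_slope <= 0:
        raise ValueError("xci_slope must be > 0")
    if not 0 < config.xci_target_r <= 1:
        raise ValueError("xci_target_r must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = rng.uniform(0.0, 1.0, size=n)
    sd_x = np.sqrt(1.0 / 12.0)  # uniform(0,1)
    r = config.xci_target_r
    noise_sd = config.xci_slope * sd_x * np.sqrt(1.0 / r**2 - 1.0)
    y = config.xci_intercept + config.xci_slope * x + rng.normal(0, noise_sd, n)
    return x, y


# ---------------------------------------------------------------------------
# Post-HCT decay


def simulate_hct(
    config: SimulationConfig,
    n_patients: int = 12,
    timepoints: Sequence[float] = (0.0, 6.0, 12.0, 24.0),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-patient exponential post-transplant LPC(26:0) trajectories.

    C_i(t) = P_i + (C0_i - P_i) exp(-k_i t) with lognormal patient effects
    on the plateau (kept strictly above the healthy upper reference limit)
    and decay rate, and multiplicative measurement noise. Long format:
    patient_id, months_post_hct, value.
    """
    if config.hct_baseline_mean <= config.hct_plateau:
        raise ValueError("baseline mean must exceed the plateau")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    floor = CONTROL_UPPER_LIMIT_NMOL_L
    for i in range(n_patients):
        c0 = max(
            rng.normal(config.hct_baseline_mean, config.hct_baseline_sd),
            config.hct_plateau * 1.2,
        )
        plateau = floor + (config.hct_plateau - floor) * np.exp(
            rng.normal(0.0, config.hct_patient_sd)
        )
        k = config.hct_decay_rate * np.exp(rng.normal(0.0, config.hct_patient_sd))
        for t in timepoints:
            value = plateau + (c0 - plateau) * np.exp(-k * t)
            value *= np.exp(rng.normal(0.0, _sigma_log2(config.hct_noise_cv) * np.log(2)))
            rows.append(
                {
                    "patient_id": f"HCT{i + 1:02d}",
                    "months_post_hct": float(t),
                    "value": float(value),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Targeted assays


def _latent_rho_for_spearman(rho_s: float) -> float:
    # Gaussian copula: spearman = (6 / pi) asin(rho / 2)
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def simulate_targeted(
    config: SimulationConfig, n_per_group: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Per-stratum targeted LPC(26:0) and C26:0 samples.

    Values are lognormal around each stratum's configured mean (the mean
    of a lognormal is matched exactly: mu_ln = ln(mean) - sigma^2 / 2).
    LPC and C26:0 share a Gaussian copula whose latent correlation is
    calibrated so the *pooled* latent correlation maps to the configured
    target Spearman; the between-group component (collinear group means)
    is accounted for analytically before solving for the within-group
    correlation.
    """
    if n_per_group is None:
        n_per_group = {
            "CALD": 24, "noCALD_gt55": 21, "noAI_gt55": 20,
            "mild_males": 17, "severe_males": 15,
            "severe_females": 26, "mild_females": 28,
        }
    means = config.targeted_group_means
    missing = set(n_per_group) - set(means)
    if missing:
        raise ValueError(f"no configured means for groups {sorted(missing)}")
    sigma = config.targeted_log_sd

    # between-group moments of the log-mean pair, weighted by group size
    w = np.array([n_per_group[g] for g in n_per_group], dtype=float)
    w = w / w.sum()
    mu1 = np.log([means[g][0] for g in n_per_group])
    mu2 = np.log([means[g][1] for g in n_per_group])
    b11 = float(np.sum(w * mu1**2) - np.sum(w * mu1) ** 2)
    b22 = float(np.sum(w * mu2**2) - np.sum(w * mu2) ** 2)
    b12 = float(np.sum(w * mu1 * mu2) - np.sum(w * mu1) * np.sum(w * mu2))
    target = _latent_rho_for_spearman(config.targeted_spearman)
    num = target * np.sqrt((sigma**2 + b11) * (sigma**2 + b22)) - b12
    rho_within = float(np.clip(num / sigma**2, -0.99, 0.99))

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    cov = np.array([[1.0, rho_within], [rho_within, 1.0]]) * sigma**2
    rows = []
    for group, n in n_per_group.items():
        lpc_mean, c26_mean = means[group]
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        lpc = np.exp(np.log(lpc_mean) - sigma**2 / 2 + z[:, 0])
        c26 = np.exp(np.log(c26_mean) - sigma**2 / 2 + z[:, 1])
        for i in range(n):
            rows.append(
                {
                    "group": group,
                    "patient": f"{group}_{i + 1:02d}",
                    "lpc26_nmol_l": float(lpc[i]),
                    "c26_umol_l": float(c26[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Study-scale configuration


def study_scale_config(
    seed: int = 0,
    n_total: int = 1556,
    n_elevated: int = 421,
    n_lower: int = 45,
    noise_cv: float = 0.2,
) -> SimulationConfig:
    """Male-study-sized configuration with planted volcano truth.

    Builds class grids totaling ``n_total`` lipids and plants per-lipid
    log2 fold changes so that exactly ``n_elevated`` lipids (the highest
    chain-length hinge scores, log2FC >= 0.9) are elevated, ``n_lower``
    short polyunsaturated TG are lowered (log2FC = -1.2), and the rest are
    null — the printed study summary used as generator input.
    """
    classes = (
        ClassGrid("LPC", 1, tuple(range(14, 31)), (0, 1, 2), 20.0, 3.0, 5.0),
        ClassGrid("CE", 1, tuple(range(14, 31)), (0, 1, 2), 20.0, 3.0, 7.0),
        ClassGrid("LPE", 1, tuple(range(14, 31)), (0, 1, 2), 20.0, 3.0, 4.0),
        ClassGrid("SM", 2, tuple(range(28, 45)), (1, 2, 3, 4), 40.0, 5.0, 6.0),
        ClassGrid("Cer", 2, tuple(range(28, 45)), (1, 2, 3, 4), 40.0, 5.0, 4.0),
        ClassGrid("PC", 2, tuple(range(28, 49)), tuple(range(0, 8)), 40.0, 8.0, 7.0),
        ClassGrid("PE", 2, tuple(range(28, 49)), tuple(range(0, 8)), 40.0, 8.0, 6.0),
        ClassGrid("PI", 2, tuple(range(28, 49)), tuple(range(0, 8)), 40.0, 8.0, 5.5),
        ClassGrid("PS", 2, tuple(range(28, 49)), tuple(range(0, 8)), 40.0, 8.0, 5.0),
        ClassGrid("PG", 2, tuple(range(28, 49)), tuple(range(0, 8)), 40.0, 8.0, 4.5),
        ClassGrid("DG", 2, tuple(range(24, 45)), tuple(range(0, 7)), 40.0, 7.0, 5.5),
        ClassGrid("TG", 3, tuple(range(40, 73)), tuple(range(0, 9)), 60.0, 9.0, 8.0),
    )
    base = SimulationConfig(seed=seed, classes=classes, noise_cv=noise_cv)
    grid = _lipid_grid(base)
    if len(grid) < n_total:
        raise ValueError(f"grids give only {len(grid)} lipids < {n_total}")
    # deterministic trim to exactly n_total: drop the highest-d TG first
    grid = grid.sort_values(
        ["class_code", "double_bonds", "total_carbons"], kind="mergesort"
    )
    keep = grid.index[: len(grid)]
    if len(grid) > n_total:
        tg = grid[grid["class_code"] == "TG"].sort_values(
            ["double_bonds", "total_carbons"], ascending=[False, False],
            kind="mergesort",
        )
        drop = set(tg.index[: len(grid) - n_total])
        keep = [name for name in grid.index if name not in drop]
    grid = grid.loc[keep]

    scores = grid["effect_scale"].sort_values(ascending=False, kind="mergesort")
    elevated = list(scores.index[:n_elevated])
    cut = float(scores.iloc[n_elevated - 1])
    top = float(scores.iloc[0])
    span = max(top - cut, 1e-9)
    planted = {}
    for name in elevated:
        planted[name] = 0.9 + 3.1 * (float(scores[name]) - cut) / span
    # short polyunsaturated TG are lowered
    tg_low = grid[
        (grid["class_code"] == "TG")
        & (grid["double_bonds"] >= 4)
        & (grid["total_carbons"] <= 54)
        & (grid["effect_scale"] < cut)
    ].sort_values(["total_carbons", "double_bonds"], kind="mergesort")
    if len(tg_low) < n_lower:
        raise ValueError("not enough short polyunsaturated TG for the lower set")
    for name in tg_low.index[:n_lower]:
        planted[name] = -1.2

    return replace(
        base, lipids=tuple(grid.index), planted_log2fc=planted
    )
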