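"""Synthetic multisite lifespan morphometry cohorts with known ground truth.

Real normative-modelling studies pool tens of thousands of scans from dozens
of sites spanning ages 3-90.  This module emulates the statistical structure
of such cohorts so every downstream component can be exercised against a
known generative truth:

* sex-specific nonlinear age trajectories for each regional measure, built
  from the same fractional-polynomial family the fitting machinery searches;
* global measures (ICV, mean cortical thickness, total surface area) with
  their own age trajectories, so regional-global coupling is confounded
  with age as in real data;
* linear coupling of each regional measure to its paired global measure;
* additive per-site offsets (sum-to-zero across sites) and multiplicative
  site scale jitter;
* heteroscedastic region-specific noise, log-uniform across measures over at
  least one decade;
* Euler numbers with a mild age dependence (worse surface quality in the
  young), rare outliers displaced by 4-8 IQRs, longitudinal follow-ups that
  track each subject's own centile, and case-control cohorts with symptom
  scores.

Ages are drawn from a piecewise-uniform mixture with a child/adolescent bump
and an adult plateau, mimicking the uneven age coverage of lifespan
consortia.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fracpoly import FP_POWERS, FPSpec, fp_basis
from .registry_io import (
    CORE_COLUMNS,
    GLOBAL_FOR_METRIC,
    MeasureSpec,
    MorphometryTable,
    build_measure_registry,
)

#: Typical scale (baseline level, units) per measure family.
_FAMILY_LEVEL = {"thickness": 2.6, "area": 1600.0, "subcortical_volume": 4000.0}
#: Amplitude of the age effect relative to the baseline level.
_FAMILY_AGE_AMP = {"thickness": 0.35, "area": 0.25, "subcortical_volume": 0.30}

#: Global-measure generative settings: level, age amplitude, noise SD.
_GLOBAL_LEVEL = {"icv": 1.45e6, "mean_ct": 2.55, "total_sa": 1.75e5}
_GLOBAL_AGE_AMP = {"icv": 0.12, "mean_ct": 0.30, "total_sa": 0.18}
_GLOBAL_NOISE = {"icv": 9e4, "mean_ct": 0.07, "total_sa": 9e3}


@dataclass(frozen=True)
class MeasureTruth:
    """Ground-truth generative parameters for one measure and sex."""

    spec: FPSpec          # age trajectory shape
    age_coefs: tuple[float, ...]
    intercept: float
    coupling: float       # slope on the (age-detrended) global covariate
    noise_sd: float


@dataclass
class GroundTruth:
    """Everything needed to reconstruct noiseless trajectories in tests."""

    measures: dict[str, dict[str, MeasureTruth]]  # name -> sex -> params
    site_offsets: dict[str, dict[str, float]]     # name -> site -> offset
    site_scales: dict[str, float]                 # site -> multiplicative jitter
    global_truth: dict[str, dict[str, MeasureTruth]]

    def trajectory(self, name: str, sex: str, age: np.ndarray) -> np.ndarray:
        """Noise-free regional trajectory at mean global covariate / site 0."""
        t = self.measures[name][sex]
        basis = fp_basis(np.asarray(age, dtype=float), t.spec)
        return t.intercept + basis @ np.asarray(t.age_coefs)


@dataclass
class SyntheticConfig:
    """Generative settings for a lifespan cohort.

    Defaults describe a mid-sized multisite sample: 1000 subjects per sex
    across 8 sites with moderate site offsets, coupling to the paired global
    measure, region noise SDs spanning one decade (log-uniform), a 1%
    extreme-outlier rate, and a child/adolescent enrolment bump (45% of
    subjects aged 3-25).
    """

    n_per_sex: int = 1000
    age_range: tuple[float, float] = (3.0, 90.0)
    site_count: int = 8
    site_offset_sd: float = 0.05   # fraction of family level
    site_scale_sd: float = 0.02
    measures: Sequence[str] | None = None  # default: full 150-measure registry
    global_coupling: float = 0.2   # regional units per global-SD
    noise_sd_range: tuple[float, float] = (0.01, 0.1)  # fraction of level
    outlier_rate: float = 0.01
    young_fraction: float = 0.45   # mass of the age bump on [3, 25]
    trait_fraction: float = 0.8    # share of noise variance stable in a subject
    #: optional per-measure ground-truth overrides applied to both sexes:
    #: {measure: {"powers": (..), "coefs": (..), "intercept": f,
    #:            "coupling": f, "noise_sd": f, "scale": f}}
    trajectory_overrides: Mapping[str, Mapping] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_rate <= 0.05:
            raise ValueError("outlier_rate must be in [0, 0.05]")
        lo, hi = self.noise_sd_range
        if not 0 < lo <= hi:
            raise ValueError("noise_sd_range must be positive and ordered")
        if not 0 <= self.trait_fraction <= 1:
            raise ValueError("trait_fraction must be in [0, 1]")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        doc = json.loads(Path(path).read_text())
        for key in ("age_range", "noise_sd_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def _sample_ages(rng, n, age_range, young_fraction):
    lo, hi = age_range
    bump_hi = min(25.0, hi)
    n_young = rng.binomial(n, young_fraction)
    young = rng.uniform(lo, bump_hi, size=n_young)
    adult = rng.uniform(lo, hi, size=n - n_young)
    # shuffle so row order carries no age information
    return rng.permutation(np.concatenate([young, adult]))


def _draw_truth(rng, spec: MeasureSpec, cfg: SyntheticConfig) -> MeasureTruth:
    level = _FAMILY_LEVEL[spec.metric]
    amp = _FAMILY_AGE_AMP[spec.metric] * level
    # one or two FP powers from the canonical set; shift 0 works (age >= 3)
    degree = int(rng.integers(1, 3))
    powers = tuple(sorted(rng.choice(FP_POWERS, size=degree, replace=False)))
    fpspec = FPSpec(powers=powers, shift=0.0, scale=10.0)
    # normalise coefficients so the age effect spans ~amp over the age range
    ages = np.linspace(3.0, 90.0, 200)
    basis = fp_basis(ages, fpspec)
    raw = rng.normal(size=degree)
    curve = basis @ raw
    span = float(np.ptp(curve)) or 1.0
    coefs = tuple(raw * amp / span)
    noise_frac = np.exp(
        rng.uniform(np.log(cfg.noise_sd_range[0]), np.log(cfg.noise_sd_range[1]))
    )
    return MeasureTruth(
        spec=fpspec,
        age_coefs=coefs,
        intercept=level,
        coupling=cfg.global_coupling * level * 0.05,  # per global-SD
        noise_sd=float(noise_frac * level),
    )


def _draw_global_truth(rng, name: str) -> MeasureTruth:
    level = _GLOBAL_LEVEL[name]
    amp = _GLOBAL_AGE_AMP[name] * level
    powers = tuple(sorted(rng.choice(FP_POWERS, size=2, replace=False)))
    fpspec = FPSpec(powers=powers, shift=0.0, scale=10.0)
    ages = np.linspace(3.0, 90.0, 200)
    basis = fp_basis(ages, fpspec)
    raw = rng.normal(size=2)
    curve = basis @ raw
    span = float(np.ptp(curve)) or 1.0
    coefs = tuple(raw * amp / span)
    return MeasureTruth(
        spec=fpspec,
        age_coefs=coefs,
        intercept=level,
        coupling=0.0,
        noise_sd=_GLOBAL_NOISE[name],
    )


def _eval_truth(t: MeasureTruth, age: np.ndarray) -> np.ndarray:
    return t.intercept + fp_basis(age, t.spec) @ np.asarray(t.age_coefs)


def generate_cohort(config: SyntheticConfig) -> tuple[MorphometryTable, GroundTruth]:
    """Generate a sex-balanced multisite cohort and its generative truth.

    Each regional value is
    ``intercept + FP(age) + coupling * (global - E[global|age])/SD
    + site offset + subject trait + scan noise``,
    with trait and scan noise splitting the configured noise variance by
    ``trait_fraction`` (the trait persists at follow-up, which is what makes
    subjects track their own centile).
    """
    cfg = config
    if cfg.n_per_sex < 2 * cfg.site_count:
        raise ValueError(
            f"n_per_sex={cfg.n_per_sex} cannot fill {cfg.site_count} sites "
            "with at least 2 subjects each"
        )
    rng = np.random.default_rng(cfg.seed)
    registry = {m.name: m for m in build_measure_registry()}
    names = list(cfg.measures) if cfg.measures is not None else list(registry)
    unknown = [n for n in names if n not in registry]
    if unknown:
        raise ValueError(f"measures not in registry: {unknown[:5]}")

    # generative parameters (one RNG stream, fully determined by the seed)
    global_truth = {
        "F": {g: _draw_global_truth(rng, g) for g in ("icv", "mean_ct", "total_sa")},
        "M": {g: _draw_global_truth(rng, g) for g in ("icv", "mean_ct", "total_sa")},
    }
    measures: dict[str, dict[str, MeasureTruth]] = {}
    for name in names:
        measures[name] = {
            "F": _draw_truth(rng, registry[name], cfg),
            "M": _draw_truth(rng, registry[name], cfg),
        }
    for name, ov in (cfg.trajectory_overrides or {}).items():
        if name not in measures:
            raise ValueError(f"override for unknown measure {name!r}")
        for sex in ("F", "M"):
            base = measures[name][sex]
            spec = (
                FPSpec(tuple(ov["powers"]), 0.0, float(ov.get("scale", 10.0)))
                if "powers" in ov
                else base.spec
            )
            measures[name][sex] = MeasureTruth(
                spec=spec,
                age_coefs=tuple(ov.get("coefs", base.age_coefs)),
                intercept=float(ov.get("intercept", base.intercept)),
                coupling=float(ov.get("coupling", base.coupling)),
                noise_sd=float(ov.get("noise_sd", base.noise_sd)),
            )
    sites = [f"site{i:02d}" for i in range(cfg.site_count)]
    site_offsets: dict[str, dict[str, float]] = {}
    for name in names:
        level = _FAMILY_LEVEL[registry[name].metric]
        raw = rng.normal(0.0, cfg.site_offset_sd * level, size=cfg.site_count)
        raw -= raw.mean()  # sum-to-zero across sites
        site_offsets[name] = dict(zip(sites, raw))
    scale_raw = rng.normal(0.0, cfg.site_scale_sd, size=cfg.site_count)
    scale_raw -= scale_raw.mean()
    site_scales = {s: float(1.0 + v) for s, v in zip(sites, scale_raw)}
    truth = GroundTruth(measures, site_offsets, site_scales, global_truth)

    frames = []
    vendors = ("Siemens", "GE", "Philips")
    fs_versions = ("6.0", "7.1")
    for sex in ("F", "M"):
        n = cfg.n_per_sex
        age = _sample_ages(rng, n, cfg.age_range, cfg.young_fraction)
        site = np.array(sites)[rng.integers(0, cfg.site_count, size=n)]
        vendor = np.array(vendors)[rng.integers(0, len(vendors), size=n)]
        fs = np.array(fs_versions)[rng.integers(0, len(fs_versions), size=n)]
        # Euler number: topological defect count proxy, worse (more negative)
        # at young ages due to motion
        euler = -(
            rng.poisson(30 + 60 * np.exp(-(age - 3.0) / 8.0)).astype(float)
        )
        df = pd.DataFrame(
            {
                "subject_id": [f"{sex}{i:06d}" for i in range(n)],
                "sex": sex,
                "age": age,
                "site": site,
                "vendor": vendor,
                "fs_version": fs,
                "euler": euler,
            }
        )
        gvals = {}
        for g in ("icv", "mean_ct", "total_sa"):
            gt = global_truth[sex][g]
            gvals[g] = _eval_truth(gt, age) + rng.normal(0, gt.noise_sd, size=n)
            df[g] = gvals[g]
        for name in names:
            t = measures[name][sex]
            gcol = registry[name].global_covariate
            gt = global_truth[sex][gcol]
            g_resid_sd = gt.noise_sd
            g_std = (gvals[gcol] - _eval_truth(gt, age)) / g_resid_sd
            base = (
                _eval_truth(t, age)
                + t.coupling * g_std
                + np.array([site_offsets[name][s] for s in site])
            )
            base *= np.array([site_scales[s] for s in site])
            trait = rng.normal(0, t.noise_sd * np.sqrt(cfg.trait_fraction), size=n)
            scan = rng.normal(
                0, t.noise_sd * np.sqrt(1.0 - cfg.trait_fraction), size=n
            )
            vals = base + trait + scan
            if cfg.outlier_rate > 0:
                hit = rng.random(n) < cfg.outlier_rate
                if hit.any():
                    q1, q3 = np.quantile(vals, [0.25, 0.75])
                    iqr = max(q3 - q1, t.noise_sd)
                    bump = rng.uniform(4.0, 8.0, size=int(hit.sum())) * iqr
                    sign = rng.choice([-1.0, 1.0], size=int(hit.sum()))
                    # morphometry is physically positive: floor the injected
                    # outliers well below the normal range instead of
                    # letting them go negative
                    vals[hit] = np.maximum(
                        vals[hit] + sign * bump, 0.05 * t.intercept
                    )
            df[name] = vals
            df[f"__trait__{name}"] = trait  # stashed for follow-up generation
        frames.append(df)

    full = pd.concat(frames, ignore_index=True)
    trait_cols = [c for c in full.columns if c.startswith("__trait__")]
    traits = full[trait_cols].copy()
    table = MorphometryTable(full.drop(columns=trait_cols))
    # keep traits on the truth object rather than in the public table
    truth.measures = measures
    truth._traits = traits  # type: ignore[attr-defined]
    truth._config = cfg  # type: ignore[attr-defined]
    return table, truth


def generate_followup(
    cohort: MorphometryTable,
    truth: GroundTruth,
    mean_interval: float = 2.35,
    interval_sd: float = 0.3,
    seed: int = 1,
) -> MorphometryTable:
    """Rescan the same subjects after a per-subject interval.

    Ages advance by draws from N(mean_interval, interval_sd) truncated below
    at 0.5 years (non-positive draws are resampled); each subject moves along
    their own trajectory, keeping their stable trait component and receiving
    fresh scan noise.  ``mean_interval=0, interval_sd=0`` leaves ages
    unchanged (a strict re-scan).

    Presets from longitudinal rescan studies: a "SLIM-like" design uses a
    mean interval of 2.35 years, a "QTAB-like" design 1.76 years.
    """
    cfg: SyntheticConfig = truth._config  # type: ignore[attr-defined]
    traits: pd.DataFrame = truth._traits  # type: ignore[attr-defined]
    rng = np.random.default_rng(seed)
    df = cohort.df.copy()
    n = len(df)
    if mean_interval == 0 and interval_sd == 0:
        interval = np.zeros(n)
    else:
        interval = rng.normal(mean_interval, interval_sd, size=n)
        for _ in range(100):
            bad = interval <= 0
            if not bad.any():
                break
            interval[bad] = rng.normal(mean_interval, interval_sd, size=int(bad.sum()))
        interval = np.maximum(interval, 0.5)
    age2 = df["age"].to_numpy() + interval
    registry = {m.name: m for m in build_measure_registry()}

    out = df.copy()
    out["age"] = age2
    for sex in ("F", "M"):
        mask = (df["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        a2 = age2[mask]
        site = df.loc[mask, "site"].to_numpy()
        gvals = {}
        for g in ("icv", "mean_ct", "total_sa"):
            gt = truth.global_truth[sex][g]
            gvals[g] = _eval_truth(gt, a2) + rng.normal(0, gt.noise_sd, size=mask.sum())
            out.loc[mask, g] = gvals[g]
        for name in truth.measures:
            t = truth.measures[name][sex]
            gcol = registry[name].global_covariate
            gt = truth.global_truth[sex][gcol]
            g_std = (gvals[gcol] - _eval_truth(gt, a2)) / gt.noise_sd
            base = (
                _eval_truth(t, a2)
                + t.coupling * g_std
                + np.array([truth.site_offsets[name][s] for s in site])
            )
            base *= np.array([truth.site_scales[s] for s in site])
            trait = traits.loc[mask, f"__trait__{name}"].to_numpy()
            scan = rng.normal(
                0, t.noise_sd * np.sqrt(1.0 - cfg.trait_fraction), size=int(mask.sum())
            )
            out.loc[mask, name] = base + trait + scan
    return MorphometryTable(out)


@dataclass
class CaseControlResult:
    """Labels, symptom scores, and the true per-measure shifts."""

    labels: np.ndarray          # 1 = case, 0 = control (aligned to cohort rows)
    symptom_scores: np.ndarray  # NaN for controls
    true_shifts: dict[str, float]
    table: MorphometryTable     # cohort with case shifts applied


def generate_case_control(
    cohort: MorphometryTable,
    truth: GroundTruth,
    affected_measures: Sequence[str],
    effect_size: float = 0.8,
    case_fraction: float = 0.4,
    symptom_noise_sd: float = 1.0,
    seed: int = 2,
) -> CaseControlResult:
    """Turn a healthy cohort into a case-control sample with symptom scores.

    Cases have each affected measure shifted by ``effect_size`` times that
    measure's noise SD (sign drawn once per measure); the symptom score is a
    linear function of a case's true standardised shifts plus Gaussian
    noise.  ``effect_size=0`` leaves cases exchangeable with controls.
    """
    if cohort.n_subjects == 0:
        raise ValueError("empty cohort")
    missing = [m for m in affected_measures if m not in truth.measures]
    if missing:
        raise ValueError(f"affected measures not in cohort truth: {missing}")
    rng = np.random.default_rng(seed)
    n = cohort.n_subjects
    labels = (rng.random(n) < case_fraction).astype(int)
    df = cohort.df.copy()
    shifts: dict[str, float] = {}
    signal = np.zeros(n)
    for name in affected_measures:
        sign = float(rng.choice([-1.0, 1.0]))
        for sex in ("F", "M"):
            mask = ((df["sex"] == sex) & (labels == 1)).to_numpy()
            delta = sign * effect_size * truth.measures[name][sex].noise_sd
            df.loc[mask, name] = df.loc[mask, name] + delta
        shifts[name] = sign * effect_size
        signal += np.where(labels == 1, sign * effect_size, 0.0)
    scores = np.full(n, np.nan)
    cases = labels == 1
    scores[cases] = signal[cases] + rng.normal(0, symptom_noise_sd, size=int(cases.sum()))
    return CaseControlResult(
        labels=labels,
        symptom_scores=scores,
        true_shifts=shifts,
        table=MorphometryTable(df),
    )
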