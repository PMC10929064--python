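"""Robustness of the optimised models to sample size and age composition.

Two analyses:

* sample-size curves — the optimised model is refitted by 5-fold CV in
  random subsets of increasing size (200 to 15000 in steps of 200 by
  default, i.e. 75 sizes) and the MAE/RMSE recorded per size, together with
  an operational plateau estimate: the smallest size from which the mean MAE
  stays within a 1% band around the asymptote (mean of the three largest
  sizes);
* age-bin analysis — the study sample is divided into nine age bins
  ((3,10], (10,20], ..., (80,90]); each optimised model's MAE/RMSE is
  re-estimated by 5-fold CV inside every bin, and the per-bin vector of
  region-wise errors is correlated (Pearson) with the full-sample vector.
  High correlations mean the region-to-region error structure — dominated by
  region-specific noise scale — is preserved in every age group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .data_prep import apply_centring, extreme_mask, make_age_bins
from .evaluation import crossval, metrics
from .fracpoly import fit_fp_fixed
from .registry_io import MorphometryTable, PretrainedBundle

__all__ = [
    "SensitivityReport",
    "sample_size_grid",
    "sample_size_curve",
    "age_bin_analysis",
]


@dataclass
class SensitivityReport:
    """Container for either robustness analysis (unused sections are None)."""

    sizes: np.ndarray | None = None
    per_size: pd.DataFrame | None = None       # size x measure -> mae, rmse
    plateau_estimate: int | None = None
    per_bin: pd.DataFrame | None = None        # sex, bin, measure -> mae, rmse
    full_sample: pd.DataFrame | None = None    # sex, measure -> mae, rmse
    bin_full_r: pd.DataFrame | None = None     # sex, bin, metric -> pearson r
    ks_normality: pd.DataFrame | None = None   # descriptive KS check
    seed: int = 0


def sample_size_grid(
    min_n: int = 200, max_n: int = 15_000, step: int = 200
) -> np.ndarray:
    """Arithmetic grid of subset sizes, inclusive of both ends when aligned."""
    if step <= 0 or min_n > max_n:
        raise ValueError("need step > 0 and min_n <= max_n")
    return np.arange(min_n, max_n + 1, step)


def sample_size_curve(
    data: MorphometryTable | pd.DataFrame,
    sizes,
    measures,
    algorithm: str = "mfpr",
    covariate_set=("age", "global_linear"),
    k: int = 5,
    seed: int = 0,
    plateau_band: float = 0.01,
) -> SensitivityReport:
    """MAE/RMSE of the optimised model across random subsets of given sizes.

    Subsets are drawn without replacement with a seeded generator; sizes
    exceeding the available sample are skipped with a warning.  The plateau
    estimate is the smallest size from which the measure-averaged MAE never
    leaves the ``plateau_band`` relative band around the asymptote.
    """
    df = data.df if isinstance(data, MorphometryTable) else data
    if isinstance(measures, str):
        measures = [measures]
    sizes = np.asarray(sizes, dtype=int)
    if not np.all(np.diff(sizes) > 0):
        raise ValueError("sizes must be strictly increasing")
    rng = np.random.default_rng(seed)
    n = len(df)
    rows = []
    used_sizes = []
    for size in sizes:
        if size > n:
            warnings.warn(f"subset size {size} > available n={n}; skipped",
                          stacklevel=2)
            continue
        idx = rng.choice(n, size=size, replace=False)
        sub = df.iloc[idx].reset_index(drop=True)
        for m in measures:
            cv = crossval(algorithm, sub, m, covariate_set, k=k, seed=seed)
            rows.append((int(size), m, cv.mean.mae, cv.mean.rmse))
        used_sizes.append(int(size))
    per_size = pd.DataFrame(rows, columns=["size", "measure", "mae", "rmse"])

    plateau = None
    if len(used_sizes) >= 3:
        curve = per_size.groupby("size")["mae"].mean()
        asymptote = float(curve.iloc[-3:].mean())
        lo, hi = asymptote * (1 - plateau_band), asymptote * (1 + plateau_band)
        inside = (curve >= lo) & (curve <= hi)
        plateau = None
        for i in range(len(curve)):
            if inside.iloc[i:].all():
                plateau = int(curve.index[i])
                break
    return SensitivityReport(
        sizes=np.asarray(used_sizes), per_size=per_size,
        plateau_estimate=plateau, seed=seed,
    )


def _fixed_form_cv(y, data_cols, terms, k, seed):
    """5-fold CV of a model whose functional forms are frozen."""
    n = len(y)
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    maes, rmses = [], []
    for tr, te in folds.split(np.arange(n)):
        data_tr = {name: v[tr] for name, v in data_cols.items()}
        data_te = {name: v[te] for name, v in data_cols.items()}
        model = fit_fp_fixed(y[tr], terms, data_tr)
        m = metrics(y[te], model.predict(data_te))
        maes.append(m.mae)
        rmses.append(m.rmse)
    return float(np.mean(maes)), float(np.mean(rmses))


def age_bin_analysis(
    data: MorphometryTable | pd.DataFrame,
    bundles: list[PretrainedBundle],
    k: int = 5,
    seed: int = 0,
    min_bin_n: int = 50,
) -> SensitivityReport:
    """Per-age-bin accuracy of pretrained models vs the full sample.

    For each bundle (sex x measure) the bundle's selected functional form is
    re-estimated by ``k``-fold CV inside each of the nine age bins and in the
    full sex-specific sample; bins with fewer than ``min_bin_n`` usable
    subjects are excluded with a warning.  Pearson correlations between the
    per-bin and full-sample region-wise metric vectors are reported per sex
    and metric, plus a descriptive KS normality check on the standardised
    paired differences.
    """
    df = data.df if isinstance(data, MorphometryTable) else data
    bin_rows, full_rows = [], []
    for bundle in bundles:
        name = bundle.measure.name
        gcol = bundle.measure.global_covariate
        sub = df.loc[(df["sex"] == bundle.sex) & df[name].notna()]
        if sub.empty:
            warnings.warn(f"no data for bundle {name}/{bundle.sex}", stacklevel=2)
            continue
        if len(sub) >= 4:  # preparation stage: drop per-measure extreme values
            sub = sub.loc[extreme_mask(sub[name].to_numpy(float))]
        centred = apply_centring(sub, bundle.centring_constants)
        y = sub[name].to_numpy(float)
        data_cols = {
            "age": centred["age"].to_numpy(float),
            gcol: centred[gcol].to_numpy(float),
        }
        terms = bundle.model.terms
        mae, rmse = _fixed_form_cv(y, data_cols, terms, k, seed)
        full_rows.append((bundle.sex, name, mae, rmse))
        bins = np.asarray(make_age_bins(sub["age"].to_numpy()).astype(str))
        for b in sorted(set(bins)):
            if b == "out_of_range":
                continue
            sel = bins == b
            if int(sel.sum()) < min_bin_n:
                warnings.warn(
                    f"age bin {b} for {name}/{bundle.sex} has n={int(sel.sum())} "
                    f"< {min_bin_n}; excluded",
                    stacklevel=2,
                )
                continue
            cols_b = {k_: v[sel] for k_, v in data_cols.items()}
            mae_b, rmse_b = _fixed_form_cv(y[sel], cols_b, terms, k, seed)
            bin_rows.append((bundle.sex, b, name, mae_b, rmse_b))

    per_bin = pd.DataFrame(bin_rows, columns=["sex", "bin", "measure",
                                              "mae", "rmse"])
    full = pd.DataFrame(full_rows, columns=["sex", "measure", "mae", "rmse"])

    r_rows, ks_rows = [], []
    for (sex, b), grp in per_bin.groupby(["sex", "bin"]):
        ref = full.loc[full["sex"] == sex].set_index("measure")
        grp = grp.set_index("measure")
        common = grp.index.intersection(ref.index)
        if len(common) < 3:
            continue
        for metric in ("mae", "rmse"):
            x = grp.loc[common, metric].to_numpy()
            yv = ref.loc[common, metric].to_numpy()
            r = float(np.corrcoef(x, yv)[0, 1])
            r_rows.append((sex, b, metric, r, len(common)))
            diff = x - yv
            sd = diff.std()
            if sd > 0:
                ks = stats.kstest((diff - diff.mean()) / sd, "norm")
                ks_rows.append((sex, b, metric, float(ks.statistic),
                                float(ks.pvalue)))
    bin_full_r = pd.DataFrame(
        r_rows, columns=["sex", "bin", "metric", "pearson_r", "n_measures"]
    )
    ks_tab = pd.DataFrame(
        ks_rows, columns=["sex", "bin", "metric", "ks_stat", "ks_p"]
    )
    return SensitivityReport(
        per_bin=per_bin, full_sample=full, bin_full_r=bin_full_r,
        ks_normality=ks_tab, seed=seed,
    )
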