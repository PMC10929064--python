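"""Cross-validated benchmarking: 5-fold CV, accuracy metrics, covariate
search, and FDR-corrected pairwise algorithm comparison.

Model accuracy is summarised by the mean absolute error (MAE, the primary
metric), the root mean square error (RMSE) and the explained variance
(EV = 1 - var(residual)/var(observed)), each computed on held-out folds and
averaged; per-fold CPU time is recorded for the efficiency comparison but
never drives a selection decision.  Algorithms are compared across regional
measures by concatenating their per-measure metric vectors and applying
paired two-sided Wilcoxon signed-rank tests with Benjamini-Hochberg
correction at q = 0.05.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from . import baseline_models as bm
from .fracpoly import Covariate, fit_mfp
from .registry_io import MeasureSpec, MorphometryTable, build_measure_registry

__all__ = [
    "FitMetrics",
    "CVResult",
    "ComparisonReport",
    "COVARIATE_COMBINATIONS",
    "metrics",
    "crossval",
    "covariate_search",
    "compare_algorithms",
    "build_design",
    "build_covariates",
]

#: The nine candidate covariate combinations evaluated during optimisation.
#: ``global_linear``/``global_fp`` denote the measure's paired global
#: covariate entering linearly or FP-eligibly; ``vendor`` and ``fs`` enter
#: as one-hot terms, ``euler`` as a continuous quality covariate.
COVARIATE_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("age",),
    ("age", "vendor"),
    ("age", "fs"),
    ("age", "euler"),
    ("age", "vendor", "fs", "euler"),
    ("age", "global_linear"),
    ("age", "global_fp"),
    ("age", "global_linear", "vendor", "fs", "euler"),
    ("age", "global_fp", "vendor", "fs", "euler"),
)

_REGISTRY = {m.name: m for m in build_measure_registry()}


@dataclass
class FitMetrics:
    mae: float
    rmse: float
    ev: float
    cpu_time: float = 0.0


@dataclass
class CVResult:
    per_fold: list[FitMetrics]
    mean: FitMetrics
    k: int
    seed: int


@dataclass
class ComparisonReport:
    """Pairwise algorithm comparison with BH-FDR adjusted significance."""

    table: pd.DataFrame  # metric, alg_a, alg_b, statistic, p, p_fdr, significant
    q: float = 0.05


def metrics(y_obs, y_pred) -> FitMetrics:
    """MAE, RMSE and explained variance of predictions against observations."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size == 0:
        raise ValueError("y_obs and y_pred must be non-empty and equal length")
    e = y_obs - y_pred
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    var_obs = float(np.var(y_obs))
    if var_obs == 0:
        warnings.warn("zero-variance observations: EV undefined", stacklevel=2)
        ev = float("nan")
    else:
        ev = 1.0 - float(np.var(e)) / var_obs
    return FitMetrics(mae=mae, rmse=rmse, ev=ev)


# ---------------------------------------------------------------------------
# design construction


def _measure_spec(measure: str | MeasureSpec) -> MeasureSpec:
    if isinstance(measure, MeasureSpec):
        return measure
    try:
        return _REGISTRY[measure]
    except KeyError:
        raise KeyError(f"measure {measure!r} not in registry") from None


def _dummies(df: pd.DataFrame, col: str, prefix: str) -> pd.DataFrame:
    return pd.get_dummies(df[col], prefix=prefix, drop_first=True, dtype=float)


def build_design(
    df: pd.DataFrame, measure: str | MeasureSpec, tokens: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix (no intercept column) for the linear/GP models."""
    spec = _measure_spec(measure)
    cols: list[pd.Series | pd.DataFrame] = []
    names: list[str] = []
    for tok in tokens:
        if tok == "age":
            cols.append(df["age"].astype(float))
            names.append("age")
        elif tok in ("global_linear", "global_fp"):
            cols.append(df[spec.global_covariate].astype(float))
            names.append(spec.global_covariate)
        elif tok == "euler":
            cols.append(df["euler"].astype(float))
            names.append("euler")
        elif tok == "vendor":
            d = _dummies(df, "vendor", "vendor")
            cols.append(d)
            names.extend(d.columns)
        elif tok == "fs":
            d = _dummies(df, "fs_version", "fs")
            cols.append(d)
            names.extend(d.columns)
        else:
            raise ValueError(f"unknown covariate token {tok!r}")
    X = pd.concat(cols, axis=1).to_numpy(dtype=float)
    return X, names


def build_covariates(
    df: pd.DataFrame,
    measure: str | MeasureSpec,
    tokens: Sequence[str],
) -> list[Covariate]:
    """Covariate list for the MFP model: age is FP-eligible and force-retained,
    the global measure enters FP-eligibly only under ``global_fp``, and the
    acquisition covariates are linear-only."""
    spec = _measure_spec(measure)
    covs: list[Covariate] = []
    for tok in tokens:
        if tok == "age":
            covs.append(
                Covariate("age", df["age"].to_numpy(float), role="fp",
                          force_retain=True)
            )
        elif tok == "global_linear":
            covs.append(
                Covariate(spec.global_covariate,
                          df[spec.global_covariate].to_numpy(float),
                          role="linear")
            )
        elif tok == "global_fp":
            covs.append(
                Covariate(spec.global_covariate,
                          df[spec.global_covariate].to_numpy(float),
                          role="fp")
            )
        elif tok == "euler":
            covs.append(Covariate("euler", df["euler"].to_numpy(float),
                                  role="linear"))
        elif tok == "vendor":
            for col, vals in _dummies(df, "vendor", "vendor").items():
                covs.append(Covariate(col, vals.to_numpy(float), role="linear"))
        elif tok == "fs":
            for col, vals in _dummies(df, "fs_version", "fs").items():
                covs.append(Covariate(col, vals.to_numpy(float), role="linear"))
        else:
            raise ValueError(f"unknown covariate token {tok!r}")
    return covs


# ---------------------------------------------------------------------------
# algorithms behind one contract


def _fit_predict(algorithm, y_tr, df_tr, df_te, measure, tokens, alpha=0.05):
    """Fit one algorithm on a training frame and predict the test frame."""
    if callable(algorithm):
        return algorithm(y_tr, df_tr, df_te, measure, tokens)
    name = algorithm.lower()
    if name == "mfpr":
        covs = build_covariates(df_tr, measure, tokens)
        model = fit_mfp(y_tr, covs, alpha=alpha)
        data_te = _covariate_data(df_te, measure, tokens)
        return model.predict(data_te)
    if name == "lms":
        extra = [t for t in tokens if t != "age"]
        if extra:
            raise ValueError(
                f"LMS accommodates only age as explanatory variable, got {extra}"
            )
        model = bm.fit_lms(y_tr, df_tr["age"].to_numpy(float))
        return model.predict(df_te["age"].to_numpy(float))
    X_tr, _ = build_design(df_tr, measure, tokens)
    X_te, _ = build_design(df_te, measure, tokens)
    if name == "olsr":
        model = bm.fit_olsr(y_tr, X_tr)
    elif name == "blr":
        model = bm.fit_blr(y_tr, X_tr)
    elif name == "gpr":
        model = bm.fit_gpr(y_tr, X_tr, noise=1e-2)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return model.predict(X_te)


def _covariate_data(df, measure, tokens) -> dict[str, np.ndarray]:
    covs = build_covariates(df, measure, tokens)
    return {c.name: c.values for c in covs}


def crossval(
    algorithm,
    data: MorphometryTable | pd.DataFrame,
    measure: str | MeasureSpec,
    covariate_set: Sequence[str] = ("age",),
    k: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
) -> CVResult:
    """k-fold cross-validation of one algorithm on one regional measure.

    Folds are disjoint, exhaustive, and sized within one of each other; rows
    with a missing value of the measure are dropped first (per-measure
    modelling).  The mean metrics are arithmetic means over folds; per-fold
    CPU time is measured with :func:`time.process_time`.
    """
    df = data.df if isinstance(data, MorphometryTable) else data
    spec = _measure_spec(measure)
    keep = df[spec.name].notna().to_numpy()
    df = df.loc[keep].reset_index(drop=True)
    y = df[spec.name].to_numpy(float)
    n = len(y)
    if n < 5 * k:
        raise ValueError(f"need n >= {5 * k} for {k}-fold CV, got {n}")
    # dummy columns must be consistent across folds: precompute frame once
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[FitMetrics] = []
    for tr_idx, te_idx in folds.split(np.arange(n)):
        df_tr = df.iloc[tr_idx]
        df_te = df.iloc[te_idx]
        t0 = time.process_time()
        pred = _fit_predict(
            algorithm, y[tr_idx], df_tr, df_te, spec, covariate_set, alpha
        )
        elapsed = time.process_time() - t0
        m = metrics(y[te_idx], pred)
        m.cpu_time = elapsed
        per_fold.append(m)
    mean = FitMetrics(
        mae=float(np.mean([m.mae for m in per_fold])),
        rmse=float(np.mean([m.rmse for m in per_fold])),
        ev=float(np.mean([m.ev for m in per_fold])),
        cpu_time=float(np.mean([m.cpu_time for m in per_fold])),
    )
    return CVResult(per_fold=per_fold, mean=mean, k=k, seed=seed)


# ---------------------------------------------------------------------------
# covariate-combination search


@dataclass
class CovariateSearchResult:
    best_set: tuple[str, ...]
    per_set: dict[tuple[str, ...], pd.DataFrame]  # measure x fold MAE table
    mean_mae: dict[tuple[str, ...], float]
    p_fdr: dict[tuple[str, ...], float]
    significant: dict[tuple[str, ...], bool]
    test_confirmation: dict[tuple[str, ...], float] | None = None


def covariate_search(
    data: MorphometryTable | pd.DataFrame,
    measures: str | Sequence[str],
    sex: str | None = None,
    algorithm: str = "mfpr",
    combinations: Sequence[Sequence[str]] = COVARIATE_COMBINATIONS,
    k: int = 5,
    seed: int = 0,
    q: float = 0.05,
    test_data: MorphometryTable | pd.DataFrame | None = None,
) -> CovariateSearchResult:
    """Evaluate candidate covariate combinations and pick the winner.

    Each combination is scored by 5-fold-CV MAE per measure on the training
    data.  Its improvement over the age-only baseline is tested with a
    paired two-sided Wilcoxon signed-rank on fold-level MAEs concatenated
    across measures, BH-corrected across combinations at ``q``.  The winner
    is the significantly improving combination with the lowest mean CV MAE
    (ties broken toward the smaller set); with none significant, age-only is
    retained.  When ``test_data`` is given, the winner (and baseline) are
    additionally confirmed by a train-on-train / predict-on-test MAE.
    """
    if isinstance(measures, str):
        measures = [measures]
    df = data.df if isinstance(data, MorphometryTable) else data
    if sex is not None:
        df = df.loc[df["sex"] == sex].reset_index(drop=True)
    combos = [tuple(c) for c in combinations]
    baseline = ("age",)
    if baseline not in combos:
        combos.insert(0, baseline)

    per_set: dict[tuple[str, ...], pd.DataFrame] = {}
    for combo in combos:
        rows = []
        for m in measures:
            try:
                cv = crossval(algorithm, df, m, combo, k=k, seed=seed)
            except (KeyError, ValueError) as exc:
                warnings.warn(f"combination {combo} skipped for {m}: {exc}",
                              stacklevel=2)
                rows = []
                break
            for fold_i, fm in enumerate(cv.per_fold):
                rows.append((m, fold_i, fm.mae, fm.rmse))
        if rows:
            per_set[combo] = pd.DataFrame(
                rows, columns=["measure", "fold", "mae", "rmse"]
            )
    if baseline not in per_set:
        raise RuntimeError("age-only baseline could not be evaluated")

    mean_mae = {c: float(t["mae"].mean()) for c, t in per_set.items()}
    base_vec = per_set[baseline].sort_values(["measure", "fold"])["mae"].to_numpy()

    raw_p: dict[tuple[str, ...], float] = {}
    for combo, tab in per_set.items():
        if combo == baseline:
            continue
        vec = tab.sort_values(["measure", "fold"])["mae"].to_numpy()
        raw_p[combo] = paired_signed_rank_p(base_vec, vec)
    if raw_p:
        rej, p_adj, *_ = multipletests(list(raw_p.values()), alpha=q,
                                       method="fdr_bh")
        p_fdr = dict(zip(raw_p.keys(), map(float, p_adj)))
        significant = {
            c: bool(r) and mean_mae[c] < mean_mae[baseline]
            for c, r in zip(raw_p.keys(), rej)
        }
    else:
        p_fdr, significant = {}, {}

    winners = [c for c in per_set if c != baseline and significant.get(c, False)]
    if winners:
        # sets statistically indistinguishable from the numerically best one
        # count as tied; the tie goes to the smaller set (variables are only
        # retained when they significantly improve performance)
        best_raw = min(winners, key=lambda c: (mean_mae[c], len(c)))
        best_vec = per_set[best_raw].sort_values(["measure", "fold"])[
            "mae"
        ].to_numpy()
        tied = []
        for c in winners:
            vec = per_set[c].sort_values(["measure", "fold"])["mae"].to_numpy()
            if c == best_raw or paired_signed_rank_p(best_vec, vec) > 0.05:
                tied.append(c)

        def complexity(c):  # FP-eligible global costs more than linear
            return len(c) + (0.5 if "global_fp" in c else 0.0)

        best = min(tied, key=lambda c: (complexity(c), mean_mae[c]))
    else:
        best = baseline

    confirmation = None
    if test_data is not None:
        test_df = (
            test_data.df if isinstance(test_data, MorphometryTable) else test_data
        )
        if sex is not None:
            test_df = test_df.loc[test_df["sex"] == sex].reset_index(drop=True)
        confirmation = {}
        for combo in {baseline, best}:
            maes = []
            for m in measures:
                spec = _measure_spec(m)
                tr = df.loc[df[spec.name].notna()]
                te = test_df.loc[test_df[spec.name].notna()]
                pred = _fit_predict(
                    algorithm, tr[spec.name].to_numpy(float), tr, te, spec, combo
                )
                maes.append(metrics(te[spec.name].to_numpy(float), pred).mae)
            confirmation[combo] = float(np.mean(maes))
    return CovariateSearchResult(
        best_set=best,
        per_set=per_set,
        mean_mae=mean_mae,
        p_fdr=p_fdr,
        significant=significant,
        test_confirmation=confirmation,
    )


def paired_signed_rank_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p; 1.0 when all pairs tie."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = a - b
    if np.allclose(diffs, 0):
        return 1.0
    return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)


def compare_algorithms(
    reports: Mapping[str, Mapping[str, np.ndarray]], q: float = 0.05
) -> ComparisonReport:
    """Pairwise comparison of algorithms from concatenated metric vectors.

    ``reports`` maps algorithm name to {metric name: vector of per-measure
    values}, with aligned measure order across algorithms.  Each algorithm
    pair gets a paired two-sided Wilcoxon signed-rank test per metric;
    Benjamini-Hochberg adjustment is applied across all pair-metric tests.
    """
    algs = list(reports)
    if len(algs) < 2:
        raise ValueError("need at least two algorithms to compare")
    metrics_names = list(reports[algs[0]])
    rows = []
    for metric in metrics_names:
        ref_len = len(np.asarray(reports[algs[0]][metric]))
        for i, a in enumerate(algs):
            if len(np.asarray(reports[a][metric])) != ref_len:
                raise ValueError(
                    f"metric vectors for {metric!r} have mismatched lengths"
                )
        for i, a in enumerate(algs):
            for b in algs[i + 1 :]:
                va = np.asarray(reports[a][metric], dtype=float)
                vb = np.asarray(reports[b][metric], dtype=float)
                p = paired_signed_rank_p(va, vb)
                stat = float(np.median(va - vb))
                rows.append((metric, a, b, stat, p))
    tab = pd.DataFrame(rows, columns=["metric", "alg_a", "alg_b",
                                      "median_diff", "p"])
    rej, p_adj, *_ = multipletests(tab["p"].to_numpy(), alpha=q, method="fdr_bh")
    tab["p_fdr"] = p_adj
    tab["significant"] = rej
    return ComparisonReport(table=tab, q=q)
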