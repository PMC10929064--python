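"""Final normative models and individual deviation z-scores.

The optimised normative model for each sex and regional measure is a
multivariable fractional-polynomial regression with a nonlinear
(FP-eligible, force-retained) age term and a linear term for the measure's
paired global covariate.  A subject's deviation score is

    z = (y_observed - y_predicted) / RMSE_m

where RMSE_m is the training-subset root-mean-square error stored in the
pretrained bundle.  Because RMSE_m is the training RMSE of an
intercept-bearing least-squares fit, z-scores computed on the training data
themselves have mean 0 and population SD 1 exactly (a useful self-check).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .data_prep import apply_centring, extreme_mask
from .evaluation import metrics
from .fracpoly import Covariate, fit_mfp
from .registry_io import (
    MeasureSpec,
    MorphometryTable,
    PretrainedBundle,
    build_measure_registry,
)

logger = logging.getLogger(__name__)

_REGISTRY = {m.name: m for m in build_measure_registry()}

#: Covariate columns centred before fitting (age and the paired global).
AGE_DOMAIN = (3.0, 90.0)


@dataclass
class DeviationScore:
    subject_id: str
    measure: str
    z: float
    y_obs: float
    y_pred: float


def train_normative_model(
    train_data: MorphometryTable | pd.DataFrame,
    measure: str | MeasureSpec,
    sex: str,
    min_n: int = 200,
    alpha: float = 0.05,
    remove_extreme_values: bool = True,
) -> PretrainedBundle:
    """Fit the optimised sex-specific normative model for one measure.

    The training table is filtered to ``sex``, rows with the measure missing
    or (optionally) outside the Tukey fences are dropped, age and the paired
    global covariate are mean-centred (constants stored in the bundle), and
    an MFP model is fitted with FP-eligible force-retained age plus the
    linear-only global covariate.  ``rmse_m`` is the training RMSE.
    """
    spec = measure if isinstance(measure, MeasureSpec) else _REGISTRY[measure]
    df = train_data.df if isinstance(train_data, MorphometryTable) else train_data
    df = df.loc[df["sex"] == sex]
    df = df.loc[df[spec.name].notna()]
    if remove_extreme_values and len(df) >= 4:
        mask = extreme_mask(df[spec.name].to_numpy(float))
        df = df.loc[mask]
    if len(df) < min_n:
        raise ValueError(
            f"training subset for {spec.name}/{sex} has n={len(df)} < "
            f"required minimum {min_n}"
        )
    age = df["age"].to_numpy(float)
    gvals = df[spec.global_covariate].to_numpy(float)
    age_mean = float(age.mean())
    g_mean = float(gvals.mean())
    constants = {"age": age_mean, spec.global_covariate: g_mean}

    # the centred-age FP transform is anchored to the modelled age domain:
    # z = (age - mean + shift)/10 spans [1, ~9.7] over ages 3-90, keeping
    # negative powers tame near the young edge and valid for any new
    # subject in range
    age_shift = age_mean - AGE_DOMAIN[0] + 10.0
    covs = [
        Covariate("age", age - age_mean, role="fp", force_retain=True,
                  shift=age_shift, scale=10.0),
        Covariate(spec.global_covariate, gvals - g_mean, role="linear"),
    ]
    y = df[spec.name].to_numpy(float)
    model = fit_mfp(y, covs, alpha=alpha)
    bundle = PretrainedBundle(
        measure=spec,
        sex=sex,
        model=model,
        centring_constants=constants,
        rmse_m=model.train_rmse,
        provenance={
            "n_train": int(len(df)),
            "software": f"morphonorm {_pkg_version}",
            "selected_forms": model.selected_forms,
        },
    )
    bundle.validate()
    return bundle


def zscore(
    bundle: PretrainedBundle, new_data: MorphometryTable | pd.DataFrame
) -> list[DeviationScore]:
    """Deviation z-scores for new subjects under a pretrained bundle.

    New data are centred with the bundle's stored constants; subjects with
    the measure missing are skipped with a log entry.  The result is
    invariant to the row order of ``new_data``.
    """
    df = new_data.df if isinstance(new_data, MorphometryTable) else new_data
    name = bundle.measure.name
    if name not in df.columns:
        raise ValueError(f"new data lack the bundle's measure column {name!r}")
    present = df[name].notna()
    n_skipped = int((~present).sum())
    if n_skipped:
        logger.info("zscore: skipped %d subjects missing %s", n_skipped, name)
    df = df.loc[present]
    centred = apply_centring(df, bundle.centring_constants)
    data = {
        "age": centred["age"].to_numpy(float),
        bundle.measure.global_covariate: centred[
            bundle.measure.global_covariate
        ].to_numpy(float),
    }
    y_pred = bundle.model.predict(data)
    y_obs = df[name].to_numpy(float)
    z = (y_obs - y_pred) / bundle.rmse_m
    return [
        DeviationScore(
            subject_id=str(sid), measure=name,
            z=float(zi), y_obs=float(o), y_pred=float(p),
        )
        for sid, zi, o, p in zip(df["subject_id"], z, y_obs, y_pred)
    ]


def scores_frame(scores: list[DeviationScore]) -> pd.DataFrame:
    """Tidy frame (subject_id, measure, y_obs, y_pred, z) from score lists."""
    return pd.DataFrame(
        [(s.subject_id, s.measure, s.y_obs, s.y_pred, s.z) for s in scores],
        columns=["subject_id", "measure", "y_obs", "y_pred", "z"],
    )


@dataclass
class StabilityReport:
    per_measure_r: pd.Series        # Pearson r of z across subjects, per measure
    delta_z: pd.DataFrame           # per subject x measure z change
    baseline_metrics: pd.DataFrame  # measure, mae, rmse (|z| treated as error)
    followup_metrics: pd.DataFrame


def longitudinal_stability(
    z_baseline: pd.DataFrame, z_followup: pd.DataFrame
) -> StabilityReport:
    """Stability of deviation scores across two timepoints.

    Inputs are tidy frames from :func:`scores_frame` (one per timepoint)
    covering the same subjects.  Reports the per-measure Pearson correlation
    of z across matched subjects, the distribution of per-subject z changes,
    and MAE/RMSE of observed-vs-predicted values at each timepoint.
    """
    merged = z_baseline.merge(
        z_followup, on=["subject_id", "measure"], suffixes=("_b", "_f")
    )
    if merged["subject_id"].nunique() < 3:
        raise ValueError("longitudinal stability needs >= 3 matched subjects")
    r_by_measure = {}
    for measure, grp in merged.groupby("measure"):
        zb = grp["z_b"].to_numpy()
        zf = grp["z_f"].to_numpy()
        if len(grp) < 3 or np.std(zb) == 0 or np.std(zf) == 0:
            r_by_measure[measure] = np.nan
        else:
            r_by_measure[measure] = float(np.corrcoef(zb, zf)[0, 1])
    delta = merged.assign(delta_z=merged["z_f"] - merged["z_b"])[
        ["subject_id", "measure", "delta_z"]
    ]

    def _point_metrics(frame, suffix):
        rows = []
        for measure, grp in frame.groupby("measure"):
            m = metrics(grp[f"y_obs{suffix}"], grp[f"y_pred{suffix}"])
            rows.append((measure, m.mae, m.rmse))
        return pd.DataFrame(rows, columns=["measure", "mae", "rmse"])

    return StabilityReport(
        per_measure_r=pd.Series(r_by_measure, name="pearson_r"),
        delta_z=delta,
        baseline_metrics=_point_metrics(merged, "_b"),
        followup_metrics=_point_metrics(merged, "_f"),
    )
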