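"""Measure registry and table / model-bundle input-output.

Regional brain morphometry comes in three families: cortical thickness and
cortical surface area for the 68 Desikan-Killiany atlas regions (34 per
hemisphere), and 14 bilateral subcortical volumes from the Aseg segmentation.
Each regional measure is modelled against age together with one *global*
covariate chosen by family: mean cortical thickness for regional thickness,
total cortical surface area for regional area, and total intracranial volume
for subcortical volumes.

The module defines:

* :func:`build_measure_registry` — the canonical, order-stable list of the
  150 :class:`MeasureSpec` targets;
* :class:`MorphometryTable` — a validated wrapper around a subject-by-measure
  :class:`pandas.DataFrame`;
* :func:`read_table` / :func:`write_table` — delimited-text ingest with
  configurable column mapping and per-row error reporting;
* :func:`save_bundle` / :func:`load_bundle` — lossless JSON serialisation of a
  pretrained normative model (:class:`PretrainedBundle`).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BUNDLE_SCHEMA_VERSION = 1

#: Mandatory non-regional columns of a morphometry table.
CORE_COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "site",
    "vendor",
    "fs_version",
    "euler",
    "icv",
    "mean_ct",
    "total_sa",
)

#: The 34 Desikan-Killiany cortical parcels (per hemisphere).
DESIKAN_KILLIANY_REGIONS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: The seven bilateral Aseg structures (14 measures with both hemispheres).
ASEG_STRUCTURES = (
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens-area",
)

#: Family → paired global covariate column.
GLOBAL_FOR_METRIC = {
    "thickness": "mean_ct",
    "area": "total_sa",
    "subcortical_volume": "icv",
}


@dataclass(frozen=True)
class MeasureSpec:
    """One regional morphometry target and its paired global covariate.

    Parameters
    ----------
    name
        FreeSurfer-style measure name, e.g. ``lh_medialorbitofrontal_thickness``
        or ``Left-Thalamus``.
    metric
        ``thickness`` | ``area`` | ``subcortical_volume``.
    hemisphere
        ``L`` | ``R`` (``NA`` reserved for midline measures; none in the
        default registry).
    global_covariate
        The mandated global column: ``mean_ct`` for thickness, ``total_sa``
        for area, ``icv`` for subcortical volume.
    """

    name: str
    metric: str
    hemisphere: str
    global_covariate: str

    def __post_init__(self) -> None:
        if self.metric not in GLOBAL_FOR_METRIC:
            raise ValueError(f"unknown metric {self.metric!r}")
        expected = GLOBAL_FOR_METRIC[self.metric]
        if self.global_covariate != expected:
            raise ValueError(
                f"metric {self.metric!r} must pair with {expected!r}, "
                f"got {self.global_covariate!r}"
            )
        if self.hemisphere not in ("L", "R", "NA"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")


def build_measure_registry() -> list[MeasureSpec]:
    """Return the canonical list of the 150 regional measure targets.

    Order is deterministic: 68 thickness measures (lh then rh, atlas order),
    68 surface-area measures, then the 14 subcortical volumes
    (Left/Right per structure).
    """
    specs: list[MeasureSpec] = []
    for metric, suffix in (("thickness", "thickness"), ("area", "area")):
        for hemi, prefix in (("L", "lh"), ("R", "rh")):
            for region in DESIKAN_KILLIANY_REGIONS:
                specs.append(
                    MeasureSpec(
                        name=f"{prefix}_{region}_{suffix}",
                        metric=metric,
                        hemisphere=hemi,
                        global_covariate=GLOBAL_FOR_METRIC[metric],
                    )
                )
    for structure in ASEG_STRUCTURES:
        for hemi, prefix in (("L", "Left"), ("R", "Right")):
            specs.append(
                MeasureSpec(
                    name=f"{prefix}-{structure}",
                    metric="subcortical_volume",
                    hemisphere=hemi,
                    global_covariate="icv",
                )
            )
    return specs


def registry_names() -> list[str]:
    """Names of all 150 registry measures, in registry order."""
    return [spec.name for spec in build_measure_registry()]


@dataclass
class MorphometryTable:
    """Subject-by-measure table with demographics and acquisition covariates.

    Wraps a :class:`pandas.DataFrame` whose columns are :data:`CORE_COLUMNS`
    plus any subset of the registry's regional measure names. Regional values
    may be missing per subject (models are fitted per measure); core fields
    may not.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing mandatory columns: {missing}")
        if self.df["subject_id"].duplicated().any():
            dupes = self.df.loc[self.df["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject_id values: {sorted(set(dupes))[:5]}")
        bad_sex = set(self.df["sex"].unique()) - {"F", "M"}
        if bad_sex:
            raise ValueError(f"sex must be F or M, found {bad_sex}")
        for col in ("icv", "mean_ct", "total_sa"):
            vals = self.df[col].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise ValueError(f"non-positive values in global measure {col!r}")
        known = set(CORE_COLUMNS) | set(registry_names())
        unknown = [c for c in self.df.columns if c not in known]
        if unknown:
            raise ValueError(f"columns not in registry: {unknown[:5]}")
        ages = self.df["age"].to_numpy(dtype=float)
        out = (ages < 3) | (ages > 90)
        if out.any():
            warnings.warn(
                f"{int(out.sum())} subjects outside the modelled age range 3-90",
                stacklevel=2,
            )

    @property
    def regional_columns(self) -> list[str]:
        core = set(CORE_COLUMNS)
        return [c for c in self.df.columns if c not in core]

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "MorphometryTable":
        return MorphometryTable(self.df.loc[mask].reset_index(drop=True))

    def by_sex(self, sex: str) -> "MorphometryTable":
        if sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        return self.subset(self.df["sex"] == sex)


def read_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> MorphometryTable:
    """Read a delimited subject table into a :class:`MorphometryTable`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    schema
        Optional map from file column names to canonical names (e.g.
        ``{"participant": "subject_id"}``). Unmapped columns keep their name.
    sep
        Field delimiter; inferred from the extension when ``None``
        (``.tsv`` → tab, otherwise comma).

    Rows with a missing or non-numeric mandatory field (age, globals, sex,
    subject_id) are dropped and the count is logged; missing regional values
    are retained as NaN.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep)
    if schema:
        raw = raw.rename(columns=dict(schema))
    missing = [c for c in CORE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"input file lacks mandatory columns: {missing}")

    numeric_core = ["age", "euler", "icv", "mean_ct", "total_sa"]
    for col in numeric_core:
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
    regional = [c for c in raw.columns if c not in CORE_COLUMNS]
    for col in regional:
        raw[col] = pd.to_numeric(raw[col], errors="coerce")

    ok = raw["subject_id"].notna() & raw["sex"].isin(["F", "M"])
    for col in numeric_core:
        ok &= raw[col].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "read_table: dropped %d of %d rows with missing/invalid mandatory fields",
            n_dropped,
            len(raw),
        )
    clean = raw.loc[ok].reset_index(drop=True)
    clean["subject_id"] = clean["subject_id"].astype(str)
    return MorphometryTable(clean)


def write_table(table: MorphometryTable, path: str | Path, sep: str | None = None) -> None:
    """Write a table as delimited text (inverse of :func:`read_table`)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.df.to_csv(path, sep=sep, index=False)


@dataclass
class PretrainedBundle:
    """A final fitted sex-specific normative model, ready for deployment.

    Attributes
    ----------
    measure
        The regional target the model predicts.
    sex
        ``F`` or ``M``; models are always sex-specific.
    model
        The fitted fractional-polynomial model (:class:`morphonorm.fracpoly.FPModel`).
    centring_constants
        Training-subset means subtracted from each covariate column before
        fitting; applied identically to any new data.
    rmse_m
        Training-subset root-mean-square error; the denominator of the
        deviation z-score ``z = (y − ŷ)/rmse_m``.
    provenance
        Free-text metadata (training sample size, software version, ...).
    """

    measure: MeasureSpec
    sex: str
    model: "object"
    centring_constants: dict[str, float]
    rmse_m: float
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if not (self.rmse_m > 0 and math.isfinite(self.rmse_m)):
            raise ValueError(f"rmse_m must be positive and finite, got {self.rmse_m}")


def save_bundle(bundle: PretrainedBundle, path: str | Path) -> None:
    """Serialise a bundle to a human-readable JSON document."""
    from .fracpoly import FPModel  # local import avoids a cycle

    bundle.validate()
    if not isinstance(bundle.model, FPModel):
        raise TypeError("bundle.model must be an FPModel")
    doc = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "measure": {
            "name": bundle.measure.name,
            "metric": bundle.measure.metric,
            "hemisphere": bundle.measure.hemisphere,
            "global_covariate": bundle.measure.global_covariate,
        },
        "sex": bundle.sex,
        "model": bundle.model.to_dict(),
        "centring_constants": {k: float(v) for k, v in bundle.centring_constants.items()},
        "rmse_m": float(bundle.rmse_m),
        "provenance": bundle.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_bundle(path: str | Path) -> PretrainedBundle:
    """Load a bundle saved by :func:`save_bundle`.

    Raises
    ------
    ValueError
        On a schema-version mismatch or a corrupted/incomplete document;
        never silently reinterprets.
    """
    from .fracpoly import FPModel

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted bundle file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise ValueError(f"not a model bundle: {path}")
    if doc["schema_version"] != BUNDLE_SCHEMA_VERSION:
        raise ValueError(
            f"bundle schema version {doc['schema_version']} != "
            f"supported {BUNDLE_SCHEMA_VERSION}"
        )
    try:
        spec = MeasureSpec(**doc["measure"])
        bundle = PretrainedBundle(
            measure=spec,
            sex=doc["sex"],
            model=FPModel.from_dict(doc["model"]),
            centring_constants={k: float(v) for k, v in doc["centring_constants"].items()},
            rmse_m=float(doc["rmse_m"]),
            provenance=doc.get("provenance", {}),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"corrupted bundle file {path}: missing field {exc}") from exc
    bundle.validate()
    return bundle
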