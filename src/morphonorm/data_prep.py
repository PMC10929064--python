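"""Data preparation: stratified splitting, extreme-value removal,
mean-centring, and age binning.

The preparation pipeline for each sex-specific subsample is: split 80/20
into training and test subsets by stratified randomisation on scanning site
and age bin; remove extreme values per measure using Tukey fences
(Q1 - 1.5*IQR, Q3 + 1.5*IQR, type-7 quantiles); mean-centre covariates using
constants computed on the training subset and applied to both subsets (the
constants ship with the pretrained model so new data can be centred
identically).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry_io import MorphometryTable

logger = logging.getLogger(__name__)

#: Right-closed age-bin edges: (3,10], (10,20], ..., (80,90].
AGE_BIN_EDGES = (3.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)

OUT_OF_RANGE_LABEL = "out_of_range"


def make_age_bins(ages) -> pd.Categorical:
    """Assign each age to one of nine decade-style bins.

    Bins are right-closed: bin 1 covers ages 3-10 inclusive, bin 2 is
    (10, 20], ..., bin 9 is (80, 90].  Ages outside [3, 90] get the explicit
    ``out_of_range`` label.
    """
    ages = np.asarray(ages, dtype=float)
    labels = [f"bin{i}" for i in range(1, 10)]
    cats = pd.cut(
        ages, bins=list(AGE_BIN_EDGES), labels=labels, include_lowest=True
    )
    cats = cats.add_categories([OUT_OF_RANGE_LABEL])
    return cats.fillna(OUT_OF_RANGE_LABEL)


@dataclass
class SplitResult:
    """An 80/20 train/test partition stratified by site and age bin."""

    train: MorphometryTable
    test: MorphometryTable
    strata_report: pd.DataFrame
    seed: int
    centring_constants: dict[str, float] = field(default_factory=dict)


def _stratum_rng(seed: int, site: str, age_bin: str) -> np.random.Generator:
    # per-stratum stream keyed by content, so input row order is irrelevant
    key = zlib.crc32(f"{site}|{age_bin}".encode()) & 0x7FFFFFFF
    return np.random.default_rng((seed, key))


def stratified_split(
    table: MorphometryTable, train_frac: float = 0.8, seed: int = 0
) -> SplitResult:
    """Split subjects into train/test within every site x age-bin stratum.

    Within each stratum the train count is ``round(n_s * train_frac)``
    (clamped so both subsets are non-empty when n_s >= 2); a stratum of size
    1 goes to train with a warning.  Assignment depends only on the seed and
    on subject identities, never on input row order.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    df = table.df
    bins = make_age_bins(df["age"].to_numpy())
    strata = pd.DataFrame(
        {"site": df["site"].to_numpy(), "age_bin": np.asarray(bins.astype(str))}
    )
    train_mask = np.zeros(len(df), dtype=bool)
    report_rows = []
    for (site, age_bin), idx in strata.groupby(["site", "age_bin"]).groups.items():
        idx = np.asarray(idx)
        n_s = len(idx)
        if n_s == 1:
            warnings.warn(
                f"stratum (site={site!r}, {age_bin}) has a single subject; "
                "assigned to train",
                stacklevel=2,
            )
            train_mask[idx] = True
            report_rows.append((site, age_bin, 1, 1, 0))
            continue
        # order by subject id so permuting input rows cannot change assignment
        ids = df["subject_id"].to_numpy()[idx]
        order = np.argsort(ids, kind="stable")
        idx = idx[order]
        n_train = int(round(n_s * train_frac))
        n_train = min(max(n_train, 1), n_s - 1)
        rng = _stratum_rng(seed, str(site), str(age_bin))
        perm = rng.permutation(n_s)
        train_mask[idx[perm[:n_train]]] = True
        report_rows.append((site, age_bin, n_s, n_train, n_s - n_train))

    report = pd.DataFrame(
        report_rows, columns=["site", "age_bin", "n", "n_train", "n_test"]
    )
    return SplitResult(
        train=table.subset(train_mask),
        test=table.subset(~train_mask),
        strata_report=report,
        seed=seed,
    )


def remove_extremes(values) -> tuple[np.ndarray, int]:
    """Drop values outside the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quantiles use linear interpolation (type-7), so the operation is exactly
    reproducible.  NaNs are ignored (neither kept nor counted as removed).
    Returns (kept values, number removed).
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        raise ValueError("remove_extremes needs at least 4 finite values")
    q1, q3 = np.quantile(finite, [0.25, 0.75])  # numpy default = type-7
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept = finite[(finite >= lo) & (finite <= hi)]
    return kept, int(finite.size - kept.size)


def extreme_mask(values) -> np.ndarray:
    """Boolean mask of values inside the Tukey fences (NaN -> False)."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        raise ValueError("extreme_mask needs at least 4 finite values")
    q1, q3 = np.quantile(finite, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    with np.errstate(invalid="ignore"):
        return np.isfinite(values) & (values >= lo) & (values <= hi)


def mean_centre(split: SplitResult, columns: list[str]) -> SplitResult:
    """Centre ``columns`` by their training-subset means, in train and test.

    The constants are computed on the training subset only and stored on the
    returned :class:`SplitResult` (and later inside pretrained bundles) so
    that held-out or new data are shifted by exactly the same amounts.
    Zero-variance columns are centred but flagged with a warning.
    """
    train_df = split.train.df.copy()
    test_df = split.test.df.copy()
    constants: dict[str, float] = dict(split.centring_constants)
    for col in columns:
        vals = pd.to_numeric(train_df[col], errors="raise")
        mean = float(np.nanmean(vals))
        if float(np.nanstd(vals)) == 0.0:
            warnings.warn(f"column {col!r} has zero variance in training data",
                          stacklevel=2)
        constants[col] = mean
        train_df[col] = train_df[col] - mean
        test_df[col] = test_df[col] - mean
    # bypass table validation: centred globals are legitimately non-positive
    train = MorphometryTable.__new__(MorphometryTable)
    train.df = train_df
    test = MorphometryTable.__new__(MorphometryTable)
    test.df = test_df
    return SplitResult(
        train=train,
        test=test,
        strata_report=split.strata_report,
        seed=split.seed,
        centring_constants=constants,
    )


def apply_centring(df: pd.DataFrame, constants: dict[str, float]) -> pd.DataFrame:
    """Apply stored centring constants to new data (deployment path)."""
    out = df.copy()
    for col, mean in constants.items():
        if col in out.columns:
            out[col] = out[col] - mean
    return out
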