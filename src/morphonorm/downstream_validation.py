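"""Do deviation z-scores beat raw measures for clinical prediction?

Two evaluation tasks with permutation inference, mirroring a case-control
deployment of normative models:

* diagnostic classification — a linear-kernel support vector classifier
  (C = 1) on either z-score features or raw morphometry, scored by the AUC
  averaged over stratified 5-fold CV repeated many times, with significance
  against a null built from random permutations of the diagnostic labels;
* symptom-severity prediction — ridge regression (penalty 1.0) on the
  leading principal components (10 by default; a warning fires when they
  explain < 90% of the variance), scored by held-out MAE, with permutation
  of the symptom scores.

All standardisation and principal-component reduction is fitted strictly
inside training folds.  Paired feature-set comparisons (delta AUC, delta
MAE) reuse the same permutation for both sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "PermutationResult",
    "svc_auc",
    "ridge_symptom_prediction",
    "permutation_test",
    "delta_statistic",
]


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    delta: bool = False  # True when the statistic is a paired difference


def svc_auc(
    features,
    labels,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    C: float = 1.0,
) -> float:
    """Mean AUC of a linear-kernel SVC over repeated stratified k-fold CV.

    Features are standardised inside each training fold; the AUC uses the
    decision-function values on the held-out fold, averaged over folds and
    repeats.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {len(classes)}")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k} folds"
        )
    aucs = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for tr, te in skf.split(X, y):
            scaler = StandardScaler().fit(X[tr])
            clf = SVC(kernel="linear", C=C)
            clf.fit(scaler.transform(X[tr]), y[tr])
            scores = clf.decision_function(scaler.transform(X[te]))
            if len(np.unique(y[te])) < 2:
                continue  # degenerate held-out fold carries no AUC
            aucs.append(roc_auc_score(y[te], scores))
    return float(np.mean(aucs))


def ridge_symptom_prediction(
    features,
    scores,
    k: int = 5,
    repeats: int = 100,
    pcs: int = 10,
    seed: int = 0,
    alpha: float = 1.0,
    variance_target: float = 0.90,
) -> float:
    """Held-out MAE of ridge regression on leading principal components.

    Within each training fold the features are standardised and reduced to
    ``pcs`` principal components (a warning is emitted when those explain
    less than ``variance_target`` of the variance); components are scaled to
    unit training variance before the ridge fit so the penalty acts evenly.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(X) != len(y):
        raise ValueError("features and scores must align")
    if pcs >= len(X) - len(X) // k:
        raise ValueError(f"pcs={pcs} >= smallest training-fold size")
    warned = False
    maes = []
    for rep in range(repeats):
        folds = KFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for tr, te in folds.split(X):
            scaler = StandardScaler().fit(X[tr])
            Xtr = scaler.transform(X[tr])
            Xte = scaler.transform(X[te])
            n_comp = min(pcs, Xtr.shape[1], len(tr) - 1)
            pca = PCA(n_components=n_comp).fit(Xtr)
            if not warned and pca.explained_variance_ratio_.sum() < variance_target:
                warnings.warn(
                    f"first {n_comp} components explain "
                    f"{pca.explained_variance_ratio_.sum():.1%} "
                    f"< {variance_target:.0%} of the variance",
                    stacklevel=2,
                )
                warned = True
            Ztr = pca.transform(Xtr)
            Zte = pca.transform(Xte)
            sd = Ztr.std(axis=0)
            sd[sd == 0] = 1.0
            model = Ridge(alpha=alpha)
            model.fit(Ztr / sd, y[tr])
            pred = model.predict(Zte / sd)
            maes.append(float(np.mean(np.abs(y[te] - pred))))
    return float(np.mean(maes))


def permutation_test(
    statistic_fn,
    features,
    target,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> PermutationResult:
    """Permutation inference for a CV statistic.

    ``statistic_fn(features, target, seed)`` must be deterministic given its
    seed.  The target (labels or scores) is permuted ``n_perm`` times with a
    seeded generator; the same statistic seed is reused so fold structure is
    identical across permutations.  When ``features`` is a 2-tuple of
    feature sets the statistic is treated as a paired difference and the
    same permutation feeds both sets (handled inside ``statistic_fn``; see
    :func:`delta_statistic`).

    p = (1 + #{null at least as extreme}) / (n_perm + 1); ``alternative``
    is ``greater`` (observed above null) or ``two-sided`` (absolute
    deviation from the null mean).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: p-values are coarse", stacklevel=2)
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    target = np.asarray(target)
    rng = np.random.default_rng(seed)
    observed = float(statistic_fn(features, target, seed))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = statistic_fn(features, rng.permutation(target), seed)
    if alternative == "greater":
        extreme = int(np.sum(null >= observed))
    else:
        center = float(null.mean())
        extreme = int(np.sum(np.abs(null - center) >= abs(observed - center)))
    p = (1 + extreme) / (n_perm + 1)
    return PermutationResult(
        observed=observed,
        null=null,
        p_value=float(p),
        delta=isinstance(features, tuple),
    )


def delta_statistic(base_fn):
    """Lift a single-set statistic into a paired difference over two sets.

    ``delta_statistic(svc_auc)((z_features, raw_features), labels, seed)``
    returns ``stat(z) - stat(raw)`` with identical fold structure on both
    sides, as required for paired permutation inference.
    """

    def stat(features, target, seed):
        a, b = features
        return base_fn(a, target, seed=seed) - base_fn(b, target, seed=seed)

    return stat
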