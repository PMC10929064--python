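"""Multivariable fractional polynomial (MFP) regression.

A fractional polynomial of degree m transforms a positive covariate z through
powers drawn from the fixed set P = {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, with the
conventions that power 0 means ln(z) and that a repeated power (p, p)
contributes the pair (z^p, z^p * ln z).  Degree-1 (FP1) models have 8
candidate shapes; degree-2 (FP2) models have 36 (28 distinct pairs plus the
8 repeats).  The functional form of each covariate is selected by the RA2
closed-test procedure: a sequence of chi-squared deviance-difference tests
comparing the best FP2 against the null model (4 df), against the linear
model (3 df), and against the best FP1 (2 df), stopping at the first
non-significant step so that the simplest adequate form wins.  With several
covariates the selection is cycled in order of decreasing significance until
the chosen forms stabilise (the MFP algorithm).

This family is well suited to lifespan growth curves: it covers monotone,
saturating and single-peak shapes while remaining a linear model in its
transformed basis, so fits are exact least squares and cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FP_POWERS",
    "FPSpec",
    "FPTerm",
    "FPModel",
    "RA2Result",
    "Covariate",
    "default_shift_scale",
    "fp_basis",
    "fit_fp_fixed",
    "search_best_fp",
    "closed_test_ra2",
    "fit_mfp",
    "fp1_candidates",
    "fp2_candidates",
]

#: The canonical fractional-polynomial power set.
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def fp1_candidates() -> list[tuple[float]]:
    """The 8 degree-1 candidate power tuples."""
    return [(p,) for p in FP_POWERS]


def fp2_candidates() -> list[tuple[float, float]]:
    """The 36 degree-2 candidates: 28 distinct pairs + 8 repeated powers."""
    cands = []
    for i, p in enumerate(FP_POWERS):
        for q in FP_POWERS[i:]:
            cands.append((p, q))
    return cands


@dataclass(frozen=True)
class FPSpec:
    """Powers plus the shift/scale making the transformed covariate positive.

    ``z = (x + shift) / scale`` must be strictly positive wherever the basis
    is evaluated.
    """

    powers: tuple[float, ...]
    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.powers) <= 2:
            raise ValueError("FP degree must be 1 or 2")
        if tuple(sorted(self.powers)) != tuple(self.powers):
            raise ValueError("powers must be sorted non-decreasing")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def default_shift_scale(x: np.ndarray) -> tuple[float, float]:
    """Shift/scale rule for a raw covariate.

    If ``min(x) <= 0`` the shift is ``-min(x)`` plus half the smallest
    positive gap between order statistics, guaranteeing positivity.  The
    scale is a power of ten chosen so the working range of z is moderate:
    ``10^round(log10(range(x)))`` when the range falls outside [0.1, 100],
    else 1.
    """
    x = np.asarray(x, dtype=float)
    xmin = float(np.min(x))
    if xmin > 0:
        shift = 0.0
    else:
        sorted_x = np.unique(x)
        gaps = np.diff(sorted_x)
        pos = gaps[gaps > 0]
        half_gap = float(pos.min()) / 2.0 if pos.size else 1.0
        shift = -xmin + half_gap
    rng = float(np.max(x) - xmin)
    if rng > 0 and not (0.1 <= rng <= 100.0):
        scale = 10.0 ** round(np.log10(rng))
    else:
        scale = 1.0
    return shift, scale


def fp_basis(x: np.ndarray, spec: FPSpec) -> np.ndarray:
    """Evaluate the FP basis columns for ``x`` under ``spec``.

    Power 0 maps to ln(z); p != 0 to z**p; a repeated power (p, p) to the
    pair (z**p, z**p * ln z).
    """
    x = np.asarray(x, dtype=float)
    z = (x + spec.shift) / spec.scale
    if np.any(z <= 0):
        bad = float(x[np.argmin(z)])
        raise ValueError(
            f"fp_basis: transformed covariate non-positive at x={bad!r} "
            f"(shift={spec.shift}, scale={spec.scale})"
        )
    lnz = np.log(z)

    def one(p: float) -> np.ndarray:
        return lnz if p == 0.0 else z**p

    cols = []
    prev: float | None = None
    for p in spec.powers:
        if prev is not None and p == prev:
            cols.append(cols[-1] * lnz)  # repeated power: z^p * ln z
        else:
            cols.append(one(p))
        prev = p
    return np.column_stack(cols)


@dataclass(frozen=True)
class FPTerm:
    """One covariate's contribution to a fitted model."""

    name: str
    kind: str  # 'fp' | 'linear'
    spec: FPSpec | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fp", "linear"):
            raise ValueError(f"bad term kind {self.kind!r}")
        if self.kind == "fp" and self.spec is None:
            raise ValueError("fp term requires an FPSpec")

    def n_columns(self) -> int:
        return len(self.spec.powers) if self.kind == "fp" else 1

    def basis(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "linear":
            return np.asarray(x, dtype=float)[:, None]
        return fp_basis(x, self.spec)


@dataclass
class FPModel:
    """A fitted fractional-polynomial regression model.

    ``coefficients`` are ordered (intercept, then each term's basis columns
    in ``terms`` order).  ``deviance`` is the Gaussian deviance
    ``n * ln(2*pi*rss/n) + n``; only deviance *differences* are meaningful.
    """

    terms: list[FPTerm]
    coefficients: np.ndarray
    rss: float
    n: int
    selected_forms: dict[str, str] = field(default_factory=dict)
    converged: bool = True
    n_cycles: int = 0

    @property
    def deviance(self) -> float:
        return gaussian_deviance(self.rss, self.n)

    @property
    def train_rmse(self) -> float:
        return float(np.sqrt(self.rss / self.n))

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    def design(self, data: Mapping[str, np.ndarray]) -> np.ndarray:
        n = len(np.asarray(data[self.terms[0].name])) if self.terms else 1
        cols = [np.ones(n)]
        for term in self.terms:
            cols.append(term.basis(np.asarray(data[term.name], dtype=float)))
        return np.column_stack(cols)

    def predict(self, data: Mapping[str, np.ndarray]) -> np.ndarray:
        """Predict from a mapping (or DataFrame) of covariate columns."""
        if not self.terms:
            first = next(iter(data.values())) if hasattr(data, "values") else None
            n = len(first) if first is not None else 1
            return np.full(n, self.intercept)
        return self.design(data) @ self.coefficients

    def summary(self) -> str:
        lines = [f"FP model (n={self.n}, train RMSE={self.train_rmse:.6g})"]
        for term in self.terms:
            if term.kind == "linear":
                lines.append(f"  {term.name}: linear")
            else:
                lines.append(
                    f"  {term.name}: FP powers {term.spec.powers} "
                    f"(shift={term.spec.shift:.6g}, scale={term.spec.scale:.6g})"
                )
        omitted = [k for k, v in self.selected_forms.items() if v == "omitted"]
        if omitted:
            lines.append(f"  omitted: {', '.join(omitted)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "terms": [
                {
                    "name": t.name,
                    "kind": t.kind,
                    "powers": list(t.spec.powers) if t.spec else None,
                    "shift": t.spec.shift if t.spec else None,
                    "scale": t.spec.scale if t.spec else None,
                }
                for t in self.terms
            ],
            "coefficients": [float(c) for c in self.coefficients],
            "rss": float(self.rss),
            "n": int(self.n),
            "selected_forms": dict(self.selected_forms),
            "converged": bool(self.converged),
            "n_cycles": int(self.n_cycles),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FPModel":
        terms = []
        for t in doc["terms"]:
            spec = (
                FPSpec(tuple(t["powers"]), t["shift"], t["scale"])
                if t["kind"] == "fp"
                else None
            )
            terms.append(FPTerm(t["name"], t["kind"], spec))
        return cls(
            terms=terms,
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            rss=float(doc["rss"]),
            n=int(doc["n"]),
            selected_forms=dict(doc.get("selected_forms", {})),
            converged=bool(doc.get("converged", True)),
            n_cycles=int(doc.get("n_cycles", 0)),
        )


def gaussian_deviance(rss: float, n: int) -> float:
    """D = n ln(2*pi*rss/n) + n; additive constant fixed across comparisons."""
    if rss <= 0:
        rss = np.finfo(float).tiny  # exact fit: deviance -> -inf capped
    return float(n * np.log(2.0 * np.pi * rss / n) + n)


def _lstsq(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact least squares with an explicit rank check."""
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design: rank {rank} < {design.shape[1]} columns"
        )
    resid = y - design @ coef
    return coef, float(resid @ resid)


def fit_fp_fixed(
    y: np.ndarray,
    terms: Sequence[FPTerm],
    data: Mapping[str, np.ndarray],
) -> FPModel:
    """Least-squares fit of a model whose functional forms are fixed.

    Raises on a rank-deficient design rather than silently pseudo-inverting.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    ncols = 1 + sum(t.n_columns() for t in terms)
    if n <= ncols:
        raise ValueError(f"need n > {ncols} observations, got {n}")
    cols = [np.ones(n)]
    for t in terms:
        cols.append(t.basis(np.asarray(data[t.name], dtype=float)))
    design = np.column_stack(cols)
    coef, rss = _lstsq(y, design)
    return FPModel(terms=list(terms), coefficients=coef, rss=rss, n=n)


# ---------------------------------------------------------------------------
# power search and the RA2 closed test


def _rss_for_design(y, base_cols, extra):
    design = np.column_stack(base_cols + extra) if extra else np.column_stack(base_cols)
    _, rss = _lstsq(y, design)
    return rss


def _candidate_columns(z, lnz, powers):
    cols = []
    prev = None
    for p in powers:
        if prev is not None and p == prev:
            cols.append(cols[-1] * lnz)
        else:
            cols.append(lnz if p == 0.0 else z**p)
        prev = p
    return cols


def _simplicity_key(powers: tuple[float, ...]):
    # prefer powers near 1 (simpler shapes), then lexicographic order
    return (sum(abs(p - 1.0) for p in powers), powers)


def _search_powers(y, z, lnz, degree, base_cols):
    """Return (best_powers, best_rss) by exhaustive enumeration."""
    cands = fp1_candidates() if degree == 1 else fp2_candidates()
    results = []
    for powers in cands:
        cols = _candidate_columns(z, lnz, powers)
        try:
            rss = _rss_for_design(y, base_cols, cols)
        except np.linalg.LinAlgError:
            continue
        results.append((powers, rss))
    if not results:
        raise np.linalg.LinAlgError("all FP candidates rank-deficient")
    best_rss = min(r for _, r in results)
    tol = 1e-8 * max(1.0, abs(best_rss))
    tied = [(powers, r) for powers, r in results if r <= best_rss + tol]
    tied.sort(key=lambda pr: _simplicity_key(pr[0]))
    return tied[0]


def search_best_fp(
    y: np.ndarray,
    x: np.ndarray,
    degree: int = 2,
    adjust: Sequence[FPTerm] = (),
    data: Mapping[str, np.ndarray] | None = None,
    name: str = "x",
    shift: float | None = None,
    scale: float | None = None,
) -> FPModel:
    """Exhaustive deviance minimisation over the FP candidate shapes.

    Enumerates the 8 FP1 or 36 FP2 candidates for covariate ``x``, adjusting
    for the fixed-form ``adjust`` terms (whose columns come from ``data``).
    Ties are broken toward simpler powers (closer to 1, then lexicographic).
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if shift is None or scale is None:
        dflt = default_shift_scale(x)
        shift = dflt[0] if shift is None else shift
        scale = dflt[1] if scale is None else scale
    z = (x + shift) / scale
    if np.any(z <= 0):
        raise ValueError("shift/scale leave non-positive transformed values")
    lnz = np.log(z)
    base_cols = [np.ones(len(y))]
    for t in adjust:
        base_cols.append(t.basis(np.asarray(data[t.name], dtype=float)))
    powers, rss = _search_powers(y, z, lnz, degree, base_cols)
    spec = FPSpec(powers=powers, shift=shift, scale=scale)
    term = FPTerm(name, "fp", spec)
    all_terms = list(adjust) + [term]
    cols = base_cols + _candidate_columns(z, lnz, powers)
    design = np.column_stack(cols)
    coef, rss = _lstsq(y, design)
    # reorder coefficients to match terms order (adjust first, searched last)
    return FPModel(terms=all_terms, coefficients=coef, rss=rss, n=len(y))


@dataclass
class RA2Result:
    """Outcome of the closed-test function selection for one covariate."""

    form: str  # 'omitted' | 'linear' | 'FP1' | 'FP2'
    spec: FPSpec | None
    p_values: dict[str, float]
    deviances: dict[str, float]

    def as_term(self, name: str) -> FPTerm | None:
        if self.form == "omitted":
            return None
        if self.form == "linear":
            return FPTerm(name, "linear")
        return FPTerm(name, "fp", self.spec)


def closed_test_ra2(
    y: np.ndarray,
    x: np.ndarray,
    alpha: float = 0.05,
    adjust: Sequence[FPTerm] = (),
    data: Mapping[str, np.ndarray] | None = None,
    force_retain: bool = False,
    shift: float | None = None,
    scale: float | None = None,
) -> RA2Result:
    """RA2 closed-test selection of the functional form of ``x``.

    Sequential chi-squared deviance-difference tests at level ``alpha``:

    1. best FP2 vs null (x omitted), 4 df — any effect of x at all?  If not
       significant the covariate is omitted (kept linear when
       ``force_retain``).
    2. best FP2 vs linear, 3 df — any nonlinearity?  If not, linear.
    3. best FP2 vs best FP1, 2 df — is the second term needed?  If not, FP1;
       otherwise FP2.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if shift is None or scale is None:
        dflt = default_shift_scale(x)
        shift = dflt[0] if shift is None else shift
        scale = dflt[1] if scale is None else scale
    z = (x + shift) / scale
    lnz = np.log(z)
    base_cols = [np.ones(n)]
    for t in adjust:
        base_cols.append(t.basis(np.asarray(data[t.name], dtype=float)))

    rss_null = _rss_for_design(y, base_cols, [])
    rss_lin = _rss_for_design(y, base_cols, [x])
    p1, rss_fp1 = _search_powers(y, z, lnz, 1, base_cols)
    p2, rss_fp2 = _search_powers(y, z, lnz, 2, base_cols)

    dev = {
        "null": gaussian_deviance(rss_null, n),
        "linear": gaussian_deviance(rss_lin, n),
        "FP1": gaussian_deviance(rss_fp1, n),
        "FP2": gaussian_deviance(rss_fp2, n),
    }

    def chi2_p(d_simple: float, d_complex: float, df: int) -> float:
        delta = max(d_simple - d_complex, 0.0)
        return float(stats.chi2.sf(delta, df))

    p_vals = {
        "any_effect": chi2_p(dev["null"], dev["FP2"], 4),
        "nonlinearity": chi2_p(dev["linear"], dev["FP2"], 3),
        "second_term": chi2_p(dev["FP1"], dev["FP2"], 2),
    }

    if p_vals["any_effect"] > alpha:
        form = "linear" if force_retain else "omitted"
        spec = None
    elif p_vals["nonlinearity"] > alpha:
        form, spec = "linear", None
    elif p_vals["second_term"] > alpha:
        form, spec = "FP1", FPSpec(p1, shift, scale)
    else:
        form, spec = "FP2", FPSpec(p2, shift, scale)
    return RA2Result(form=form, spec=spec, p_values=p_vals, deviances=dev)


# ---------------------------------------------------------------------------
# multivariable cycling


@dataclass
class Covariate:
    """One model covariate with its eligibility for FP transformation.

    ``role='fp'`` lets the closed test pick among omitted/linear/FP1/FP2;
    ``role='linear'`` restricts the choice to omitted vs linear (1-df test).
    ``force_retain`` keeps the covariate at least linear regardless of
    significance (used for age: a normative model without age is
    meaningless).
    """

    name: str
    values: np.ndarray
    role: str = "fp"
    force_retain: bool = False
    shift: float | None = None  # override the automatic shift/scale, e.g.
    scale: float | None = None  # when the deployment range is known a priori

    def __post_init__(self) -> None:
        if self.role not in ("fp", "linear"):
            raise ValueError(f"bad covariate role {self.role!r}")
        self.values = np.asarray(self.values, dtype=float)


def fit_mfp(
    y: np.ndarray,
    covariates: Sequence[Covariate],
    alpha: float = 0.05,
    max_cycles: int = 5,
) -> FPModel:
    """MFP: cycle RA2 form selection over covariates until forms stabilise.

    Covariates are visited in order of decreasing significance from an
    initial all-linear fit; each visit reruns the closed test adjusting for
    the current forms of the others.  Terminates when a full cycle leaves all
    forms unchanged, or at ``max_cycles`` with a warning.
    """
    if not covariates:
        raise ValueError("fit_mfp requires at least one covariate")
    y = np.asarray(y, dtype=float)
    n = len(y)
    data = {c.name: c.values for c in covariates}

    # visit order: decreasing |t| from an initial all-linear fit
    design = np.column_stack([np.ones(n)] + [c.values for c in covariates])
    coef, rss = _lstsq(y, design)
    dof = n - design.shape[1]
    sigma2 = rss / max(dof, 1)
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, np.finfo(float).tiny))
    tstats = np.abs(coef[1:] / se[1:])
    order = list(np.argsort(-tstats))

    shifts = {}
    for c in covariates:
        auto = default_shift_scale(c.values)
        shifts[c.name] = (
            auto[0] if c.shift is None else c.shift,
            auto[1] if c.scale is None else c.scale,
        )
    forms: dict[str, RA2Result | None] = {c.name: None for c in covariates}
    # start all-linear so the first visits adjust for something sensible
    current: dict[str, FPTerm | None] = {
        c.name: FPTerm(c.name, "linear") for c in covariates
    }

    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        changed = False
        for idx in order:
            cov = covariates[idx]
            adjust = [
                t
                for other, t in current.items()
                if other != cov.name and t is not None
            ]
            if cov.role == "fp":
                shift, scale = shifts[cov.name]
                res = closed_test_ra2(
                    y,
                    cov.values,
                    alpha=alpha,
                    adjust=adjust,
                    data=data,
                    force_retain=cov.force_retain,
                    shift=shift,
                    scale=scale,
                )
            else:
                res = _linear_omit_test(
                    y, cov.values, alpha, adjust, data, cov.force_retain
                )
            forms[cov.name] = res
            new_term = res.as_term(cov.name)
            if _term_differs(current[cov.name], new_term):
                changed = True
            current[cov.name] = new_term
        if not changed:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MFP did not converge in {max_cycles} cycles; returning last forms",
            stacklevel=2,
        )

    final_terms = [current[c.name] for c in covariates if current[c.name] is not None]
    model = fit_fp_fixed(y, final_terms, data)
    model.selected_forms = {
        c.name: (forms[c.name].form if forms[c.name] else "omitted")
        for c in covariates
    }
    model.converged = converged
    model.n_cycles = cycle
    return model


def _linear_omit_test(y, x, alpha, adjust, data, force_retain) -> RA2Result:
    """1-df deviance test: does a linear-only covariate earn its place?"""
    n = len(y)
    base_cols = [np.ones(n)]
    for t in adjust:
        base_cols.append(t.basis(np.asarray(data[t.name], dtype=float)))
    rss_null = _rss_for_design(y, base_cols, [])
    rss_lin = _rss_for_design(y, base_cols, [np.asarray(x, dtype=float)])
    dev = {
        "null": gaussian_deviance(rss_null, n),
        "linear": gaussian_deviance(rss_lin, n),
    }
    p = float(stats.chi2.sf(max(dev["null"] - dev["linear"], 0.0), 1))
    if force_retain or p <= alpha:
        form = "linear"
    else:
        form = "omitted"
    return RA2Result(form=form, spec=None, p_values={"any_effect": p}, deviances=dev)


def _term_differs(a: FPTerm | None, b: FPTerm | None) -> bool:
    if (a is None) != (b is None):
        return True
    if a is None:
        return False
    return (a.kind, a.spec) != (b.kind, b.spec)
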