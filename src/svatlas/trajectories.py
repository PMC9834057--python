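"""Developmental-trajectory statistics.

Age effects on a feature f_i(t) are modeled as f_i(t) = s(t) + gamma_i with
s a penalized cubic spline and gamma_i a subject-specific random intercept
(GAMM); atlas-level features drop the random intercept (GAM).  The penalized
spline is fitted through its mixed-model representation: a cubic B-spline
basis with a second-difference penalty is split into unpenalized fixed
effects (intercept + linear trend) and an iid random-coefficient block, and
the smoothing parameter is the REML-estimated variance ratio (statsmodels
MixedLM).  Growth rates are reported as percentage change, velocities by
numerical differentiation of the fitted curve, and hemispheric asymmetry by
the laterality index LI = (left - right)/(left + right) with one-sample
two-tailed t-tests at the 1% significance level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

__all__ = [
    "FeatureTable",
    "TrajectoryFit",
    "fit_gamm",
    "fit_gam",
    "percent_change",
    "velocity_and_peak",
    "laterality_index",
    "laterality_test",
    "roi_summary",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject", "age_months", "feature", "value")


@dataclass
class FeatureTable:
    """Long-format feature observations (subject, age, feature, roi, value)."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"FeatureTable lacks column {col!r}")
        if "roi" not in df.columns:
            df["roi"] = ""
        df["roi"] = df["roi"].fillna("")
        if (df["age_months"] < 0).any():
            raise ValueError("ages must be >= 0")
        dup = df.duplicated(subset=["subject", "age_months", "feature", "roi"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate (subject, age, feature, roi) rows")
        self.data = df

    def select(self, feature: str, roi: str | None = None) -> pd.DataFrame:
        df = self.data[self.data["feature"] == feature]
        if roi is not None:
            df = df[df["roi"] == roi]
        if df.empty:
            raise ValueError(f"no rows for feature {feature!r}")
        return df

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


# --------------------------------------------------------------------------
# penalized-spline machinery (mixed-model representation)
# --------------------------------------------------------------------------


def _bspline_design(ages: np.ndarray, lo: float, hi: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with k basis functions on [lo, hi]."""
    if k < 4:
        raise ValueError("need k >= 4 basis functions for cubic splines")
    inner = np.linspace(lo, hi, k - 2)[1:-1]
    knots = np.r_[[lo] * 4, inner, [hi] * 4]
    t = np.clip(ages, lo, hi)
    design = BSpline.design_matrix(t, knots, 3).toarray()
    return design, knots


def _mixed_decomposition(knots: np.ndarray, k: int):
    """Split the penalized basis into fixed (null space) and random parts.

    Second-difference penalty S = D'D; eigenvectors with positive eigenvalue
    scaled by 1/sqrt(eigenvalue) become the random-coefficient transform.
    """
    D = np.diff(np.eye(k), n=2, axis=0)
    S = D.T @ D
    lam, U = np.linalg.eigh(S)
    pos = lam > 1e-10 * lam.max()
    return U[:, pos] / np.sqrt(lam[pos])  # (k, k-2)


@dataclass
class TrajectoryFit:
    """Fitted age trajectory with a callable evaluator on the observed range."""

    age_range: tuple[float, float]
    knots: np.ndarray
    coef_fixed: np.ndarray  # intercept + linear trend
    coef_spline: np.ndarray  # random-part coefficients (mixed representation)
    transform: np.ndarray  # basis -> random-part map
    smoothing_ratio: float  # residual variance / spline variance (lambda)
    intercept_variance: float  # subject random-intercept variance (GAMM; 0 for GAM)
    subject_effects: dict = field(default_factory=dict)
    k: int = 0

    def __call__(self, ages) -> np.ndarray:
        return self.predict(ages)

    def predict(self, ages) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        lo, hi = self.age_range
        if np.any(ages < lo - 1e-9) or np.any(ages > hi + 1e-9):
            raise ValueError(f"age outside fitted range [{lo}, {hi}]")
        t = np.clip(ages, lo, hi)
        B = BSpline.design_matrix(t, self.knots, 3).toarray()
        X = np.column_stack([np.ones_like(t), t - lo])
        out = X @ self.coef_fixed + (B @ self.transform) @ self.coef_spline
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite fitted curve")
        return out


def _fit_penalized(
    ages: np.ndarray,
    values: np.ndarray,
    subjects: np.ndarray | None,
    k: int,
) -> TrajectoryFit:
    lo, hi = float(ages.min()), float(ages.max())
    n_distinct = len(np.unique(np.round(ages, 6)))
    if n_distinct < 3:
        raise ValueError("need >= 3 distinct ages")
    if n_distinct < k - 2:
        raise ValueError(
            f"rank deficiency: {n_distinct} distinct ages cannot support k={k}; "
            "use a smaller k"
        )
    B, knots = _bspline_design(ages, lo, hi, k)
    T = _mixed_decomposition(knots, k)
    Z = B @ T  # (n, k-2) penalized random part
    X = np.column_stack([np.ones_like(ages), ages - lo])  # unpenalized null space

    var_spline, var_subj, var_resid = _reml_variances(values, X, Z, subjects)

    # mixed-model equations with the REML variances
    blocks = [X, Z]
    pen = [np.zeros(X.shape[1]), np.full(Z.shape[1], var_resid / max(var_spline, 1e-12))]
    subj_ids = None
    if subjects is not None and var_subj > 0:
        subj_ids = np.unique(subjects)
        Zu = (subjects[:, None] == subj_ids[None, :]).astype(float)
        blocks.append(Zu)
        pen.append(np.full(len(subj_ids), var_resid / max(var_subj, 1e-12)))
    C = np.hstack(blocks)
    P = np.diag(np.concatenate(pen))
    beta = np.linalg.solve(C.T @ C + P, C.T @ values)

    nX, nZ = X.shape[1], Z.shape[1]
    subject_effects = {}
    if subj_ids is not None:
        subject_effects = dict(zip(subj_ids, beta[nX + nZ :]))
    return TrajectoryFit(
        age_range=(lo, hi),
        knots=knots,
        coef_fixed=beta[:nX],
        coef_spline=beta[nX : nX + nZ],
        transform=T,
        smoothing_ratio=float(var_resid / max(var_spline, 1e-12)),
        intercept_variance=float(var_subj),
        subject_effects=subject_effects,
        k=k,
    )


def _reml_variances(values, X, Z, subjects):
    """REML variance components via statsmodels MixedLM (single group).

    Returns (spline variance, subject-intercept variance, residual variance).
    Falls back to a near-unpenalized fit when the mixed model is degenerate
    (e.g. noiseless or constant data).
    """
    from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

    n = len(values)
    resid_ols = values - X @ np.linalg.lstsq(X, values, rcond=None)[0]
    scale0 = float(np.var(values)) if np.var(values) > 0 else 1.0
    if float(resid_ols @ resid_ols) / n < 1e-12 * scale0:
        # data is (numerically) linear/constant: no smoothing signal at all
        return 1e-8 * scale0, 0.0, max(float(resid_ols @ resid_ols) / n, 1e-12 * scale0)

    names = ["spline"]
    mats = [[Z]]
    colnames = [[[f"z{j}" for j in range(Z.shape[1])]]]
    if subjects is not None:
        subj_ids = np.unique(subjects)
        Zu = (subjects[:, None] == subj_ids[None, :]).astype(float)
        names.append("subject")
        mats.append([Zu])
        colnames.append([[str(s) for s in subj_ids]])
    vcs = VCSpec(names, colnames, mats)
    groups = np.zeros(n)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(values, X, groups, exog_vc=vcs)
            fit = model.fit(reml=True, method=["lbfgs", "powell"], maxiter=200)
        vc = dict(zip(names, fit.vcomp))
        var_resid = float(fit.scale)
        var_spline = float(max(vc.get("spline", 0.0), 1e-10 * scale0))
        var_subj = float(max(vc.get("subject", 0.0), 0.0))
        if not np.isfinite(var_resid) or var_resid <= 0:
            raise ValueError("bad REML scale")
        return var_spline, var_subj, var_resid
    except Exception as exc:  # pragma: no cover - degenerate numerical cases
        log.warning("REML fit failed (%s); using weak default smoothing", exc)
        return scale0, 0.1 * scale0 if subjects is not None else 0.0, 0.01 * scale0


def fit_gamm(table: FeatureTable, feature: str, k: int = 6, roi: str | None = None) -> TrajectoryFit:
    """Population trajectory with subject random intercepts (REML smoothing)."""
    df = table.select(feature, roi)
    subjects = df["subject"].to_numpy()
    if len(np.unique(subjects)) < 2:
        raise ValueError("GAMM needs >= 2 subjects")
    return _fit_penalized(
        df["age_months"].to_numpy(float), df["value"].to_numpy(float), subjects, k
    )


def fit_gam(atlas_values, k: int = 6) -> TrajectoryFit:
    """Atlas-level trajectory: same spline machinery, no random effects.

    `atlas_values` is a sequence of (age, value) pairs.
    """
    arr = np.asarray(list(atlas_values), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("atlas_values must be (age, value) pairs")
    if len(np.unique(np.round(arr[:, 0], 6))) < 4:
        raise ValueError("GAM needs >= 4 distinct ages")
    return _fit_penalized(arr[:, 0], arr[:, 1], None, k)


# --------------------------------------------------------------------------
# derived quantities
# --------------------------------------------------------------------------


def percent_change(fit: TrajectoryFit, t_start: float, t_end: float) -> float:
    """100 * (f(t_end) - f(t_start)) / f(t_start)."""
    f0 = float(fit.predict(t_start)[0])
    f1 = float(fit.predict(t_end)[0])
    if abs(f0) < 1e-12:
        raise ZeroDivisionError("percentage change undefined: f(t_start) ~ 0")
    return 100.0 * (f1 - f0) / f0


def velocity_and_peak(
    fit: TrajectoryFit, grid_step: float = 0.1
) -> tuple[np.ndarray, np.ndarray, float]:
    """Central-difference velocity curve and the age of maximal growth.

    Returns (grid ages, velocity, peak age); ties resolve to the earliest
    age on the grid.
    """
    lo, hi = fit.age_range
    if hi - lo < 2 * grid_step:
        raise ValueError("fitted range too short for the velocity grid")
    ages = np.arange(lo, hi + grid_step / 2, grid_step)
    f = fit.predict(ages)
    vel = np.gradient(f, grid_step)
    peak = float(ages[int(np.argmax(vel))])
    return ages, vel, peak


def laterality_index(left: float, right: float) -> float:
    """LI = (left - right) / (left + right); antisymmetric under swap."""
    denom = left + right
    if denom == 0:
        raise ZeroDivisionError("laterality index undefined: left + right = 0")
    return (left - right) / denom


def laterality_test(li_values) -> dict:
    """One-sample two-tailed t-test of LI against 0 at the 1% level."""
    x = np.asarray(list(li_values), dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3 for the t-test")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate sample: zero variance")
    t, p = stats.ttest_1samp(x, 0.0)
    return {
        "t": float(t),
        "p": float(p),
        "df": len(x) - 1,
        "significant": bool(p < 0.01),
    }


def roi_summary(values, roi_labels, vertex_areas_) -> dict:
    """Area-weighted mean of a per-vertex feature per ROI label.

    Unlabeled vertices (label '' / None / 0 for integer labels) are
    excluded; empty ROIs are reported as NaN.
    """
    values = np.asarray(values, dtype=float)
    areas = np.asarray(vertex_areas_, dtype=float)
    labels = np.asarray(roi_labels)
    if not (len(values) == len(areas) == len(labels)):
        raise ValueError("values/labels/areas length mismatch")
    unlabeled = {"", None, 0} if labels.dtype.kind in "iu" else {"", None}
    out = {}
    for roi in np.unique(labels):
        if roi in unlabeled:
            continue
        m = (labels == roi) & np.isfinite(values)
        if not m.any() or areas[m].sum() == 0:
            out[roi] = float("nan")
        else:
            out[roi] = float(np.average(values[m], weights=areas[m]))
    return out
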