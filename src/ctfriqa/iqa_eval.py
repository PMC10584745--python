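"""Performance evaluation of objective quality metrics against subjective
scores.

Raw metric scales are generally nonlinearly related to subjective scores, so
before computing linear statistics each metric's scores Y are passed through
a five-parameter logistic (5PL) regression

    Y_L = b1 * (1/2 - 1/(1 + exp(b2 (Y - b3)))) + b4 Y + b5

fitted by least squares against the subjective scores X.  Prediction
accuracy and consistency (PLCC, RMSE) are computed on the regressed Y_L;
prediction monotonicity (SROCC) on the raw Y, since rank correlation is
invariant under the monotone part of the map.  Pairwise method comparisons
use a one-tailed F-test on regression residual variances; subgroup analyses
repeat everything on noise-only / blur-only slices and per anatomical site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

MIN_SERIES = 8


class InsufficientDataError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Five-parameter logistic regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FivePLFit:
    beta: tuple[float, float, float, float, float]
    converged: bool
    residuals: np.ndarray  # Y_L - X per item
    sse: float
    y_l: np.ndarray

    def predict(self, y: np.ndarray) -> np.ndarray:
        return logistic5(y, *self.beta)


def logistic5(y: np.ndarray, b1: float, b2: float, b3: float, b4: float, b5: float) -> np.ndarray:
    z = np.clip(b2 * (np.asarray(y, dtype=float) - b3), -500.0, 500.0)
    return b1 * (0.5 - 1.0 / (1.0 + np.exp(z))) + b4 * y + b5


def _ols_affine(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    vy = y.var()
    if vy == 0:
        return 0.0, float(x.mean())
    slope = float(np.cov(y, x, bias=True)[0, 1] / vy)
    return slope, float(x.mean() - slope * y.mean())


def _logistic_column(y: np.ndarray, b2: float, b3: float) -> np.ndarray:
    z = np.clip(b2 * (y - b3), -500.0, 500.0)
    return 0.5 - 1.0 / (1.0 + np.exp(z))


def _solve_linear(y: np.ndarray, x: np.ndarray, b2: float, b3: float):
    """Exact least squares over the linear parameters (b1, b4, b5) at fixed
    (b2, b3); the 5PL model is linear in them (variable projection)."""
    a = np.column_stack([_logistic_column(y, b2, b3), y, np.ones_like(y)])
    coef, *_ = np.linalg.lstsq(a, x, rcond=None)
    res = a @ coef - x
    return coef, res, float(res @ res)


def fit_5pl(y: np.ndarray, x: np.ndarray, max_nfev: int = 5000) -> FivePLFit:
    """Least-squares 5PL fit of subjective scores X on metric scores Y.

    Deterministic.  The model is linear in (b1, b4, b5), so those are solved
    exactly at every step and the optimizer searches only (b2, b3)
    (variable projection), starting from b2 = 2/SD(Y), b3 = median(Y) with a
    fixed 16-point jittered multi-start on non-convergence.  The exact
    ordinary-least-squares affine solution is always a candidate, so the fit
    never does worse than the best straight line (the family nests affine
    maps at b1 = 0).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("X and Y must be equal-length 1-D arrays")
    if len(y) < MIN_SERIES:
        raise InsufficientDataError(f"need >= {MIN_SERIES} points, got {len(y)}")
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise ValueError("scores must be finite (cap unbounded metrics first)")

    slope, intercept = _ols_affine(y, x)
    degenerate = y.var() == 0
    sd_y = float(y.std()) if not degenerate else 1.0
    med_y = float(np.median(y))

    best: dict = {}

    def consider(b2: float, b3: float, converged: bool) -> float:
        coef, res, sse = _solve_linear(y, x, b2, b3)
        if np.isfinite(sse) and (not best or sse < best["sse"] - 1e-15):
            best.update(
                beta=(float(coef[0]), float(b2), float(b3), float(coef[1]), float(coef[2])),
                sse=sse,
                converged=converged,
            )
        return sse

    # exact affine fallback: b1 = 0 via a zero logistic column contribution
    a_res = y * slope + intercept - x
    best.update(
        beta=(0.0, 2.0 / sd_y, med_y, slope, intercept),
        sse=float(a_res @ a_res),
        converged=True,
    )

    if not degenerate:

        def outer(params):
            _, res, _ = _solve_linear(y, x, params[0], params[1])
            return res

        # coarse deterministic survey of the two nonlinear parameters (the
        # linear ones are solved exactly at each cell), to avoid local optima
        grid_best = (2.0 / sd_y, med_y, np.inf)
        for b2 in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
            for b3 in np.quantile(y, (0.1, 0.3, 0.5, 0.7, 0.9)):
                _, _, sse = _solve_linear(y, x, b2 / sd_y, b3)
                if np.isfinite(sse) and sse < grid_best[2]:
                    grid_best = (b2 / sd_y, float(b3), sse)

        starts = [(2.0 / sd_y, med_y), grid_best[:2]]
        rng = np.random.default_rng(0)  # fixed: the fit is a deterministic map
        for i, start in enumerate(starts):
            try:
                sol = optimize.least_squares(
                    outer, start, method="lm", xtol=1e-10, ftol=1e-10, gtol=1e-10,
                    max_nfev=max_nfev,
                )
            except Exception:
                continue
            consider(sol.x[0], sol.x[1], bool(sol.success))
            if i == 0 and not sol.success:
                # jittered multi-start fallback on non-convergence
                starts += [
                    (2.0 / sd_y * rng.lognormal(0.0, 0.5), med_y + rng.normal(0.0, sd_y))
                    for _ in range(16)
                ]

    y_l = logistic5(y, *best["beta"])
    return FivePLFit(
        beta=best["beta"],
        converged=bool(best["converged"]) and not degenerate,
        residuals=y_l - x,
        sse=float(best["sse"]),
        y_l=y_l,
    )


# ---------------------------------------------------------------------------
# Correlation / error statistics
# ---------------------------------------------------------------------------


def plcc(x: np.ndarray, y_l: np.ndarray) -> float:
    """Pearson linear correlation between subjective and regressed scores."""
    x = np.asarray(x, dtype=float)
    y_l = np.asarray(y_l, dtype=float)
    if len(x) < 3 or len(x) != len(y_l):
        raise ValueError("need equal-length series with n >= 3")
    if x.std() == 0 or y_l.std() == 0:
        raise UndefinedCorrelationError("constant input series")
    return float(stats.pearsonr(x, y_l).statistic)


def srocc(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank-order correlation (tie-corrected rank Pearson).

    Equals the classical ``1 - 6 sum(d_i^2) / (n (n^2 - 1))`` form whenever
    the series are tie-free; capped metrics produce ties, which mid-ranks
    handle correctly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need equal-length series with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("constant input series")
    return float(stats.spearmanr(x, y).statistic)


def srocc_d2(x: np.ndarray, y: np.ndarray) -> float:
    """The rank-difference closed form (valid only for tie-free series)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    d = stats.rankdata(x) - stats.rankdata(y)
    return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1.0)))


def rmse(x: np.ndarray, y_l: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y_l = np.asarray(y_l, dtype=float)
    if x.shape != y_l.shape:
        raise ValueError("series lengths differ")
    return float(np.sqrt(np.mean((y_l - x) ** 2)))


# ---------------------------------------------------------------------------
# Residual F-tests and significance matrices
# ---------------------------------------------------------------------------


def residual_f_test(res_a: np.ndarray, res_b: np.ndarray, alpha: float = 0.05) -> str:
    """One-tailed variance-ratio test on two residual vectors.

    Returns '1' if method a's residual variance is significantly smaller
    (a performs better), '0' if significantly larger, '-' otherwise.  The
    null hypothesis is equal variances; both variances are mean-centered
    sample variances with n-1 degrees of freedom.
    """
    res_a = np.asarray(res_a, dtype=float)
    res_b = np.asarray(res_b, dtype=float)
    n = len(res_a)
    if n != len(res_b) or n < MIN_SERIES:
        raise ValueError(f"need equal-length residual vectors with n >= {MIN_SERIES}")
    va = res_a.var(ddof=1)
    vb = res_b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both residual vectors have zero variance")
    if vb == 0:
        return "0"
    f = va / vb
    dof = n - 1
    if f < stats.f.ppf(alpha, dof, dof):
        return "1"
    if f > stats.f.ppf(1.0 - alpha, dof, dof):
        return "0"
    return "-"


@dataclass(frozen=True)
class SignificanceMatrix:
    """Pairwise codeword table: one symbol in {1, -, 0} per subgroup,
    concatenated in ``subgroup_order``."""

    methods: tuple[str, ...]
    subgroup_order: tuple[str, ...]
    cells: dict[tuple[str, str], str]
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        data = {
            col: [self.cells[(row, col)] for row in self.methods] for col in self.methods
        }
        return pd.DataFrame(data, index=list(self.methods))


def significance_matrix(
    residuals: dict[str, dict[str, np.ndarray]],
    subgroup_order: tuple[str, ...],
    alpha: float = 0.05,
) -> SignificanceMatrix:
    """Build the codeword matrix from per-method, per-subgroup residuals.

    ``residuals[method][subgroup]`` is the residual vector of that method's
    5PL fit on that subgroup.  The diagonal is all '-' and off-diagonal
    symbols are antisymmetric (1 <-> 0) per position by construction of the
    variance-ratio test.
    """
    methods = tuple(residuals.keys())
    cells: dict[tuple[str, str], str] = {}
    for a in methods:
        for b in methods:
            if a == b:
                cells[(a, b)] = " ".join("-" for _ in subgroup_order)
                continue
            symbols = []
            for grp in subgroup_order:
                ra = residuals[a].get(grp)
                rb = residuals[b].get(grp)
                if ra is None or rb is None:
                    symbols.append("-")
                else:
                    symbols.append(residual_f_test(ra, rb, alpha))
            cells[(a, b)] = " ".join(symbols)
    return SignificanceMatrix(
        methods=methods, subgroup_order=tuple(subgroup_order), cells=cells, alpha=alpha
    )


# ---------------------------------------------------------------------------
# Study-level evaluation
# ---------------------------------------------------------------------------

DISTORTION_GROUPS = ("noise", "blur")
SITE_GROUPS = ("head", "chest", "abdomen")


def _subgroup_mask(df: pd.DataFrame, group: str) -> pd.Series:
    if group == "all":
        return pd.Series(True, index=df.index)
    if group == "noise":
        return (df["sigma_blur"] == 0) & (df["sigma_noise"] > 0)
    if group == "blur":
        return (df["sigma_noise"] == 0) & (df["sigma_blur"] > 0)
    if group in SITE_GROUPS:
        return df["site"] == group
    raise ValueError(f"unknown subgroup {group!r}")


def evaluate(
    records: pd.DataFrame,
    methods: tuple[str, ...],
    groups: tuple[str, ...] = ("all", "noise", "blur", "head", "chest", "abdomen"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, SignificanceMatrix]]:
    """Full evaluation harness over a study record table.

    ``records`` needs columns ``X``, ``sigma_noise``, ``sigma_blur``,
    ``site`` and one column per metric.  Each (method, subgroup) series gets
    its own 5PL refit; subgroups smaller than the regression minimum are
    skipped with a warning row.  Returns the per-group summary table and the
    codeword matrices (one over distortion subgroups, one over sites).
    """
    rows = []
    residuals: dict[str, dict[str, np.ndarray]] = {m: {} for m in methods}
    for group in groups:
        mask = _subgroup_mask(records, group)
        sub = records[mask]
        for method in methods:
            if len(sub) < MIN_SERIES:
                rows.append(
                    {"group": group, "method": method, "n": len(sub), "status": "skipped"}
                )
                continue
            x = sub["X"].to_numpy(dtype=float)
            y = sub[method].to_numpy(dtype=float)
            fit = fit_5pl(y, x)
            residuals[method][group] = fit.residuals
            rows.append(
                {
                    "group": group,
                    "method": method,
                    "n": len(sub),
                    "status": "ok" if fit.converged else "degenerate",
                    "plcc": plcc(x, fit.y_l) if fit.y_l.std() > 0 else np.nan,
                    "srocc": srocc(x, y) if y.std() > 0 else np.nan,
                    "rmse": rmse(x, fit.y_l),
                }
            )
    summary = pd.DataFrame(rows)
    matrices = {
        "distortion": significance_matrix(
            {m: residuals[m] for m in methods}, DISTORTION_GROUPS, alpha
        ),
        "site": significance_matrix({m: residuals[m] for m in methods}, SITE_GROUPS, alpha),
        "all": significance_matrix({m: residuals[m] for m in methods}, ("all",), alpha),
    }
    return summary, matrices
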