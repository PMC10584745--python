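"""Double-stimulus continuous quality scale scoring and inter-rater agreement.

In a double-stimulus session each observer marks both the hidden reference
and the distorted image on a continuous 0-100 scale.  The DSCQS score of a
pair is the mean (over observers) of the reference-minus-distorted mark
difference; the subjective score is ``X = 100 - DSCQS`` so that higher means
better quality.  Agreement across observers is quantified with ICC(2,1):
two-way random effects, absolute agreement, single measure, with the
F-based 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DSCQSRecord:
    pair_id: str
    dscqs_score: float
    subjective_score: float  # exactly 100 - dscqs_score
    n_observers: int
    differences: tuple[float, ...]  # per-observer mark_ref - mark_dist


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    var_items: float
    var_observers: float
    var_residual: float


class IncompleteSheetError(ValueError):
    """Mark sheet has missing (pair, observer) cells."""


def _check_complete(sheet: pd.DataFrame) -> None:
    counts = sheet.groupby("pair_id")["observer_id"].nunique()
    n_obs = sheet["observer_id"].nunique()
    bad = counts[counts != n_obs]
    if len(bad) or sheet[["mark_ref", "mark_dist"]].isna().any().any():
        raise IncompleteSheetError(f"incomplete mark sheet for pairs: {list(bad.index)[:10]}")


def dscqs_scores(sheet: pd.DataFrame) -> list[DSCQSRecord]:
    """Collapse a long-format mark sheet into per-pair DSCQS records.

    The subjective score is not clipped: panels that rate a distorted image
    above the hidden reference legitimately produce X > 100.
    """
    _check_complete(sheet)
    records = []
    for pair_id, grp in sheet.groupby("pair_id", sort=False):
        diffs = (grp["mark_ref"] - grp["mark_dist"]).to_numpy(dtype=float)
        d = float(diffs.mean())
        records.append(
            DSCQSRecord(
                pair_id=str(pair_id),
                dscqs_score=d,
                subjective_score=100.0 - d,
                n_observers=len(diffs),
                differences=tuple(diffs),
            )
        )
    return records


def subjective_table(sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-pair subjective-score table (keeps distortion columns if present)."""
    recs = dscqs_scores(sheet)
    df = pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in recs],
            "X": [r.subjective_score for r in recs],
            "dscqs": [r.dscqs_score for r in recs],
            "n_observers": [r.n_observers for r in recs],
        }
    )
    extra = [c for c in ("sigma_noise", "sigma_blur", "site") if c in sheet.columns]
    if extra:
        meta = sheet.groupby("pair_id", sort=False)[extra].first().reset_index()
        df = df.merge(meta, on="pair_id", how="left")
    return df


def ratings_matrix(sheet: pd.DataFrame, kind: str = "difference") -> np.ndarray:
    """Items x observers matrix for agreement analysis.

    ``difference`` (default): per-observer subjective difference scores,
    ``100 - (mark_ref - mark_dist)`` — agreement on perceived quality
    difference.  ``raw``: the distorted-image marks themselves.
    """
    _check_complete(sheet)
    if kind == "difference":
        values = 100.0 - (sheet["mark_ref"] - sheet["mark_dist"])
    elif kind == "raw":
        values = sheet["mark_dist"]
    else:
        raise ValueError(f"unknown ratings kind {kind!r}")
    wide = sheet.assign(_v=values).pivot(index="pair_id", columns="observer_id", values="_v")
    return wide.to_numpy(dtype=float)


def _anova_mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    """Two-way (items x observers, one observation per cell) mean squares:
    rows (MSR), columns (MSC), residual (MSE)."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2_1(ratings: np.ndarray, confidence: float = 0.95) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` with the
    McGraw-Wong F-based confidence interval.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ratings must be an items x observers matrix, >= 2 each")
    if np.isnan(m).any():
        raise ValueError("ratings matrix contains missing values")
    n, k = m.shape
    msr, msc, mse = _anova_mean_squares(m)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate ratings matrix: zero total variance")
    icc = (msr - mse) / denom

    # variance components (method-of-moments)
    var_items = max((msr - mse) / k, 0.0)
    var_obs = max((msc - mse) / n, 0.0)

    alpha = 1.0 - confidence
    # Satterthwaite df for the absolute-agreement interval
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        ci_low = ci_high = 1.0
    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return IccResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        var_items=float(var_items),
        var_observers=float(var_obs),
        var_residual=float(mse),
    )


def icc_consistency(ratings: np.ndarray) -> float:
    """ICC(3,1) (consistency, single measure); always >= ICC(2,1) on the same
    matrix since absolute agreement additionally penalizes observer offsets."""
    m = np.asarray(ratings, dtype=float)
    n, k = m.shape
    msr, _msc, mse = _anova_mean_squares(m)
    return float((msr - mse) / (msr + (k - 1) * mse))
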