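"""Fisher Discriminant Analysis, PLS / kernel-PLS severity regression,
and seafood-intake correlations.

FDA finds the linear combination of the analyte panel that maximizes the
between-class to within-class scatter ratio; for two classes the
direction is ``w ∝ (S_W + ridge·I)^{-1} (m_case − m_control)`` with
``S_W`` the pooled within-class scatter.  Inputs are standardized first
because percentages and dimensionless ratios live on very different
scales; standardization leaves the score C-statistic unchanged in exact
arithmetic while conditioning the scatter inversion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ANALYTES, CohortTable
from .density import RocSummary, c_statistic

__all__ = ["FdaModel", "PlsModel", "fda_fit", "pls_regress", "seafood_correlation"]

log = logging.getLogger(__name__)


def _design(table: CohortTable, variables) -> tuple[np.ndarray, np.ndarray, int]:
    """Complete-case design matrix and binary class labels (1 = ASD)."""
    rows, labels = [], []
    dropped = 0
    for r in table.records:
        vals = [r.get(v) for v in variables]
        if not all(np.isfinite(vals)):
            dropped += 1
            continue
        rows.append(vals)
        labels.append(1 if r.cohort == "ASD" else 0)
    if dropped:
        warnings.warn(f"dropped {dropped} record(s) with missing values", stacklevel=3)
    return np.asarray(rows, dtype=float), np.asarray(labels), dropped


@dataclass
class FdaModel:
    """Fitted two-class Fisher discriminant.

    ``weights`` is the unit-norm discriminant direction in the
    standardized variable space; ``scores_*`` are the projections of each
    cohort onto it; ``score_c_statistic`` is the PDF-based C-statistic of
    the score distributions.
    """

    variables: tuple[str, ...]
    weights: np.ndarray
    ridge: float
    scores_asd: np.ndarray
    scores_neu: np.ndarray
    score_c_statistic: RocSummary
    center: np.ndarray
    scale: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project new rows (original units, ``variables`` order)."""
        return ((np.atleast_2d(x) - self.center) / self.scale) @ self.weights


def fda_fit(
    table: CohortTable,
    variables=ANALYTES,
    ridge: float = 1e-8,
    standardize: bool = True,
) -> FdaModel:
    """Fit FDA on ``variables`` (default: the full 15-analyte panel).

    Records missing any variable are dropped with a warning; each cohort
    must retain at least two records.  A singular within-class scatter is
    an error when ``ridge`` is zero.
    """
    variables = tuple(variables)
    x, y, _ = _design(table, variables)
    n_asd, n_neu = int((y == 1).sum()), int((y == 0).sum())
    if n_asd < 2 or n_neu < 2:
        raise ValueError(
            f"need >= 2 complete records per cohort, got ASD={n_asd}, NEU={n_neu}"
        )
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1) if standardize else np.ones(x.shape[1])
    if np.any(scale == 0):
        zero = [v for v, s in zip(variables, scale) if s == 0]
        raise ValueError(f"constant variable(s): {zero}")
    xs = (x - center) / scale

    m_asd = xs[y == 1].mean(axis=0)
    m_neu = xs[y == 0].mean(axis=0)
    sw = np.zeros((xs.shape[1], xs.shape[1]))
    for cls, m in ((1, m_asd), (0, m_neu)):
        d = xs[y == cls] - m
        sw += d.T @ d
    a = sw + ridge * np.eye(sw.shape[0])
    try:
        w = np.linalg.solve(a, m_asd - m_neu)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "within-class scatter is singular; pass a positive ridge"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise ValueError("within-class scatter is singular; pass a positive ridge")
    w = w / np.linalg.norm(w)
    scores = xs @ w
    roc = c_statistic(scores[y == 1], scores[y == 0], method="pdf_integral")
    return FdaModel(
        variables=variables,
        weights=w,
        ridge=ridge,
        scores_asd=scores[y == 1],
        scores_neu=scores[y == 0],
        score_c_statistic=roc,
        center=center,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# PLS severity regression
# ---------------------------------------------------------------------------


@dataclass
class PlsModel:
    """PLS1 (or kernel-PLS1) regression of a severity score on analytes."""

    n_components: int
    kernel: str
    gamma: float | None
    target_label: str
    r_squared: float
    r_squared_loo: float | None
    fitted: np.ndarray
    y: np.ndarray


def _nipals_pls1_fitted(x: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Fitted values of NIPALS PLS1 on centered data."""
    xc = x.copy()
    yc = y.copy()
    yhat = np.zeros_like(y)
    for _ in range(n_components):
        w = xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = xc @ w
        tt = t @ t
        if tt < 1e-14:
            break
        p = xc.T @ t / tt
        q = yc @ t / tt
        yhat += q * t
        xc -= np.outer(t, p)
        yc = yc - q * t
    return yhat


def _kernel_pls1_fitted(k: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Fitted values of kernel PLS1 on a centered Gram matrix."""
    kc = k.copy()
    yc = y.copy()
    yhat = np.zeros_like(y)
    for _ in range(n_components):
        t = kc @ yc
        nt = np.linalg.norm(t)
        if nt < 1e-12:
            break
        t /= nt
        q = yc @ t
        yhat += q * t
        proj = np.eye(len(y)) - np.outer(t, t)
        kc = proj @ kc @ proj
        yc = yc - q * t
    return yhat


def _center_gram(k: np.ndarray) -> np.ndarray:
    n = k.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ k @ j


def _rbf_gram(x: np.ndarray, gamma: float) -> np.ndarray:
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * x @ x.T
    return np.exp(-gamma * np.maximum(d2, 0))


def median_heuristic_gamma(x: np.ndarray) -> float:
    """1 / median squared pairwise distance (RBF bandwidth default)."""
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * x @ x.T
    upper = d2[np.triu_indices_from(d2, k=1)]
    med = float(np.median(upper))
    if med <= 0:
        raise ValueError("degenerate pairwise distances; set gamma explicitly")
    return 1.0 / med


def pls_regress(
    table: CohortTable,
    x_variables,
    y_label: str,
    n_components: int = 2,
    kernel: str = "linear",
    gamma: float | None = None,
    loo: bool = False,
) -> PlsModel:
    """Regress one severity instrument on the analyte panel.

    ``kernel="linear"`` uses NIPALS PLS1; ``kernel="rbf"`` uses kernel
    PLS1 on a centered RBF Gram matrix (``gamma`` defaults to the median
    heuristic).  Reports in-sample R² and, with ``loo=True``,
    leave-one-out R² (which can be negative).
    """
    x_variables = tuple(x_variables)
    rows, ys = [], []
    for r in table.records:
        yv = r.severity_scores.get(y_label)
        vals = [r.get(v) for v in x_variables]
        if yv is None or not np.isfinite(yv) or not all(np.isfinite(vals)):
            continue
        rows.append(vals)
        ys.append(yv)
    x = np.asarray(rows, dtype=float)
    y = np.asarray(ys, dtype=float)
    if y.size < 10:
        raise ValueError(f"need >= 10 records with {y_label!r}, got {y.size}")
    if n_components > min(x.shape[0] - 1, x.shape[1] if kernel == "linear" else x.shape[0] - 1):
        raise ValueError("n_components exceeds the rank of the centered design")
    if kernel not in ("linear", "rbf"):
        raise ValueError(f"unknown kernel {kernel!r}")

    def fit_predict(x_tr, y_tr, x_te):
        xm, ym = x_tr.mean(axis=0), y_tr.mean()
        if kernel == "linear":
            yh = _nipals_pls1_fitted(x_tr - xm, y_tr - ym, n_components)
            # refit coefficients for out-of-sample prediction
            beta = np.linalg.lstsq(x_tr - xm, yh, rcond=None)[0]
            return (x_te - xm) @ beta + ym
        g = gamma if gamma is not None else median_heuristic_gamma(x_tr)
        k_tr = _center_gram(_rbf_gram(x_tr, g))
        yh = _kernel_pls1_fitted(k_tr, y_tr - ym, n_components)
        alpha = np.linalg.lstsq(k_tr, yh, rcond=None)[0]
        sq_tr = np.sum(x_tr**2, axis=1)
        sq_te = np.sum(x_te**2, axis=1)
        k_te = np.exp(-g * np.maximum(sq_te[:, None] + sq_tr[None, :] - 2 * x_te @ x_tr.T, 0))
        # center the test Gram rows against the training distribution
        k_full = _rbf_gram(x_tr, g)
        ones = np.ones((len(x_te), len(x_tr))) / len(x_tr)
        j = np.eye(len(x_tr)) - np.ones((len(x_tr), len(x_tr))) / len(x_tr)
        k_te_c = (k_te - ones @ k_full) @ j
        return k_te_c @ alpha + ym

    xm, ym = x.mean(axis=0), y.mean()
    if kernel == "linear":
        yhat = _nipals_pls1_fitted(x - xm, y - ym, n_components) + ym
        g_used = None
    else:
        g_used = gamma if gamma is not None else median_heuristic_gamma(x)
        k = _center_gram(_rbf_gram(x, g_used))
        yhat = _kernel_pls1_fitted(k, y - ym, n_components) + ym
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0

    r2_loo = None
    if loo:
        preds = np.empty_like(y)
        for i in range(y.size):
            mask = np.ones(y.size, dtype=bool)
            mask[i] = False
            preds[i] = fit_predict(x[mask], y[mask], x[i : i + 1])[0]
        r2_loo = 1 - float(np.sum((y - preds) ** 2)) / ss_tot if ss_tot > 0 else 0.0

    return PlsModel(
        n_components=n_components,
        kernel=kernel,
        gamma=g_used,
        target_label=y_label,
        r_squared=r2,
        r_squared_loo=r2_loo,
        fitted=yhat,
        y=y,
    )


# ---------------------------------------------------------------------------
# Seafood correlations
# ---------------------------------------------------------------------------


def seafood_correlation(
    table: CohortTable,
    groups=("ASD", "NEU", "pooled"),
    analytes=ANALYTES,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-analyte correlation with seafood meals per month.

    Pairwise-complete per analyte and group; fewer than 3 complete pairs
    yields a missing value with a warning.  ``method`` is ``"pearson"``
    (default, matching a regression framing) or ``"spearman"``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    out = pd.DataFrame(index=list(analytes), columns=list(groups), dtype=float)
    for group in groups:
        recs = [
            r
            for r in table.records
            if (group == "pooled" or r.cohort == group)
            and r.seafood_meals_per_month is not None
        ]
        seafood = np.array([r.seafood_meals_per_month for r in recs], dtype=float)
        for analyte in analytes:
            vals = np.array([r.get(analyte) for r in recs], dtype=float)
            ok = np.isfinite(vals) & np.isfinite(seafood)
            if ok.sum() < 3:
                warnings.warn(
                    f"{analyte}/{group}: fewer than 3 complete pairs", stacklevel=2
                )
                continue
            if method == "pearson":
                out.loc[analyte, group] = float(stats.pearsonr(vals[ok], seafood[ok])[0])
            else:
                out.loc[analyte, group] = float(stats.spearmanr(vals[ok], seafood[ok])[0])
    return out
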