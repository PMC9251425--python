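"""Discrimination and descriptive comparisons of the diet indices.

AUC of the ROC curve is computed as the tie-corrected rank statistic
(concordant-pair fraction, ties counted half), with variance and paired
model comparison by DeLong's structural-components method.  Risk scores for
the ROC come from the linear predictor of the fully adjusted Cox model
including the index term; labels are event vs no event over follow-up.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError
from .survival import _encode, _exposure_columns, fit_cox


# ---------------------------------------------------------------------------
# AUC / DeLong
# ---------------------------------------------------------------------------
def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong placements: per-positive and per-negative components and AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n          # per positive subject
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per negative subject
    auc = v10.mean()
    return auc, v10, v01


def compute_auc(scores, labels, alpha: float = 0.05) -> dict:
    """AUC with a DeLong (structural-components) confidence interval.

    Returns dict with ``auc``, ``ci_lower``, ``ci_upper``, ``se``,
    ``n_pos``, ``n_neg``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise AlignmentError("scores and labels must have equal length")
    auc, v10, v01 = _structural_components(s, y)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    return {
        "auc": float(auc),
        "se": se,
        "ci_lower": float(np.clip(auc - z * se, 0, 1)),
        "ci_upper": float(np.clip(auc + z * se, 0, 1)),
        "n_pos": m,
        "n_neg": n,
    }


def compare_auc(scores_a, scores_b, labels) -> dict:
    """Paired DeLong test of AUC(a) vs AUC(b) on the same subjects.

    Returns ``auc_a``, ``auc_b``, ``delta``, ``z``, ``p`` (two-sided).
    Identical score vectors give delta 0 and p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (a.shape == b.shape == y.shape):
        raise AlignmentError("paired scores and labels must have equal length")
    auc_a, v10a, v01a = _structural_components(a, y)
    auc_b, v10b, v01b = _structural_components(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 0:
        z_stat, p = 0.0, 1.0
        if delta != 0:  # degenerate but unequal: report certainty
            z_stat, p = np.inf * np.sign(delta), 0.0
    else:
        z_stat = delta / np.sqrt(var)
        p = 2 * stats.norm.sf(abs(z_stat))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b),
            "delta": float(delta), "z": float(z_stat), "p": float(p)}


def model_score_for_roc(df: pd.DataFrame, covariates: list[str],
                        exposure: str = "per_sd") -> pd.Series:
    """Per-subject risk score: linear predictor of the adjusted Cox model
    including the index term (labels are the event indicators)."""
    expo = _exposure_columns(df, exposure)
    fit = fit_cox(df, covariates, expo)
    design = pd.concat([expo.astype(float), _encode(df, covariates)], axis=1)
    design = design.drop(columns=fit.dropped, errors="ignore")
    beta = fit.summary["coef"].reindex(design.columns).fillna(0.0).to_numpy()
    return pd.Series(design.to_numpy() @ beta, index=df.index, name="risk_score")


# ---------------------------------------------------------------------------
# Concordance of the two indices
# ---------------------------------------------------------------------------
def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise AlignmentError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


# ---------------------------------------------------------------------------
# Descriptive baseline table
# ---------------------------------------------------------------------------
def descriptive_table(df: pd.DataFrame, group_col: str,
                      variables: dict[str, str]) -> pd.DataFrame:
    """Between-group baseline comparison (Table-1 style).

    ``variables`` maps column -> kind: ``continuous`` (mean +/- SD, ANOVA),
    ``nonnormal`` (median [IQR], Kruskal-Wallis) or ``categorical``
    (n (%), chi-square).  The grouping variable must be binary; constant
    categorical variables are skipped with a note.
    """
    groups = df[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError("grouping variable must be binary")
    g0, g1 = sorted(groups)
    d0, d1 = df[df[group_col] == g0], df[df[group_col] == g1]
    if d0.empty or d1.empty:
        raise ValueError("empty group")

    rows = []
    for var, kind in variables.items():
        a, b = d0[var].dropna(), d1[var].dropna()
        if kind == "continuous":
            stat, p = stats.f_oneway(a, b)
            rows.append((var, f"{a.mean():.2f} ± {a.std():.2f}",
                         f"{b.mean():.2f} ± {b.std():.2f}", p, "anova"))
        elif kind == "nonnormal":
            stat, p = stats.kruskal(a, b)
            rows.append((var,
                         f"{a.median():.2f} [{a.quantile(.25):.2f}, {a.quantile(.75):.2f}]",
                         f"{b.median():.2f} [{b.quantile(.25):.2f}, {b.quantile(.75):.2f}]",
                         p, "kruskal"))
        elif kind == "categorical":
            tab = pd.crosstab(df[var], df[group_col])
            if tab.shape[0] < 2:
                rows.append((var, _pct(a), _pct(b), np.nan, "skipped: constant"))
                continue
            stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
            rows.append((var, _pct(a), _pct(b), p, "chi2"))
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
    out = pd.DataFrame(rows, columns=["variable", f"group_{g0}", f"group_{g1}",
                                      "p", "test"])
    return out.set_index("variable")


def _pct(series: pd.Series) -> str:
    n = int((series != 0).sum())
    return f"{n} ({100.0 * n / max(len(series), 1):.1f}%)"
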