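"""Per-sex OLS of CoM displacement on gravity level and task; reporting.

The model, fitted separately per sex and response axis, is

    d = b0 + b_g * I(1 g) + b_task * I(dynamic) + eps,

estimated by ordinary least squares with the three start/middle/end window
means per trial pooled as independent observations (matching the printed
degrees of freedom of the original analysis; a cluster-robust standard
error option by participant is available but off by default).  The module
also exposes a Shapiro-Wilk normality screen and a publication-style report
grid (coefficient (SE) with significance stars and fit statistics).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

RESPONSES = ("dY", "dZ")

#: significance-star legend: ordered (threshold, stars); exact p-values are
#: always reported alongside, so the legend is presentation only.
DEFAULT_STARS = ((0.01, "***"), (0.05, "**"))


@dataclass
class RegressionFit:
    response: str
    sex: Optional[str]
    coef: dict[str, float]            # {"g_level", "task", "const"} (cm)
    se: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    n_obs: int
    r2: float
    adj_r2: float
    resid_se: float                   # cm, df = n - p
    f_stat: float
    f_pvalue: float
    dropped_terms: tuple[str, ...] = ()
    robust: bool = False


class SingularDesignError(ValueError):
    pass


def _stars(p: float, legend=DEFAULT_STARS) -> str:
    for thr, s in sorted(legend):
        if p < thr:
            return s
    return ""


def _response_column(df: pd.DataFrame, response: str) -> str:
    for cand in (response, f"{response}_cm"):
        if cand in df.columns:
            return cand
    raise KeyError(f"no column for response {response!r} (tried {response}, {response}_cm)")


def fit_ols(
    rows: pd.DataFrame,
    response: str = "dY",
    sex: Optional[str] = None,
    cluster: Optional[str] = None,
) -> RegressionFit:
    """Closed-form OLS of a displacement response on g-level and task.

    ``rows`` needs columns ``g_level`` and ``task`` (0/1 indicators), the
    response (``dY``/``dZ`` or ``dY_cm``/``dZ_cm``) and, if ``sex`` is given,
    a ``sex`` column to filter on.  A constant indicator column is dropped
    with a warning (and recorded in ``dropped_terms``); a collinear design
    raises :class:`SingularDesignError` naming the columns.  ``cluster``
    switches the standard errors to a CR1 cluster-robust sandwich grouped by
    that column.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    df = rows
    if sex is not None:
        df = df[df["sex"] == sex]
    ycol = _response_column(df, response)
    df = df.loc[np.isfinite(df[ycol].to_numpy(dtype=float))]
    n = len(df)
    if n < 4:
        raise ValueError(f"need >= 4 rows after filtering, got {n}")
    for col in ("g_level", "task"):
        vals = set(pd.unique(df[col]))
        if not vals <= {0, 1}:
            raise ValueError(f"{col} must be a 0/1 indicator, found values {vals}")

    terms = ["const", "g_level", "task"]
    cols = [np.ones(n)]
    dropped: list[str] = []
    for name in ("g_level", "task"):
        v = df[name].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"indicator {name!r} is constant; dropped from the design")
            dropped.append(name)
            terms.remove(name)
        else:
            cols.append(v)
    X = np.column_stack(cols)
    y = df[ycol].to_numpy(dtype=float)

    XtX = X.T @ X
    # guard against exact collinearity of the two indicators
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"singular design: columns {terms[1:]} are collinear after filtering"
        )
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    p = X.shape[1]
    dof = n - p
    rss = float(resid @ resid)
    sigma2 = rss / dof if dof > 0 else float("nan")
    XtX_inv = np.linalg.inv(XtX)

    if cluster is not None:
        groups = df[cluster].to_numpy()
        uniq = pd.unique(groups)
        meat = np.zeros((p, p))
        for g in uniq:
            Xg = X[groups == g]
            ug = resid[groups == g]
            sg = Xg.T @ ug
            meat += np.outer(sg, sg)
        g_n = len(uniq)
        # CR1 small-sample factor
        c = (g_n / (g_n - 1)) * ((n - 1) / dof) if g_n > 1 and dof > 0 else 1.0
        cov = c * XtX_inv @ meat @ XtX_inv
    else:
        cov = sigma2 * XtX_inv
    se = np.sqrt(np.diag(cov))

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)

    ybar = y.mean()
    tss = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else float("nan")
    k = p - 1
    if k > 0 and rss > 0:
        f_stat = (tss - rss) / k / (rss / dof)
        f_p = float(sps.f.sf(f_stat, k, dof))
    else:
        f_stat = float("inf") if k > 0 else float("nan")
        f_p = 0.0 if k > 0 else float("nan")

    def to_map(values) -> dict[str, float]:
        return {t: float(v) for t, v in zip(terms, values)}

    return RegressionFit(
        response=response,
        sex=sex,
        coef=to_map(beta),
        se=to_map(se),
        tvalues=to_map(tvals),
        pvalues=to_map(pvals),
        n_obs=n,
        r2=float(r2),
        adj_r2=float(adj_r2),
        resid_se=float(math.sqrt(sigma2)) if dof > 0 else float("nan"),
        f_stat=float(f_stat),
        f_pvalue=f_p,
        dropped_terms=tuple(dropped),
        robust=cluster is not None,
    )


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value (Royston / AS R94 approximation).

    A screening statistic only; n must be in [3, 5000] and the sample must
    not be constant.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if not np.all(np.isfinite(x)):
        raise ValueError("Shapiro-Wilk requires finite values")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


# -- report grid ------------------------------------------------------------

_GRID_COLS = (("dY", "male"), ("dY", "female"), ("dZ", "male"), ("dZ", "female"))
_COL_TITLES = ("Y axis - M", "Y axis - F", "Z axis - M", "Z axis - F")
_TERM_ROWS = (("g_level", "G-level"), ("task", "Task"), ("const", "Constant"))


def table3_report(
    fits: Iterable[RegressionFit],
    stars: Sequence[tuple[float, str]] = DEFAULT_STARS,
) -> str:
    """Render fits as a publication-style grid.

    One column per (axis, sex) cell; coefficient rows show
    ``value stars (SE)``; missing cells render as NA.  Exact p-values are
    appended below the grid so the star legend can never obscure them.
    """
    by_cell: dict[tuple[str, Optional[str]], RegressionFit] = {}
    for f in fits:
        by_cell[(f.response, f.sex)] = f

    def cell(fit: Optional[RegressionFit], term: str) -> str:
        if fit is None or term not in fit.coef:
            return "NA"
        return (
            f"{fit.coef[term]:.2f}{_stars(fit.pvalues[term], stars)} "
            f"({fit.se[term]:.2f})"
        )

    header = ["Variable", *_COL_TITLES]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join(["---"] * len(header)) + "|"]
    cells = [by_cell.get(c) for c in _GRID_COLS]
    for term, title in _TERM_ROWS:
        lines.append("| " + " | ".join([title, *[cell(f, term) for f in cells]]) + " |")

    def stat_row(title: str, fmt, attr: str) -> str:
        vals = [("NA" if f is None else fmt(getattr(f, attr))) for f in cells]
        return "| " + " | ".join([title, *vals]) + " |"

    lines.append(stat_row("Observations", lambda v: f"{v:d}", "n_obs"))
    lines.append(stat_row("R2", lambda v: f"{v:.2f}", "r2"))
    lines.append(stat_row("Adjusted R2", lambda v: f"{v:.2f}", "adj_r2"))
    lines.append(stat_row("Residual Std. Error", lambda v: f"{v:.2f}", "resid_se"))
    lines.append(stat_row("F Statistic", lambda v: f"{v:.2f}", "f_stat"))
    legend = "; ".join(f"{s} p < {thr:g}" for thr, s in sorted(stars))
    lines.append("")
    lines.append(f"Stars: {legend}. Exact p-values:")
    for (resp, sex), f in sorted(by_cell.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        ps = ", ".join(f"{t}={f.pvalues[t]:.4g}" for t in f.pvalues)
        lines.append(f"  {resp} / {sex}: {ps}")
    return "\n".join(lines)


def parse_table3_report(text: str) -> dict[str, dict[str, dict[str, float]]]:
    """Parse a :func:`table3_report` grid back into numbers.

    Returns ``{column_title: {row_title: {"coef": ..., "se": ...}}}`` for
    coefficient rows and ``{"value": ...}`` for statistic rows.  Used to
    verify render/parse consistency.
    """
    lines = [l for l in text.splitlines() if l.startswith("|")]
    if len(lines) < 3:
        raise ValueError("not a report grid")
    headers = [h.strip() for h in lines[0].strip("|").split("|")][1:]
    out: dict[str, dict[str, dict[str, float]]] = {h: {} for h in headers}
    coef_re = re.compile(r"^(-?\d+(?:\.\d+)?)\**\s*\((-?\d+(?:\.\d+)?)\)$")
    for line in lines[2:]:
        parts = [p.strip() for p in line.strip("|").split("|")]
        row, cells = parts[0], parts[1:]
        for h, c in zip(headers, cells):
            if c == "NA":
                continue
            m = coef_re.match(c)
            if m:
                out[h][row] = {"coef": float(m.group(1)), "se": float(m.group(2))}
            else:
                out[h][row] = {"value": float(c)}
    return out
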