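"""Expression-based survival stratification and MASA gene calling.

For each gene, samples are split into low/high expression groups at the
cutpoint maximizing the absolute standardized two-group log-rank statistic
(maximally selected rank statistics), scanning every midpoint of consecutive
sorted unique expression values whose split keeps at least a minimum
proportion of samples on each side. The gene is survival-associated when the
log-rank p at the selected cutoff is <= 0.05 (the naive p, not a
maxstat-corrected one, which makes the gate anti-conservative by
construction), methylation-affected when its cross-validated R2 exceeds 0.3,
and MASA when both hold. A Pearson chi-square / odds-ratio test summarizes
the association between the two gene properties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

R2_THRESHOLD = 0.3
P_THRESHOLD = 0.05
MIN_EVENTS = 20


@dataclass(frozen=True)
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p: float
    z: float  # signed standardized statistic (O - E) / sqrt(V), group 1


@dataclass(frozen=True)
class MaxstatResult:
    cutoff: float
    z: float  # standardized statistic at the cutoff
    statistic: float  # z**2, chi-square 1 df
    p: float  # naive log-rank p at the selected cutoff


def _risk_tables(time: np.ndarray, event: np.ndarray):
    """At-risk / death indicator matrices over distinct event times."""
    ev = event.astype(bool)
    ts = np.unique(time[ev])
    at_risk = time[None, :] >= ts[:, None]  # (T, n)
    deaths = (time[None, :] == ts[:, None]) & ev[None, :]
    return ts, at_risk, deaths


def _logrank_from_tables(at_risk, deaths, group_matrix):
    """(O - E, V) per group column with the hypergeometric variance."""
    n_t = at_risk.sum(axis=1).astype(float)[:, None]
    d_t = deaths.sum(axis=1).astype(float)[:, None]
    n1 = at_risk.astype(float) @ group_matrix
    d1 = deaths.astype(float) @ group_matrix
    frac = n1 / n_t
    expected = d_t * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d_t * frac * (1 - frac) * (n_t - d_t) / (n_t - 1)
    v = np.where(n_t > 1, v, 0.0)
    return (d1 - expected).sum(axis=0), v.sum(axis=0)


def logrank_test(time, event, group) -> LogrankResult:
    """Two-group log-rank chi-square (1 df) with aggregated risk sets.

    ``group`` is a boolean membership vector; tied event times are handled
    by the standard pooled risk-set formulation. When no variance can be
    accumulated (e.g. one group never overlaps the risk sets) the test is
    uninformative and p = 1 is returned with a warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    g = np.asarray(group, dtype=bool)
    if not g.any() or g.all():
        raise ValueError("both groups must be non-empty")
    ts, at_risk, deaths = _risk_tables(time, event)
    if len(ts) == 0:
        warnings.warn("no events observed; log-rank test is uninformative")
        return LogrankResult(statistic=0.0, p=1.0, z=0.0)
    u, v = _logrank_from_tables(at_risk, deaths, g.astype(float)[:, None])
    if v[0] <= 0:
        warnings.warn("log-rank variance is zero; returning p = 1")
        return LogrankResult(statistic=0.0, p=1.0, z=0.0)
    z = float(u[0] / np.sqrt(v[0]))
    chi2 = z * z
    return LogrankResult(statistic=chi2, p=float(stats.chi2.sf(chi2, 1)), z=z)


def maxstat_cutoff(
    values, time, event, minprop: float = 0.1
) -> MaxstatResult:
    """Exhaustive maximally-selected log-rank scan over expression cutpoints.

    Candidates are midpoints of consecutive sorted unique values whose
    low/high split keeps at least ``minprop`` of samples per side; the
    cutpoint with the maximal |standardized statistic| wins (first such
    cutpoint on ties).
    """
    x = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = len(x)
    if int(event.sum()) < MIN_EVENTS:
        raise ValueError(
            f"need at least {MIN_EVENTS} events for cutpoint selection, "
            f"got {int(event.sum())}"
        )
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValueError("expression is constant; no cutpoint exists")
    cand = (uniq[:-1] + uniq[1:]) / 2.0
    n_low = np.searchsorted(np.sort(x), cand, side="right")
    min_side = int(np.ceil(minprop * n))
    ok = (n_low >= min_side) & (n - n_low >= min_side)
    cand = cand[ok]
    if len(cand) == 0:
        raise ValueError("no admissible cutpoint under the minimum group proportion")

    _, at_risk, deaths = _risk_tables(time, event)
    membership = (x[:, None] <= cand[None, :]).astype(float)  # (n, C)
    u, v = _logrank_from_tables(at_risk, deaths, membership)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(v > 0, u / np.sqrt(v), 0.0)
    i = int(np.argmax(np.abs(z)))
    chi2 = float(z[i] ** 2)
    return MaxstatResult(
        cutoff=float(cand[i]),
        z=float(z[i]),
        statistic=chi2,
        p=float(stats.chi2.sf(chi2, 1)),
    )


def survival_scan(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    minprop: float = 0.1,
) -> pd.DataFrame:
    """Per-gene maxstat cutoff + log-rank p over a clinical table.

    Samples are aligned by intersection; genes for which no cutoff exists
    (constant expression, too few events) are reported with NaN and a
    reason. Adds a Benjamini-Hochberg column for reference; the MASA gate
    uses the raw p values.
    """
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    common = [s for s in expression.columns if s in clin.index]
    clin = clin.loc[common]
    time = clin["time"].to_numpy(dtype=float)
    event = clin["event"].to_numpy()
    rows = []
    for gid, row in expression[common].iterrows():
        try:
            res = maxstat_cutoff(row.to_numpy(dtype=float), time, event, minprop)
            rows.append((gid, res.cutoff, res.z, res.statistic, res.p, ""))
        except ValueError as exc:
            rows.append((gid, np.nan, np.nan, np.nan, np.nan, str(exc)))
    out = pd.DataFrame(
        rows, columns=["gene_id", "cutoff", "z", "statistic", "logrank_p", "note"]
    )
    valid = out["logrank_p"].notna()
    out["logrank_q"] = np.nan
    if valid.any():
        out.loc[valid, "logrank_q"] = multipletests(
            out.loc[valid, "logrank_p"], method="fdr_bh"
        )[1]
    return out


def call_masa(
    fit_metrics: pd.DataFrame,
    scan: pd.DataFrame,
    r2_threshold: float = R2_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Intersect methylation-affected (R2 > 0.3) and survival-associated
    (log-rank p <= 0.05) genes.

    ``fit_metrics`` needs columns gene_id and r2; ``scan`` is the output of
    :func:`survival_scan`. Genes missing from either input are excluded.
    Boundary semantics: strictly greater for R2, inclusive for p.
    """
    merged = fit_metrics[["gene_id", "r2"]].merge(
        scan[["gene_id", "cutoff", "logrank_p", "logrank_q"]], on="gene_id", how="inner"
    )
    merged = merged[merged["logrank_p"].notna()].reset_index(drop=True)
    merged["methylation_affected"] = merged["r2"] > r2_threshold
    merged["survival_associated"] = merged["logrank_p"] <= p_threshold
    merged["masa"] = merged["methylation_affected"] & merged["survival_associated"]
    return merged


def association_test(masa: pd.DataFrame) -> dict:
    """Pearson chi-square and odds ratio for affected x associated genes.

    OR = (a*d)/(b*c) with a = affected & associated; the 95% CI uses the
    Woolf (log-OR) formula. A zero cell triggers the Haldane 0.5 correction
    for the OR/CI only (flagged); the chi-square is always computed on the
    raw table without continuity correction.
    """
    a = int((masa["methylation_affected"] & masa["survival_associated"]).sum())
    b = int((masa["methylation_affected"] & ~masa["survival_associated"]).sum())
    c = int((~masa["methylation_affected"] & masa["survival_associated"]).sum())
    d = int((~masa["methylation_affected"] & ~masa["survival_associated"]).sum())
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("all marginals of the 2x2 table must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    haldane = bool((table == 0).any())
    ta = table + 0.5 if haldane else table
    log_or = np.log(ta[0, 0] * ta[1, 1] / (ta[0, 1] * ta[1, 0]))
    se = np.sqrt((1.0 / ta).sum())
    return {
        "table": [[a, b], [c, d]],
        "chi2": float(chi2),
        "p": float(p),
        "odds_ratio": float(np.exp(log_or)),
        "ci_low": float(np.exp(log_or - 1.96 * se)),
        "ci_high": float(np.exp(log_or + 1.96 * se)),
        "haldane_corrected": haldane,
    }
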