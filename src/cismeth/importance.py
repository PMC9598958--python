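"""Probe-importance scoring and regional aggregation of regulatory effects.

For each gene, the absolute refit coefficients are min-max scaled over all
its cis probes (zeros included in the pool, so the minimum is 0 whenever any
probe was shrunk out), zero-coefficient probes are dropped after scaling,
and the normalized value is rounded to one decimal. A probe is *effective*
when its coefficient is nonzero and *important* when its rounded normalized
coefficient equals 1.0; ties at the per-gene maximum all count as important.

Summaries report, per distance bin / CpG-island relation / gene component
and per coefficient sign, the percentage of important probes among effective
probes, plus a pooled logistic regression contrasting the odds of importance
across CpG-island relations (open sea as the reference level).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .regression import GeneFit

RECORD_COLUMNS = [
    "gene_id",
    "probe_id",
    "raw_coefficient",
    "sign",
    "normalized",
    "effective",
    "important",
]


def _round_half_away(x: np.ndarray, decimals: int = 1) -> np.ndarray:
    scale = 10.0**decimals
    return np.floor(np.abs(x) * scale + 0.5) / scale * np.sign(x)


def normalize_coefficients(
    gene_id: str, probe_ids: Sequence[str], coefficients
) -> pd.DataFrame:
    """Min-max scale |coefficients| within one gene and flag importance.

    Returns one row per effective (nonzero) probe. A gene whose
    coefficients are all zero emits no records. If max == min with nonzero
    coefficients present (e.g. a single nonzero probe) every effective probe
    is normalized to 1.0.
    """
    coefs = np.asarray(coefficients, dtype=float)
    absc = np.abs(coefs)
    lo, hi = absc.min(), absc.max()
    if hi == 0:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    if hi > lo:
        normalized = (absc - lo) / (hi - lo)
    else:
        normalized = np.ones_like(absc)
    rounded = _round_half_away(normalized)
    effective = absc > 0
    out = pd.DataFrame(
        {
            "gene_id": gene_id,
            "probe_id": np.asarray(probe_ids, dtype=object),
            "raw_coefficient": coefs,
            "sign": np.where(coefs < 0, "negative", "positive"),
            "normalized": rounded,
            "effective": effective,
            "important": rounded == 1.0,
        }
    )
    return out[effective].reset_index(drop=True)


def build_importance_table(
    fits: Mapping[str, GeneFit] | Sequence[GeneFit],
    annotations: pd.DataFrame | None = None,
    r2: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Importance records for many genes, joined to probe annotations.

    ``annotations`` is the per-(gene, probe) table from
    :func:`cismeth.annotation.annotate_probes`; when given, the records gain
    signed_distance, cgi_relation and component columns. ``r2`` optionally
    attaches each gene's cross-validated R2 for sensitivity filtering.
    """
    items = fits.values() if isinstance(fits, Mapping) else fits
    frames = [
        normalize_coefficients(f.gene_id, f.probe_ids, f.coefficients) for f in items
    ]
    frames = [f for f in frames if not f.empty]
    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=RECORD_COLUMNS)
    )
    if annotations is not None and not records.empty:
        records = records.merge(
            annotations[
                ["gene_id", "probe_id", "signed_distance", "cgi_relation", "component"]
            ],
            on=["gene_id", "probe_id"],
            how="left",
        )
    if r2 is not None and not records.empty:
        records["r2"] = records["gene_id"].map(r2)
    return records


def distance_profile(
    records: pd.DataFrame,
    bin_width: int = 1000,
    dist_range: tuple[int, int] = (-1_000_000, 1_000_000),
    min_effective: int = 1,
) -> pd.DataFrame:
    """Percent important among effective per (distance bin, sign).

    Bins are half-open [left, left + bin_width). Bins with fewer than
    ``min_effective`` effective probes report a missing percentage (never
    0): a ratio over an empty or nearly empty bin carries no information.
    """
    lo, hi = dist_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    sub = records[
        (records["signed_distance"] >= lo) & (records["signed_distance"] < edges[-1])
    ].copy()
    sub["bin_left"] = (
        ((sub["signed_distance"] - lo) // bin_width) * bin_width + lo
    ).astype(int)
    rows = []
    grouped = sub.groupby(["bin_left", "sign"])
    counts = grouped["important"].agg(n_important="sum", n_effective="size")
    for left in edges[:-1]:
        for sign in ("negative", "positive"):
            if (left, sign) in counts.index:
                n_imp, n_eff = counts.loc[(left, sign)]
            else:
                n_imp, n_eff = 0, 0
            pct = 100.0 * n_imp / n_eff if n_eff >= max(min_effective, 1) else np.nan
            rows.append((int(left), sign, int(n_imp), int(n_eff), pct))
    return pd.DataFrame(
        rows, columns=["bin_left", "sign", "n_important", "n_effective", "percent"]
    )


def region_profile(
    records: pd.DataFrame,
    key: str,
    window: tuple[int, int] | None = None,
    min_r2: float | None = None,
) -> pd.DataFrame:
    """Percent important among effective per category (and sign).

    ``key`` is "cgi_relation" or "component". ``window`` optionally
    restricts to signed distances in [lo, hi]; ``min_r2`` restricts to genes
    with cross-validated R2 above the threshold (requires an r2 column).
    """
    if key not in ("cgi_relation", "component"):
        raise ValueError(f"unknown grouping key: {key}")
    sub = records
    if window is not None:
        lo, hi = window
        sub = sub[(sub["signed_distance"] >= lo) & (sub["signed_distance"] <= hi)]
    if min_r2 is not None:
        sub = sub[sub["r2"] > min_r2]
    rows = []
    for (cat, sign), grp in sub.groupby([key, "sign"]):
        n_eff = len(grp)
        n_imp = int(grp["important"].sum())
        rows.append((cat, sign, n_imp, n_eff, 100.0 * n_imp / n_eff))
    return pd.DataFrame(
        rows, columns=[key, "sign", "n_important", "n_effective", "percent"]
    )


def region_logistic(
    records: pd.DataFrame, reference: str = "open_sea"
) -> pd.DataFrame:
    """Logistic regression of importance on CpG-island relation.

    Outcome: important (1) vs effective-but-not-important (0), pooled over
    genes; predictors are indicator variables for each CGI relation with
    ``reference`` as the baseline (its coefficient is absorbed by the
    intercept and not reported). Perfect separation or non-convergence is
    flagged rather than raised.
    """
    cats = [c for c in records["cgi_relation"].dropna().unique() if c != reference]
    if len(cats) < 1:
        raise ValueError("need at least two CGI-relation categories")
    y = records["important"].astype(float).to_numpy()
    Xd = pd.DataFrame({c: (records["cgi_relation"] == c).astype(float) for c in sorted(cats)})
    X = sm.add_constant(Xd)
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0)
        params, pvals = fit.params, fit.pvalues
        if not fit.mle_retvals.get("converged", True) or np.abs(params).max() > 15:
            separated = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separated = True
        params = pd.Series(np.nan, index=X.columns)
        pvals = pd.Series(np.nan, index=X.columns)
    rows = []
    for c in sorted(cats):
        rows.append(
            (
                c,
                float(params[c]),
                float(pvals[c]),
                int(((records["cgi_relation"] == c) & records["important"]).sum()),
                int((records["cgi_relation"] == c).sum()),
                separated,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["cgi_relation", "coef", "pvalue", "n_important", "n_effective", "separated"],
    )
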