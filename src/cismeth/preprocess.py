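"""Expression normalization, gene/probe filtering and beta-value imputation."""

from __future__ import annotations

from math import ceil

import numpy as np
import pandas as pd


def counts_to_logtpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Raw gene counts (genes x samples) to log2(TPM + 1).

    TPM per sample: (count / gene length) rescaled to sum to 1e6 over genes.
    Raises for negative counts, non-positive or missing lengths, and for an
    all-zero sample (TPM undefined).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be >= 0")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {zero.index.tolist()}; TPM undefined")
    tpm = rate.div(colsum, axis=1) * 1e6
    return np.log2(tpm + 1.0)


def filter_genes(
    expression: pd.DataFrame,
    gene_chrom: pd.Series,
    cis_probe_count: pd.Series,
    gene_type: pd.Series | None = None,
    chrom_blocklist: tuple[str, ...] = ("chrX", "chrY"),
    min_value: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep protein-coding autosomal genes that are expressed and have cis probes.

    A gene is kept when its value is >= ``min_value`` in at least half the
    samples (ceil(n/2) for odd n), its chromosome is not blocklisted, it has
    at least one cis probe, and (when ``gene_type`` is given) it is
    protein-coding. Returns (filtered expression, per-gene report with the
    drop reason).
    """
    n = expression.shape[1]
    need = ceil(n / 2)
    expressed = (expression >= min_value).sum(axis=1) >= need
    chrom = gene_chrom.reindex(expression.index)
    autosomal = ~chrom.isin(chrom_blocklist) & chrom.notna()
    probes = cis_probe_count.reindex(expression.index).fillna(0)
    has_probe = probes > 0
    coding = (
        gene_type.reindex(expression.index) == "protein_coding"
        if gene_type is not None
        else pd.Series(True, index=expression.index)
    )
    keep = expressed & autosomal & has_probe & coding
    reason = np.select(
        [~coding, ~autosomal, ~has_probe, ~expressed],
        ["not_protein_coding", "sex_chromosome", "no_cis_probes", "low_expression"],
        default="",
    )
    report = pd.DataFrame(
        {"gene_id": expression.index, "kept": keep.to_numpy(), "reason": reason}
    )
    return expression.loc[keep], report


def filter_impute_probes(
    beta: pd.DataFrame, max_missing: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop probes missing in more than ``max_missing`` of samples; impute the rest.

    Remaining missing entries are set to the probe's median over available
    samples (mean of the two central values for even counts, the numpy/pandas
    convention). Non-missing entries are never changed.
    """
    frac = beta.isna().mean(axis=1)
    keep = frac <= max_missing
    kept = beta.loc[keep]
    med = kept.median(axis=1, skipna=True)
    imputed = kept.T.fillna(med).T
    report = pd.DataFrame(
        {
            "probe_id": beta.index,
            "missing_fraction": frac.to_numpy(),
            "kept": keep.to_numpy(),
        }
    )
    return imputed, report
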