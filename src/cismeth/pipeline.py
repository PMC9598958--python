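"""Stage orchestration: simulate -> annotate -> preprocess -> fit ->
importance -> survival -> MASA -> window comparison.

Every stage reads and writes plain tab-separated tables under the run
directory, so any stage can be rerun from the cached outputs of the
previous ones and every number in the summary is recomputable from the
emitted intermediates. A manifest records the config, seed, package
versions and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__, io
from .annotation import annotate_probes
from .importance import (
    build_importance_table,
    distance_profile,
    region_logistic,
    region_profile,
)
from .preprocess import filter_genes, filter_impute_probes
from .regression import DEFAULT_ALPHA_GRID, cross_validate
from .simulate import SimulationConfig, simulate_dataset
from .survival import association_test, call_masa, survival_scan

log = logging.getLogger("cismeth")


@dataclass
class RunConfig:
    out_dir: str = "cismeth_run"
    simulation: SimulationConfig | None = None
    # input paths, used when simulation is None
    gtf: str | None = None
    cgi_bed: str | None = None
    probe_manifest: str | None = None
    beta_matrix: str | None = None
    expression_matrix: str | None = None
    clinical: str | None = None
    # analysis parameters
    window_bp: int = 1_000_000
    restricted_window: tuple[int, int] = (-2000, 7000)
    alpha_mode: str = "global"  # "global": fixed alpha; "grid": per-gene search
    alpha: float = 0.1
    n_folds: int = 5
    seed: int = 0
    r2_threshold: float = 0.3
    p_threshold: float = 0.05
    max_missing: float = 0.10
    maxstat_minprop: float = 0.1
    chrom_blocklist: tuple[str, ...] = ("chrX", "chrY")
    bin_width: int = 1000

    def __post_init__(self) -> None:
        if self.alpha_mode not in ("global", "grid"):
            raise ValueError("alpha_mode must be 'global' or 'grid'")
        for name, lo, hi in (
            ("r2_threshold", 0, 1),
            ("p_threshold", 0, 1),
            ("max_missing", 0, 1),
            ("maxstat_minprop", 0, 0.5),
            ("alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo},{hi}], got {v}")

    @property
    def alpha_grid(self) -> tuple[float, ...]:
        return (self.alpha,) if self.alpha_mode == "global" else DEFAULT_ALPHA_GRID

    def data_path(self, name: str) -> str:
        return os.path.join(self.out_dir, "data", name)

    def out_path(self, name: str) -> str:
        return os.path.join(self.out_dir, name)

    def input_files(self) -> dict[str, str]:
        if self.simulation is not None:
            return {
                "gtf": self.data_path("genes.gtf"),
                "cgi_bed": self.data_path("cgi.bed"),
                "probe_manifest": self.data_path("probes.tsv"),
                "beta_matrix": self.data_path("beta.tsv"),
                "expression_matrix": self.data_path("expression.tsv"),
                "clinical": self.data_path("clinical.tsv"),
            }
        paths = {
            "gtf": self.gtf,
            "cgi_bed": self.cgi_bed,
            "probe_manifest": self.probe_manifest,
            "beta_matrix": self.beta_matrix,
            "expression_matrix": self.expression_matrix,
            "clinical": self.clinical,
        }
        missing = [k for k, v in paths.items() if v is None]
        if missing:
            raise ValueError(f"missing input paths: {missing}")
        return paths

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        if self.simulation is not None:
            payload["simulation"] = dataclasses.asdict(self.simulation)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        sim = payload.get("simulation")
        if sim is not None:
            sim = dict(sim)
            if "effect_region" in sim:
                sim["effect_region"] = tuple(sim["effect_region"])
            if "effect_size_range" in sim:
                sim["effect_size_range"] = tuple(sim["effect_size_range"])
            payload["simulation"] = SimulationConfig(**sim)
        for key in ("restricted_window", "chrom_blocklist"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_simulate(cfg: RunConfig) -> None:
    if cfg.simulation is None:
        raise ValueError("stage_simulate requires a simulation config")
    io.ensure_dir(os.path.join(cfg.out_dir, "data"))
    ds = simulate_dataset(cfg.simulation)
    io.write_gtf(ds.genes, cfg.data_path("genes.gtf"))
    io.write_bed(ds.cgis, cfg.data_path("cgi.bed"))
    io.write_table(ds.probes, cfg.data_path("probes.tsv"))
    io.write_matrix(ds.beta, cfg.data_path("beta.tsv"))
    io.write_matrix(ds.expression, cfg.data_path("expression.tsv"))
    io.write_table(ds.clinical, cfg.data_path("clinical.tsv"))
    ds.truth.to_json(cfg.data_path("truth.json"))
    log.info("simulate: %d genes, %d probes, %d samples",
             len(ds.genes), len(ds.probes), ds.config.n_samples)


def stage_annotate(cfg: RunConfig) -> pd.DataFrame:
    paths = cfg.input_files()
    genes = io.read_gtf(paths["gtf"])
    cgis = io.read_bed(paths["cgi_bed"])
    probes = io.read_table(paths["probe_manifest"])
    anno = annotate_probes(
        genes, probes, cgis, cfg.window_bp, chrom_blocklist=cfg.chrom_blocklist
    )
    io.write_table(anno, cfg.out_path("annotated_probes.tsv"))
    log.info("annotate: %d (gene, probe) pairs", len(anno))
    return anno


def stage_preprocess(cfg: RunConfig) -> None:
    paths = cfg.input_files()
    anno = io.read_table(cfg.out_path("annotated_probes.tsv"))
    beta = io.read_matrix(paths["beta_matrix"])
    expr = io.read_matrix(paths["expression_matrix"])
    genes = io.read_gtf(paths["gtf"])
    beta_f, probe_report = filter_impute_probes(beta, cfg.max_missing)

    chrom = pd.Series({g.gene_id: g.chrom for g in genes})
    gtype = pd.Series({g.gene_id: g.gene_type for g in genes})
    kept_probes = set(beta_f.index)
    cis_counts = (
        anno[anno["probe_id"].isin(kept_probes)].groupby("gene_id").size()
    )
    common = [s for s in expr.columns if s in beta_f.columns]
    expr_f, gene_report = filter_genes(
        expr[common], chrom, cis_counts, gtype, cfg.chrom_blocklist
    )
    io.write_matrix(beta_f[common], cfg.out_path("beta_filtered.tsv"))
    io.write_matrix(expr_f, cfg.out_path("expression_filtered.tsv"))
    io.write_table(probe_report, cfg.out_path("probe_filter_report.tsv"))
    io.write_table(gene_report, cfg.out_path("gene_filter_report.tsv"))
    log.info("preprocess: kept %d/%d probes, %d/%d genes",
             beta_f.shape[0], beta.shape[0], expr_f.shape[0], expr.shape[0])


def stage_fit(cfg: RunConfig, window: tuple[int, int] | None = None, tag: str = "full") -> None:
    anno = io.read_table(cfg.out_path("annotated_probes.tsv"))
    beta = io.read_matrix(cfg.out_path("beta_filtered.tsv"))
    expr = io.read_matrix(cfg.out_path("expression_filtered.tsv"))
    if window is not None:
        lo, hi = window
        anno = anno[(anno["signed_distance"] >= lo) & (anno["signed_distance"] <= hi)]
    row_of = {p: i for i, p in enumerate(beta.index)}
    X_all = beta.to_numpy().T
    metric_rows, coef_rows = [], []
    for gid in expr.index:
        sub = anno[anno["gene_id"] == gid]
        pids = [p for p in sub["probe_id"] if p in row_of]
        if not pids:
            log.warning("fit[%s]: gene %s has no probes in window; skipped", tag, gid)
            continue
        X = X_all[:, [row_of[p] for p in pids]]
        y = expr.loc[gid].to_numpy(dtype=float)
        fit = cross_validate(
            X, y, gene_id=gid, probe_ids=pids,
            alpha_grid=cfg.alpha_grid, n_folds=cfg.n_folds, seed=cfg.seed,
        )
        metric_rows.append(
            (gid, fit.spec.alpha, fit.spec.lam, fit.intercept,
             fit.cv.mse, fit.cv.rmse, fit.cv.mae, fit.cv.r2, fit.n, fit.p)
        )
        coef_rows.extend(zip([gid] * fit.p, fit.probe_ids, fit.coefficients))
    metrics = pd.DataFrame(
        metric_rows,
        columns=["gene_id", "alpha", "lambda", "intercept",
                 "mse", "rmse", "mae", "r2", "n", "p"],
    )
    coefs = pd.DataFrame(coef_rows, columns=["gene_id", "probe_id", "coefficient"])
    io.write_table(metrics, cfg.out_path(f"fits_{tag}_metrics.tsv"))
    io.write_table(coefs, cfg.out_path(f"fits_{tag}_coefficients.tsv"))
    log.info("fit[%s]: %d genes, median cv R2 %.3f",
             tag, len(metrics), float(metrics["r2"].median()))


def _load_fit_tables(cfg: RunConfig, tag: str = "full"):
    metrics = io.read_table(cfg.out_path(f"fits_{tag}_metrics.tsv"))
    coefs = io.read_table(cfg.out_path(f"fits_{tag}_coefficients.tsv"))
    return metrics, coefs


def stage_importance(cfg: RunConfig) -> None:
    from .regression import GeneFit, Metrics, PenaltySpec

    metrics, coefs = _load_fit_tables(cfg, "full")
    anno = io.read_table(cfg.out_path("annotated_probes.tsv"))
    r2 = dict(zip(metrics["gene_id"], metrics["r2"]))
    fits = []
    for gid, grp in coefs.groupby("gene_id", sort=True):
        fits.append(
            GeneFit(
                gene_id=gid, probe_ids=grp["probe_id"].tolist(), intercept=0.0,
                coefficients=grp["coefficient"].to_numpy(), cv=None,
                spec=PenaltySpec(0.1, 0.0), n=0, p=len(grp),
            )
        )
    records = build_importance_table(fits, anno, r2=r2)
    io.write_table(records, cfg.out_path("importance_records.tsv"))

    full = distance_profile(records, cfg.bin_width, (-cfg.window_bp, cfg.window_bp))
    zoom = distance_profile(records, cfg.bin_width, (-25_000, 25_000))
    io.write_table(full, cfg.out_path("distance_profile_full.tsv"))
    io.write_table(zoom, cfg.out_path("distance_profile_25kb.tsv"))
    for key in ("cgi_relation", "component"):
        io.write_table(region_profile(records, key), cfg.out_path(f"profile_{key}.tsv"))
        io.write_table(
            region_profile(records, key, window=cfg.restricted_window),
            cfg.out_path(f"profile_{key}_window.tsv"),
        )
    io.write_table(region_logistic(records), cfg.out_path("cgi_logistic.tsv"))
    log.info("importance: %d effective records, %d important",
             len(records), int(records["important"].sum()))


def stage_survival(cfg: RunConfig) -> None:
    paths = cfg.input_files()
    expr = io.read_matrix(cfg.out_path("expression_filtered.tsv"))
    clinical = io.read_table(paths["clinical"])
    scan = survival_scan(expr, clinical, cfg.maxstat_minprop)
    io.write_table(scan, cfg.out_path("survival_scan.tsv"))
    log.info("survival: %d genes scanned, %d failed",
             len(scan), int(scan["logrank_p"].isna().sum()))


def stage_masa(cfg: RunConfig) -> dict:
    metrics, _ = _load_fit_tables(cfg, "full")
    scan = io.read_table(cfg.out_path("survival_scan.tsv"))
    masa = call_masa(metrics, scan, cfg.r2_threshold, cfg.p_threshold)
    io.write_table(masa, cfg.out_path("masa.tsv"))
    assoc = association_test(masa)
    with open(cfg.out_path("association.json"), "w") as fh:
        json.dump(assoc, fh, indent=1)
    log.info("masa: %d/%d genes; OR %.3f",
             int(masa["masa"].sum()), len(masa), assoc["odds_ratio"])
    return assoc


def compare_windows(full: pd.DataFrame, restricted: pd.DataFrame):
    """Pair per-gene metrics of the full and restricted-window fits.

    Returns the merged table and Pearson r (+ p) per metric across genes.
    """
    merged = full.merge(
        restricted, on="gene_id", suffixes=("_full", "_restricted")
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 shared genes to correlate")
    corrs = {}
    for m in ("mse", "rmse", "mae", "r2"):
        r, p = sps.pearsonr(merged[f"{m}_full"], merged[f"{m}_restricted"])
        corrs[m] = {"r": float(r), "p": float(p)}
    return merged, corrs


def stage_compare(cfg: RunConfig) -> dict:
    full, _ = _load_fit_tables(cfg, "full")
    restricted, _ = _load_fit_tables(cfg, "restricted")
    merged, corrs = compare_windows(full, restricted)
    io.write_table(merged, cfg.out_path("window_comparison.tsv"))
    with open(cfg.out_path("window_correlations.json"), "w") as fh:
        json.dump(corrs, fh, indent=1)
    log.info("compare: R2 r=%.3f", corrs["r2"]["r"])
    return corrs


def write_manifest(cfg: RunConfig) -> None:
    import sklearn

    manifest = {
        "cismeth_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
        "seed": cfg.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=str)),
        "input_checksums": {
            k: _sha256(v) for k, v in cfg.input_files().items() if os.path.exists(v)
        },
    }
    with open(cfg.out_path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def write_summary(cfg: RunConfig) -> dict:
    metrics, _ = _load_fit_tables(cfg, "full")
    records = io.read_table(cfg.out_path("importance_records.tsv"))
    masa = io.read_table(cfg.out_path("masa.tsv"))
    with open(cfg.out_path("association.json")) as fh:
        assoc = json.load(fh)
    with open(cfg.out_path("window_correlations.json")) as fh:
        corrs = json.load(fh)
    gene_report = io.read_table(cfg.out_path("gene_filter_report.tsv"))
    probe_report = io.read_table(cfg.out_path("probe_filter_report.tsv"))
    summary = {
        "seed": cfg.seed,
        "genes_input": int(len(gene_report)),
        "genes_kept": int(gene_report["kept"].sum()),
        "probes_input": int(len(probe_report)),
        "probes_kept": int(probe_report["kept"].sum()),
        "genes_fit": int(len(metrics)),
        "median_cv_r2": float(metrics["r2"].median()),
        "genes_r2_gt_threshold": int((metrics["r2"] > cfg.r2_threshold).sum()),
        "effective_records": int(len(records)),
        "important_records": int(records["important"].sum()),
        "masa_genes": int(masa["masa"].sum()),
        "association": assoc,
        "window_correlations": corrs,
    }
    with open(cfg.out_path("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


_STAGES = ("simulate", "annotate", "preprocess", "fit", "fit_restricted",
           "importance", "survival", "masa", "compare")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages in order; returns the summary dict.

    A stage failure aborts with the stage name attached to the exception.
    """
    io.ensure_dir(cfg.out_dir)
    for stage in _STAGES:
        if stage == "simulate" and cfg.simulation is None:
            continue
        try:
            if stage == "simulate":
                stage_simulate(cfg)
            elif stage == "annotate":
                stage_annotate(cfg)
            elif stage == "preprocess":
                stage_preprocess(cfg)
            elif stage == "fit":
                stage_fit(cfg, None, "full")
            elif stage == "fit_restricted":
                stage_fit(cfg, cfg.restricted_window, "restricted")
            elif stage == "importance":
                stage_importance(cfg)
            elif stage == "survival":
                stage_survival(cfg)
            elif stage == "masa":
                stage_masa(cfg)
            elif stage == "compare":
                stage_compare(cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    write_manifest(cfg)
    return write_summary(cfg)
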