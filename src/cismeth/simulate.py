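"""Synthetic genomes, methylation, expression and survival with planted truth.

The generator emulates the statistical structure of a tumour methylation /
expression study: CpG probes scattered around transcription start sites with
density decaying with distance, bimodal beta values in [0,1] with occasional
missingness, expression that is a sparse linear function of a few nearby CpGs
(mostly negative effects concentrated in the promoter-proximal window) plus
Gaussian noise, and survival times whose hazard is tied to the expression of
a subset of the methylation-driven genes.

Every random draw is funnelled through numpy Generators derived from the
single config seed, so a given (config, seed) is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import ceil

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    Transcript,
    cgi_relation,
    gene_component,
    merge_intervals,
    select_tss,
    signed_distance,
)

# per-stage RNG stream tags (combined with the config seed)
_STREAM_GENOME = 11
_STREAM_EFFECTS = 13
_STREAM_METH = 17
_STREAM_SURV = 19

# beta-mixture shape: per-probe mean from a low or high methylation mode,
# per-sample values from Beta(m*kappa, (1-m)*kappa)
_BETA_KAPPA = 8.0
# probe-level jitter (sd) around the shared latent of a planted causal cluster
_CLUSTER_JITTER = 0.005


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe a mid-sized tumour cohort: 300 samples, 200 genes with
    a Poisson(30) probe cloud each (minimum 5), 30% of genes driven by a
    planted CpG cluster in the promoter-proximal window [-2 kb, +7 kb] with
    absolute effect sizes in [1, 3] (80% negative), residual noise sd 0.5 on
    the log2 expression scale, 2% missing beta entries, and survival linked
    to 10% of the causal genes at a hazard ratio of 2 per expression z-score.
    """

    n_samples: int = 300
    n_genes: int = 200
    probes_per_gene: float = 30.0
    window_bp: int = 1_000_000
    chrom_length_bp: int = 30_000_000
    genes_per_chrom: int = 100
    causal_fraction: float = 0.3
    causal_probes_per_gene: int = 2
    effect_region: tuple[int, int] = (-2000, 7000)
    negative_effect_prob: float = 0.8
    effect_size_range: tuple[float, float] = (1.0, 3.0)
    noise_sd: float = 0.5
    missing_rate: float = 0.02
    survival_linked_fraction: float = 0.1
    hazard_ratio: float = 2.0
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "causal_fraction",
            "negative_effect_prob",
            "missing_rate",
            "survival_linked_fraction",
            "censor_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_samples", "probes_per_gene", "causal_probes_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.window_bp > self.chrom_length_bp:
            raise ValueError(
                f"cis window ({self.window_bp} bp) is larger than the simulated "
                f"chromosome ({self.chrom_length_bp} bp); enlarge chrom_length_bp"
            )
        lo, hi = self.effect_region
        if lo >= hi:
            raise ValueError("effect_region must be a non-empty (lo, hi) interval")


@dataclass
class GeneTruth:
    gene_id: str
    tss: int
    strand: str
    causal: bool
    survival_linked: bool
    intercept: float
    causal_probes: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationTruth:
    """Planted ground truth: per-gene effects and per-probe annotations."""

    genes: dict[str, GeneTruth]
    probes: pd.DataFrame  # probe_id, gene_id, signed_distance, cgi_relation, component

    def causal_genes(self) -> list[str]:
        return [g for g, t in self.genes.items() if t.causal]

    def linked_genes(self) -> list[str]:
        return [g for g, t in self.genes.items() if t.survival_linked]

    def to_json(self, path) -> None:
        payload = {
            "genes": {g: asdict(t) for g, t in self.genes.items()},
            "probes": self.probes.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = {g: GeneTruth(**t) for g, t in payload["genes"].items()}
        return cls(genes=genes, probes=pd.DataFrame(payload["probes"]))


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    cgis: pd.DataFrame
    probes: pd.DataFrame
    truth: SimulationTruth
    beta: pd.DataFrame
    expression: pd.DataFrame
    clinical: pd.DataFrame


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _build_gene(rng: np.random.Generator, gene_id: str, chrom: str, start: int) -> GeneModel:
    n_ex = int(rng.integers(3, 7))
    ex_lens = rng.integers(150, 1200, n_ex)
    in_lens = rng.integers(400, 3500, n_ex - 1)
    exons = []
    cursor = start
    for i in range(n_ex):
        exons.append((cursor, cursor + int(ex_lens[i])))
        cursor = exons[-1][1] + (int(in_lens[i]) if i < n_ex - 1 else 0)
    strand = "+" if rng.random() < 0.5 else "-"
    transcripts = [Transcript(f"{gene_id}.t1", tuple(exons))]
    if rng.random() < 0.5 and n_ex > 2:
        # shorter isoform missing the strand-5'-most exon; never wins TSS choice
        short = exons[1:] if strand == "+" else exons[:-1]
        transcripts.append(Transcript(f"{gene_id}.t2", tuple(short)))
    return GeneModel(gene_id, chrom, strand, tuple(transcripts))


def simulate_genome(
    config: SimulationConfig, with_truth: bool = False
):
    """Simulate gene models, CpG islands and the probe manifest.

    Probe positions are drawn around each gene's TSS from a 70/30 mixture of
    a Laplace (scale 30 kb) and a uniform over the full cis window, so probe
    density decays with distance but the far window is still populated.
    Planted causal probes (see :class:`SimulationConfig`) are part of the
    emitted manifest. With ``with_truth=True`` also returns the
    :class:`SimulationTruth`.
    """
    rng = _rng(config, _STREAM_GENOME)
    n_chrom = max(1, ceil(config.n_genes / config.genes_per_chrom))
    margin = min(100_000, config.chrom_length_bp // 10)

    genes: list[GeneModel] = []
    cgi_raw: dict[str, list[tuple[int, int]]] = {}
    probe_rows: list[tuple[str, str, int]] = []
    truth_probe_rows: list[tuple[str, str, int]] = []  # probe_id, gene_id, signed dist

    for i in range(config.n_genes):
        chrom_idx = i // config.genes_per_chrom
        chrom = f"chr{chrom_idx + 1}"
        on_chrom = min(
            config.genes_per_chrom,
            config.n_genes - chrom_idx * config.genes_per_chrom,
        )
        step = max(1, (config.chrom_length_bp - 2 * margin) // max(on_chrom, 1))
        slot = i % config.genes_per_chrom
        start = margin + slot * step + int(rng.integers(0, max(step // 4, 1)))
        gene = _build_gene(rng, f"G{i:04d}", chrom, start)
        genes.append(gene)

    pid = 0
    for gene in genes:
        tss, _ = select_tss(gene)
        # CpG islands: often one overlapping the TSS, sometimes a distal one
        islands = cgi_raw.setdefault(gene.chrom, [])
        if rng.random() < 0.6:
            s = max(0, tss - int(rng.integers(200, 1200)))
            islands.append((s, tss + int(rng.integers(200, 1500))))
        if rng.random() < 0.4:
            off = int(rng.integers(4000, 60000)) * (1 if rng.random() < 0.5 else -1)
            c = max(0, tss + off)
            islands.append((c, c + int(rng.integers(300, 1500))))

        m = max(5, int(rng.poisson(config.probes_per_gene)))
        lap = rng.random(m) < 0.7
        d = np.where(
            lap,
            rng.laplace(0.0, 30_000.0, m),
            rng.uniform(-config.window_bp, config.window_bp, m),
        )
        d = np.clip(np.rint(d).astype(np.int64), -config.window_bp, config.window_bp)
        pos = tss + d if gene.strand == "+" else tss - d
        pos = np.clip(pos, 0, config.chrom_length_bp - 1)
        for p in pos:
            probe_rows.append((f"cg{pid:08d}", gene.chrom, int(p)))
            truth_probe_rows.append((f"cg{pid:08d}", gene.gene_id, int(p)))
            pid += 1

    # planted causal clusters
    erng = _rng(config, _STREAM_EFFECTS)
    gene_ids = [g.gene_id for g in genes]
    n_causal = int(round(config.causal_fraction * config.n_genes))
    causal_ids = set(
        erng.choice(gene_ids, size=n_causal, replace=False) if n_causal else []
    )
    n_linked = int(round(config.survival_linked_fraction * n_causal))
    linked_ids = set(
        erng.choice(sorted(causal_ids), size=n_linked, replace=False) if n_linked else []
    )

    gene_truth: dict[str, GeneTruth] = {}
    lo, hi = config.effect_region
    pad = min(400, (hi - lo) // 4)
    for gene in genes:
        tss, _ = select_tss(gene)
        t = GeneTruth(
            gene_id=gene.gene_id,
            tss=int(tss),
            strand=gene.strand,
            causal=gene.gene_id in causal_ids,
            survival_linked=gene.gene_id in linked_ids,
            intercept=float(erng.uniform(5.0, 9.0)),
        )
        if t.causal:
            center = int(erng.integers(lo + pad, hi - pad))
            mag = float(erng.uniform(*config.effect_size_range))
            sign = -1.0 if erng.random() < config.negative_effect_prob else 1.0
            for _ in range(config.causal_probes_per_gene):
                dd = int(np.clip(center + erng.integers(-300, 301), lo, hi))
                p = tss + dd if gene.strand == "+" else tss - dd
                p = int(np.clip(p, 0, config.chrom_length_bp - 1))
                probe_id = f"cg{pid:08d}"
                pid += 1
                probe_rows.append((probe_id, gene.chrom, p))
                truth_probe_rows.append((probe_id, gene.gene_id, p))
                t.causal_probes[probe_id] = sign * mag
        gene_truth[gene.gene_id] = t

    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"])
    cgis = pd.DataFrame(
        [
            (chrom, s, e)
            for chrom, ivals in sorted(cgi_raw.items())
            for s, e in merge_intervals(ivals)
        ],
        columns=["chrom", "start", "end"],
    )

    if not with_truth:
        return genes, cgis, probes

    gene_by_id = {g.gene_id: g for g in genes}
    islands_by_chrom = {
        chrom: list(zip(grp["start"], grp["end"])) for chrom, grp in cgis.groupby("chrom")
    }
    tp = pd.DataFrame(truth_probe_rows, columns=["probe_id", "gene_id", "pos"])
    dists = np.empty(len(tp), dtype=np.int64)
    rels = np.empty(len(tp), dtype=object)
    comps = np.empty(len(tp), dtype=object)
    for gid, grp in tp.groupby("gene_id"):
        gene = gene_by_id[gid]
        tss, tr = select_tss(gene)
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        dists[idx] = signed_distance(pos, tss, gene.strand)
        rels[idx] = cgi_relation(pos, islands_by_chrom.get(gene.chrom, []))
        comps[idx] = gene_component(pos, gene, tr)
    tp["signed_distance"] = dists
    tp["cgi_relation"] = rels
    tp["component"] = comps
    truth = SimulationTruth(genes=gene_truth, probes=tp)
    return genes, cgis, probes, truth


def simulate_methylation_expression(
    genes: list[GeneModel],
    probes: pd.DataFrame,
    truth: SimulationTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw beta values and expression given a simulated genome.

    Non-causal probes get an independent bimodal beta distribution (per-probe
    mean from a low or high methylation mode). The causal probes of a gene
    share a per-sample latent methylation level with small probe-level jitter,
    mimicking a co-methylated regulatory element; expression is intercept +
    sum(effect * beta) + N(0, noise_sd). Missing entries are inserted at
    ``missing_rate`` after expression is computed.
    """
    rng = _rng(config, _STREAM_METH)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    n = config.n_samples

    probe_ids = probes["probe_id"].tolist()
    beta = np.empty((len(probe_ids), n))
    row_of = {p: i for i, p in enumerate(probe_ids)}

    causal_of_probe: dict[str, str] = {}
    for gid, t in truth.genes.items():
        for p in t.causal_probes:
            causal_of_probe[p] = gid

    # independent probes first, in manifest order
    for p in probe_ids:
        i = row_of[p]
        if p in causal_of_probe:
            continue
        mode_low = rng.random() < 0.5
        m = rng.beta(2, 6) if mode_low else rng.beta(6, 2)
        beta[i] = rng.beta(m * _BETA_KAPPA, (1 - m) * _BETA_KAPPA, n)

    # then causal clusters, one latent per gene
    for gid in sorted(truth.genes):
        t = truth.genes[gid]
        if not t.causal_probes:
            continue
        m = rng.uniform(0.25, 0.75)
        latent = rng.beta(m * _BETA_KAPPA, (1 - m) * _BETA_KAPPA, n)
        for p in sorted(t.causal_probes):
            beta[row_of[p]] = np.clip(
                latent + rng.normal(0.0, _CLUSTER_JITTER, n), 0.0, 1.0
            )

    expr = np.empty((len(genes), n))
    gene_ids = [g.gene_id for g in genes]
    for gi, gid in enumerate(gene_ids):
        t = truth.genes[gid]
        y = np.full(n, t.intercept)
        for p, eff in t.causal_probes.items():
            y = y + eff * beta[row_of[p]]
        y = y + rng.normal(0.0, config.noise_sd, n)
        expr[gi] = y

    if config.missing_rate > 0:
        mask = rng.random(beta.shape) < config.missing_rate
        beta = np.where(mask, np.nan, beta)

    beta_df = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    expr_df = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    return beta_df, expr_df


def simulate_survival(
    expression: pd.DataFrame,
    truth: SimulationTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Exponential survival times with hazard tied to linked-gene expression.

    The per-sample log hazard is log(hazard_ratio) times the sum of z-scored
    expression over survival-linked genes (baseline median 24 time units).
    With probability ``censor_rate`` a sample is censored uniformly before
    its event time. Columns: sample, time, event.
    """
    rng = _rng(config, _STREAM_SURV)
    samples = list(expression.columns)
    n = len(samples)
    linked = [g for g in truth.linked_genes() if g in expression.index]
    risk = np.zeros(n)
    if linked and config.hazard_ratio != 1.0:
        sub = expression.loc[linked].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        risk = np.log(config.hazard_ratio) * z.sum(axis=0)
    lam0 = np.log(2.0) / 24.0
    t_event = rng.exponential(1.0 / (lam0 * np.exp(risk)))
    censored = rng.random(n) < config.censor_rate
    frac = rng.random(n)
    time = np.where(censored, t_event * frac, t_event)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame(
        {"sample": samples, "time": time, "event": (~censored).astype(int)}
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all generator stages and bundle the result."""
    genes, cgis, probes, truth = simulate_genome(config, with_truth=True)
    beta, expr = simulate_methylation_expression(genes, probes, truth, config)
    clinical = simulate_survival(expr, truth, config)
    return SyntheticDataset(
        config=config,
        genes=genes,
        cgis=cgis,
        probes=probes,
        truth=truth,
        beta=beta,
        expression=expr,
        clinical=clinical,
    )
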