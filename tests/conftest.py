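import numpy as np
import pandas as pd
import pytest

from cismeth import (
    SimulationConfig,
    annotate_probes,
    build_importance_table,
    call_masa,
    cross_validate,
    filter_genes,
    filter_impute_probes,
    simulate_dataset,
    survival_scan,
)

# Frozen seed of the reference synthetic study used by the recovery tests.
STUDY_SEED = 11


class Study:
    """The default-scale synthetic study, fit once and shared by tests."""

    def __init__(self, seed: int = STUDY_SEED):
        self.config = SimulationConfig(seed=seed)
        self.dataset = simulate_dataset(self.config)
        ds = self.dataset
        self.annotations = annotate_probes(
            ds.genes, ds.probes, ds.cgis, self.config.window_bp
        )
        self.beta, self.probe_report = filter_impute_probes(ds.beta)
        chrom = pd.Series({g.gene_id: g.chrom for g in ds.genes})
        counts = self.annotations.groupby("gene_id").size()
        self.expression, self.gene_report = filter_genes(
            ds.expression, chrom, counts
        )
        self._row_of = {p: i for i, p in enumerate(self.beta.index)}
        self._X = self.beta.to_numpy().T

        self.fits = {}
        self.fits_restricted = {}
        lo, hi = -2000, 7000
        for gid in self.expression.index:
            sub = self.annotations[self.annotations["gene_id"] == gid]
            y = self.expression.loc[gid].to_numpy(dtype=float)
            self.fits[gid] = self._fit(gid, sub, y, seed)
            in_win = sub[(sub["signed_distance"] >= lo) & (sub["signed_distance"] <= hi)]
            if len(in_win):
                self.fits_restricted[gid] = self._fit(gid, in_win, y, seed)

        self.r2 = {g: f.cv.r2 for g, f in self.fits.items()}
        self.records = build_importance_table(self.fits, self.annotations, r2=self.r2)
        self.scan = survival_scan(self.expression, ds.clinical)
        metrics = pd.DataFrame(
            {"gene_id": list(self.r2), "r2": list(self.r2.values())}
        )
        self.masa = call_masa(metrics, self.scan)

    def _fit(self, gid, sub, y, seed):
        pids = [p for p in sub["probe_id"] if p in self._row_of]
        X = self._X[:, [self._row_of[p] for p in pids]]
        return cross_validate(
            X, y, gene_id=gid, probe_ids=pids, alpha_grid=(0.1,), seed=seed
        )

    @property
    def truth(self):
        return self.dataset.truth

    def planted_probes(self) -> set[tuple[str, str]]:
        return {
            (g, p)
            for g in self.truth.causal_genes()
            for p in self.truth.genes[g].causal_probes
        }


@pytest.fixture(scope="session")
def study() -> Study:
    return Study()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture()
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        n_samples=60,
        n_genes=20,
        genes_per_chrom=10,
        probes_per_gene=12,
        seed=7,
    )
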