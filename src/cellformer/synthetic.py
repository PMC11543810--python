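"""Seeded synthetic scRNA-seq count data with known cell types.

Counts follow a gamma-Poisson (negative binomial) model, the standard
overdispersed description of UMI counts: each gene has a base mean,
each cell type up-regulates its own block of marker genes by a fold
change, optional independent Bernoulli dropout zeroes entries, and an
optional per-batch log-normal gene-wise scale factor emulates
cross-platform (batch) effects that survive library-size normalisation.
Everything is a deterministic function of the seed, so fixtures are
regenerated at test time rather than shipped.

What this emulates: grouped marker structure, overdispersion, sparsity,
multiplicative batch effects.  What it does not: realistic library-size
variation, continuous trajectories, ambient RNA or doublets.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .io_preprocess import ExpressionMatrix, LabelSet, encode_labels, write_expression

__all__ = ["SynthConfig", "simulate_counts", "make_benchmark_suite", "PROFILES"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    marker_fold_change : mean multiplier of a type's marker genes (>1).
    dispersion : gamma-Poisson overdispersion; variance = μ + dispersion·μ².
    dropout_rate : probability an entry is zeroed independently.
    gene_mean_sd : sd of the log-normal spread of per-gene base means
        around ``base_mean``; real transcriptomes span orders of
        magnitude in mean expression, which is what mean-binned
        dispersion ranking corrects for.
    batch_scale_sd : sd of the per-batch log-normal gene-wise scale
        (0 disables batch effects even with several batches).
    """

    n_cells: int = 600
    n_genes: int = 200
    type_proportions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    markers_per_type: int = 20
    marker_fold_change: float = 8.0
    base_mean: float = 1.0
    gene_mean_sd: float = 1.0
    dispersion: float = 0.3
    dropout_rate: float = 0.2
    batch_scale_sd: float = 0.0
    n_batches: int = 1
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.type_proportions) - 1.0) > 1e-9:
            raise ValueError("type proportions must sum to 1")
        if self.markers_per_type * len(self.type_proportions) > self.n_genes:
            raise ValueError("markers_per_type × n_types exceeds n_genes")
        if self.marker_fold_change < 1.0:
            raise ValueError("marker_fold_change must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


def simulate_counts(
    cfg: SynthConfig,
) -> tuple[ExpressionMatrix, LabelSet, dict[str, list[int]], np.ndarray]:
    """Draw a counts matrix plus labels, the marker map and batch ids.

    Returns (raw ExpressionMatrix, LabelSet, {type: marker gene indices},
    per-cell batch index).
    """
    rng = np.random.default_rng(cfg.seed)
    n_types = len(cfg.type_proportions)
    type_names = [f"type_{chr(ord('A') + t)}" for t in range(n_types)]

    # cell type assignment: exact proportions (rounded), shuffled
    counts_per_type = np.floor(np.asarray(cfg.type_proportions) * cfg.n_cells).astype(int)
    counts_per_type[0] += cfg.n_cells - counts_per_type.sum()
    type_of_cell = np.repeat(np.arange(n_types), counts_per_type)
    rng.shuffle(type_of_cell)

    batch_of_cell = rng.integers(0, cfg.n_batches, size=cfg.n_cells)

    marker_map = {
        type_names[t]: list(range(t * cfg.markers_per_type, (t + 1) * cfg.markers_per_type))
        for t in range(n_types)
    }

    gene_mean = cfg.base_mean * np.exp(
        rng.normal(0.0, cfg.gene_mean_sd, size=cfg.n_genes)
    )
    mean = np.tile(gene_mean, (n_types, 1))
    for t, name in enumerate(type_names):
        mean[t, marker_map[name]] *= cfg.marker_fold_change

    # per-batch gene-wise multiplicative effect (log-normal)
    batch_scale = np.ones((cfg.n_batches, cfg.n_genes))
    if cfg.n_batches > 1 and cfg.batch_scale_sd > 0:
        batch_scale = np.exp(
            rng.normal(0.0, cfg.batch_scale_sd, size=(cfg.n_batches, cfg.n_genes))
        )

    mu = mean[type_of_cell] * batch_scale[batch_of_cell]
    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        mu = rng.gamma(shape, mu / shape)
    counts = rng.poisson(mu).astype(np.float64)
    if cfg.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= cfg.dropout_rate

    x = ExpressionMatrix(
        values=counts,
        cell_ids=tuple(f"cell_{i:05d}" for i in range(cfg.n_cells)),
        gene_ids=tuple(f"gene_{j:04d}" for j in range(cfg.n_genes)),
        stage="raw",
    )
    labels = encode_labels([type_names[t] for t in type_of_cell])
    return x, labels, marker_map, batch_of_cell


#: benchmark profile → generator settings
PROFILES: dict[str, SynthConfig] = {
    # three balanced, well-separated types
    "separable": SynthConfig(n_cells=600, n_genes=200,
                             type_proportions=(1 / 3, 1 / 3, 1 / 3)),
    # one rare type at 5% prevalence
    "imbalanced": SynthConfig(n_cells=600, n_genes=200,
                              type_proportions=(0.475, 0.475, 0.05)),
    # same types, two batches with gene-wise scale differences
    "crossbatch": SynthConfig(n_cells=800, n_genes=200, n_batches=2,
                              batch_scale_sd=0.4),
    # seven batches for leave-one-out fusion training
    "fusion": SynthConfig(n_cells=1400, n_genes=200, n_batches=7,
                          batch_scale_sd=0.4),
}


def make_benchmark_suite(profile: str, out_dir: str | os.PathLike, seed: int = 0) -> dict:
    """Write a named fixture (h5ad + CSV + manifest.json) and return the manifest.

    Regenerating from the manifest reproduces identical files.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    base = PROFILES[profile]
    cfg = SynthConfig(**{**asdict(base), "seed": seed})
    x, labels, marker_map, batches = simulate_counts(cfg)
    os.makedirs(out_dir, exist_ok=True)
    h5ad_path = os.path.join(out_dir, f"{profile}.h5ad")
    csv_path = os.path.join(out_dir, f"{profile}.csv")
    write_expression(x, h5ad_path, "h5ad", labels=labels)
    write_expression(x, csv_path, "csv", labels=labels)
    batch_path = os.path.join(out_dir, f"{profile}_batches.csv")
    with open(batch_path, "w") as fh:
        fh.write("cell_id,batch\n")
        for cid, b in zip(x.cell_ids, batches):
            fh.write(f"{cid},{b}\n")
    manifest = {
        "profile": profile,
        "config": asdict(cfg),
        "marker_map": marker_map,
        "files": [os.path.basename(p) for p in (h5ad_path, csv_path, batch_path)],
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
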