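"""Synthetic benchmark generator with planted regulation and a planted module.

The generator emulates the statistical structure the modeling stages
assume, so every stage is testable without external downloads:

* each TF t has a latent per-sample activity a_t ~ N(0,1); TFs of the
  planted indirect module share a common factor with loading
  sqrt(module_correlation), giving them the dense activity correlations the
  modularity stage looks for;
* each TF's target genes (and its own coding gene) read out a_t plus
  independent Gaussian noise, so the weighted-mean activity estimator
  approximately inverts the construction;
* the modeling target gene follows the planted linear model
  beta0 + sum_t beta_t * es_t * a_t + N(0, noise_sd), with a separate
  planted regulator set per condition;
* missing values are sprinkled uniformly at a configurable rate.

The emitted network contains TF -> own-target edges, TF -> target-gene
edges (every TF is a direct candidate), module-internal TF -> TF edges,
edges from module TFs onto the planted direct regulators' coding genes, and
sparse random background TF -> TF edges.  All randomness flows through one
seeded generator, so equal seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .regnet import RegulatoryNetwork

__all__ = ["SyntheticTruth", "generate", "PRESETS"]

TARGET_GENE = "TARGET"


@dataclass
class SyntheticTruth:
    planted_direct_A: dict[str, float]
    planted_direct_B: dict[str, float]
    planted_indirect: tuple[str, ...]
    noise_sd: float
    module_correlation: float
    n_samples_A: int
    n_samples_B: int
    target_gene: str
    seed: int
    es_to_target: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_direct_A": self.planted_direct_A,
                    "planted_direct_B": self.planted_direct_B,
                    "planted_indirect": list(self.planted_indirect),
                    "noise_sd": self.noise_sd,
                    "module_correlation": self.module_correlation,
                    "n_samples_A": self.n_samples_A,
                    "n_samples_B": self.n_samples_B,
                    "target_gene": self.target_gene,
                    "seed": self.seed,
                    "es_to_target": self.es_to_target,
                },
                fh,
                indent=2,
            )


def _tf_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"TF{i + 1:0{width}d}" for i in range(n)]


def generate(
    n_tfs: int = 20,
    n_targets_per_tf: int = 5,
    n_samples_A: int = 200,
    n_samples_B: int = 200,
    planted_direct_A: dict[str, float] | None = None,
    planted_direct_B: dict[str, float] | None = None,
    planted_indirect: list[str] | None = None,
    module_correlation: float = 0.6,
    noise_sd: float = 0.5,
    na_frac: float = 0.02,
    target_noise_sd: float = 0.25,
    beta0: float = 0.0,
    background_edge_rate: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionMatrix, RegulatoryNetwork, SyntheticTruth]:
    """Draw one synthetic dataset; see the module docstring for the model.

    ``planted_direct_A``/``B`` map TF name -> true beta per condition
    (defaults: the first two TFs in A, the second and third in B).
    ``planted_indirect`` defaults to the last four TFs, which must be
    disjoint from neither direct set by construction but are chosen so here.
    """
    if not (0 < module_correlation < 1):
        raise ValueError("module_correlation must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    tfs = _tf_names(n_tfs)
    if planted_direct_A is None:
        planted_direct_A = {tfs[0]: 1.0, tfs[1]: 1.0}
    if planted_direct_B is None:
        planted_direct_B = {tfs[1]: 1.0, tfs[2]: 1.0}
    for d in {**planted_direct_A, **planted_direct_B}:
        if d not in tfs:
            raise ValueError(f"planted regulator {d!r} not among the {n_tfs} TFs")
    if planted_indirect is None:
        planted_indirect = tfs[-4:] if n_tfs >= 4 else []
    planted_indirect = list(planted_indirect)

    n_total = n_samples_A + n_samples_B
    samples = [f"S{A + 1:03d}" for A in range(n_total)]
    cond = {s: ("A" if i < n_samples_A else "B") for i, s in enumerate(samples)}

    # latent activities; module TFs load on a shared factor
    shared = rng.standard_normal(n_total)
    a = np.empty((n_tfs, n_total))
    rho = module_correlation
    for i, t in enumerate(tfs):
        eps = rng.standard_normal(n_total)
        if t in planted_indirect:
            a[i] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps
        else:
            a[i] = eps

    # network: TF -> own readout targets, TF -> TARGET, module wiring, background
    edge_rows: list[tuple[str, str, str, float]] = []
    es_to_target: dict[str, float] = {}
    gene_rows: dict[str, np.ndarray] = {}
    for i, t in enumerate(tfs):
        for j in range(n_targets_per_tf):
            gname = f"G_{t}_{j + 1}"
            edge_rows.append((t, gname, "chip", float(rng.uniform(0.5, 1.5))))
            gene_rows[gname] = a[i] + target_noise_sd * rng.standard_normal(n_total)
        es_to_target[t] = 1.0
        edge_rows.append((t, TARGET_GENE, "chip", 1.0))
        # coding gene readout of the TF itself
        gene_rows[t] = a[i] + target_noise_sd * rng.standard_normal(n_total)

    direct_union = sorted(set(planted_direct_A) | set(planted_direct_B))
    for ind in planted_indirect:
        for d in direct_union:
            if ind != d:
                edge_rows.append((ind, d, "chip", float(rng.uniform(0.8, 1.2))))
    for t1 in planted_indirect:
        for t2 in planted_indirect:
            if t1 != t2:
                edge_rows.append((t1, t2, "chip", float(rng.uniform(0.8, 1.2))))
    existing = {(r, t) for r, t, _, _ in edge_rows}
    for t1 in tfs:
        for t2 in tfs:
            if t1 != t2 and (t1, t2) not in existing:
                if rng.random() < background_edge_rate:
                    edge_rows.append((t1, t2, "motif", float(rng.uniform(0.1, 0.4))))

    # planted linear response per condition
    target = np.full(n_total, beta0, dtype=float)
    idx = {t: i for i, t in enumerate(tfs)}
    mask_A = np.arange(n_total) < n_samples_A
    for t, beta in planted_direct_A.items():
        target[mask_A] += beta * es_to_target[t] * a[idx[t], mask_A]
    for t, beta in planted_direct_B.items():
        target[~mask_A] += beta * es_to_target[t] * a[idx[t], ~mask_A]
    target += noise_sd * rng.standard_normal(n_total)
    gene_rows[TARGET_GENE] = target

    genes = [TARGET_GENE] + sorted(g for g in gene_rows if g != TARGET_GENE)
    values = pd.DataFrame(
        np.vstack([gene_rows[g] for g in genes]), index=genes, columns=samples
    )
    if na_frac > 0:
        mask = rng.random(values.shape) < na_frac
        values = values.mask(mask)

    expr = ExpressionMatrix(values, cond)
    net = RegulatoryNetwork(
        pd.DataFrame(edge_rows, columns=["regulator", "target", "source", "weight"])
    )
    truth = SyntheticTruth(
        planted_direct_A=dict(planted_direct_A),
        planted_direct_B=dict(planted_direct_B),
        planted_indirect=tuple(planted_indirect),
        noise_sd=noise_sd,
        module_correlation=module_correlation,
        n_samples_A=n_samples_A,
        n_samples_B=n_samples_B,
        target_gene=TARGET_GENE,
        seed=seed,
        es_to_target=es_to_target,
    )
    return expr, net, truth


#: ready-made parameter sets for the command line
PRESETS = {
    "small": dict(n_tfs=8, n_targets_per_tf=3, n_samples_A=60, n_samples_B=60),
    "paper-shaped": dict(n_tfs=75, n_targets_per_tf=5, n_samples_A=445, n_samples_B=18),
}
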