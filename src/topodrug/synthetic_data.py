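"""Seeded generators for molecular graphs and tabular inputs.

The generators emulate the statistical shape of the study inputs so that
every pipeline stage can be exercised and property-tested without any
external data: connected simple graphs with organic-skeleton degree caps,
property tables following the quadratic generating model
``P = A + B*TI + C*TI**2 + noise``, and positive decision matrices.

All randomness flows through :class:`numpy.random.Generator` (PCG64)
seeded from the config, so identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .molgraph import MolecularGraph
from .topo_indices import compute_indices

__all__ = [
    "GeneratorConfig",
    "random_molecular_graph",
    "synthetic_qspr_table",
    "random_decision_matrix",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration shared by all generators.

    ``max_degree`` defaults to 4 to mimic heavy-atom organic skeletons;
    ``extra_edge_probability`` controls how many Bernoulli ring-closing
    edges are added on top of the random spanning tree.
    """

    seed: int = 0
    n_vertices: int = 12
    max_degree: int = 4
    extra_edge_probability: float = 0.1
    n_drugs: int = 10
    n_criteria: int = 6
    noise_sd: float = 0.0
    coefficients: tuple[float, float, float] = (2.0, 3.0, 0.5)
    index_name: str = "NM1"
    value_range: tuple[float, float] = (1.0, 1000.0)

    def __post_init__(self) -> None:
        if self.n_vertices < 2:
            raise ValueError("n_vertices must be >= 2")
        if not (0.0 <= self.extra_edge_probability < 1.0):
            raise ValueError("extra_edge_probability must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.max_degree == 1 and self.n_vertices > 2:
            raise ValueError("max_degree=1 admits no connected graph on >2 vertices")
        if self.max_degree < 1:
            raise ValueError("max_degree must be >= 1")


def _rng(cfg: GeneratorConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def random_molecular_graph(cfg: GeneratorConfig, name: str | None = None) -> MolecularGraph:
    """Connected simple graph with degrees capped at ``cfg.max_degree``.

    Built as a random spanning tree (vertices attach one at a time to a
    uniformly chosen earlier vertex with spare degree) plus Bernoulli
    extra edges that respect the cap.
    """
    rng = _rng(cfg, salt=1)
    n, cap = cfg.n_vertices, cfg.max_degree
    g = nx.Graph()
    g.add_node(0)
    for v in range(1, n):
        candidates = [u for u in g.nodes if g.degree(u) < cap]
        u = int(rng.choice(candidates))
        g.add_edge(u, v)
    if cfg.extra_edge_probability > 0 and n > 2:
        for u in range(n):
            for v in range(u + 1, n):
                if g.has_edge(u, v):
                    continue
                if g.degree(u) >= cap or g.degree(v) >= cap:
                    continue
                if rng.random() < cfg.extra_edge_probability:
                    g.add_edge(u, v)
    return MolecularGraph(name=name or f"synthetic-{cfg.seed}", graph=g)


def random_graph_set(cfg: GeneratorConfig) -> list[MolecularGraph]:
    """``cfg.n_drugs`` independent graphs named synthetic-<seed>-<i>."""
    return [
        random_molecular_graph(replace(cfg, seed=cfg.seed * 1000 + i), name=f"synthetic-{cfg.seed}-{i}")
        for i in range(cfg.n_drugs)
    ]


def synthetic_qspr_table(graphs: list[MolecularGraph], cfg: GeneratorConfig) -> pd.DataFrame:
    """Property table generated from the quadratic model on one index.

    ``P_i = A + B*TI_i + C*TI_i**2 + Normal(0, noise_sd)`` with TI chosen
    by ``cfg.index_name``.  Requires at least 4 graphs spanning at least
    3 distinct index values so the downstream fit is identified.
    """
    if len(graphs) < 4:
        raise ValueError("need at least 4 graphs")
    ti = np.array([getattr(compute_indices(g), cfg.index_name) for g in graphs], dtype=float)
    if np.unique(ti).size < 3:
        raise ValueError("degenerate index spread: need >= 3 distinct index values")
    a, b, c = cfg.coefficients
    rng = _rng(cfg, salt=2)
    noise = rng.normal(0.0, cfg.noise_sd, size=ti.size) if cfg.noise_sd > 0 else 0.0
    prop = a + b * ti + c * ti**2 + noise
    return pd.DataFrame(
        {cfg.index_name: ti, "P": prop},
        index=pd.Index([g.name for g in graphs], name="drug"),
    )


def random_decision_matrix(cfg: GeneratorConfig) -> pd.DataFrame:
    """Positive decision matrix, entries log-uniform in ``cfg.value_range``."""
    if cfg.n_drugs < 2 or cfg.n_criteria < 1:
        raise ValueError("need at least 2 alternatives and 1 criterion")
    rng = _rng(cfg, salt=3)
    lo, hi = cfg.value_range
    if not (0 < lo < hi):
        raise ValueError("value_range must satisfy 0 < lo < hi")
    vals = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(cfg.n_drugs, cfg.n_criteria)))
    return pd.DataFrame(
        vals,
        index=pd.Index([f"alt{i+1}" for i in range(cfg.n_drugs)], name="alternative"),
        columns=[f"c{j+1}" for j in range(cfg.n_criteria)],
    )
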