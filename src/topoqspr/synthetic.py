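"""Synthetic chemical-like graphs and property values with known truth.

Generates connected simple graphs with degrees capped at 4 (the organic
heavy-atom valence limit), computes their descriptors, and simulates a
property as a polynomial of one chosen descriptor plus Gaussian noise —
so every pipeline stage can be tested against known ground truth.

Construction: a uniform random spanning tree on n vertices (random
attachment, respecting the degree cap), then extra non-adjacent vertex
pairs are joined with probability ``extra_edge_prob`` where both endpoints
still have spare valence.  Connectivity holds by construction; the noise
is homoscedastic Gaussian, matching the OLS error model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import MolecularGraph, edge_partition
from .indices import INDEX_NAMES, DescriptorVector, compute_all

__all__ = ["SyntheticStudy", "random_molecular_graph", "simulate_property",
           "make_dataset"]


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated dataset: graphs, descriptors and a simulated property."""

    molecules: tuple[MolecularGraph, ...]
    descriptors: tuple[DescriptorVector, ...]
    true_coefficients: tuple[float, float, float, float]
    driver_index: str
    noise_sd: float
    seed: int
    properties: np.ndarray

    def descriptor_frame(self) -> pd.DataFrame:
        return pd.DataFrame([d.as_dict() for d in self.descriptors],
                            columns=list(INDEX_NAMES))

    def driver_values(self) -> np.ndarray:
        return self.descriptor_frame()[self.driver_index].to_numpy()


def random_molecular_graph(n_vertices: int, max_degree: int = 4,
                           extra_edge_prob: float = 0.1,
                           seed: int | np.random.Generator = 0
                           ) -> MolecularGraph:
    """Connected simple graph with all degrees in [1, max_degree].

    Built as a random spanning tree (each new vertex attaches to a uniform
    pick among vertices with spare valence) plus random extra edges, never
    exceeding ``max_degree``.
    """
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    if not 2 <= max_degree <= 4:
        raise ValueError("max_degree must be in [2, 4]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    deg = np.zeros(n_vertices, dtype=int)
    edges: list[tuple[str, str]] = []
    for v in range(1, n_vertices):
        open_slots = np.nonzero(deg[:v] < max_degree)[0]
        if len(open_slots) == 0:
            raise ValueError("infeasible: degree cap saturated while "
                             "building the spanning tree")
        u = int(rng.choice(open_slots))
        edges.append((str(u), str(v)))
        deg[u] += 1
        deg[v] += 1
    present = {frozenset(e) for e in edges}
    for u in range(n_vertices):
        for v in range(u + 1, n_vertices):
            if deg[u] >= max_degree or deg[v] >= max_degree:
                continue
            if frozenset((str(u), str(v))) in present:
                continue
            if rng.random() < extra_edge_prob:
                edges.append((str(u), str(v)))
                present.add(frozenset((str(u), str(v))))
                deg[u] += 1
                deg[v] += 1
    return MolecularGraph.from_pairs(edges)


def simulate_property(descriptor_values, beta, sigma: float = 0.0,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """y_j = b0 + b1*x_j + b2*x_j^2 + b3*x_j^3 + N(0, sigma^2)."""
    x = np.asarray(descriptor_values, dtype=float)
    beta = tuple(beta) + (0.0,) * (4 - len(tuple(beta)))
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    y = beta[0] + beta[1] * x + beta[2] * x ** 2 + beta[3] * x ** 3
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=x.shape)
    return y


def make_dataset(m_molecules: int = 17, n_vertices: int = 20,
                 max_degree: int = 4, extra_edge_prob: float = 0.1,
                 beta=(10.0, 2.0, 0.0, 0.0), sigma: float = 5.0,
                 driver_index: str = "M1", seed: int = 0) -> SyntheticStudy:
    """End-to-end study: graphs -> partitions -> descriptors -> property.

    Defaults mirror the reference study's scale: 17 molecules of roughly
    drug-like size (20 heavy atoms), a single descriptor (M1) driving the
    response linearly, and moderate homoscedastic noise.
    """
    if driver_index not in INDEX_NAMES:
        raise KeyError(f"unknown index {driver_index!r}")
    rng = np.random.default_rng(seed)
    molecules = tuple(
        random_molecular_graph(n_vertices, max_degree, extra_edge_prob, rng)
        for _ in range(m_molecules))
    descriptors = tuple(compute_all(edge_partition(g)) for g in molecules)
    frame = pd.DataFrame([d.as_dict() for d in descriptors])
    y = simulate_property(frame[driver_index].to_numpy(), beta, sigma, rng)
    return SyntheticStudy(molecules=molecules, descriptors=descriptors,
                          true_coefficients=tuple(beta) + (0.0,) * (4 - len(tuple(beta))),
                          driver_index=driver_index, noise_sd=float(sigma),
                          seed=seed, properties=y)
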