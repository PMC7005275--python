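"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from anchorscreen import (
    BarcodeMap,
    GuideReference,
    SimulationConfig,
    simulate_screen,
)


@pytest.fixture
def tiny_reference() -> GuideReference:
    return GuideReference(
        guide_ids=("g1", "g2", "g3", "g4"),
        spacers=(
            "ACGTACGTACGTACGTACGT",
            "TTTTCCCCGGGGAAAATTTT",
            "GATCGATCGATCGATCGATC",
            "AAAACCCCGGGGTTTTACGT",
        ),
        gene_symbols=("GENEA", "GENEA", "GENEB", "GENEB"),
    )


@pytest.fixture
def tiny_barcodes() -> BarcodeMap:
    return BarcodeMap({"AAAACCCC": "c1", "GGGGTTTT": "c2", "ACGTACGT": "pDNA"})


@pytest.fixture
def small_screen():
    config = SimulationConfig(n_genes=60, seed=7)
    counts, truth = simulate_screen(config)
    return config, counts, truth


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def brute_force_ks_plus(in_values, out_values) -> float:
    """sup_x [F_in(x) - F_out(x)] by evaluating both ECDFs at every
    observed value with plain loops."""
    in_values = list(in_values)
    out_values = list(out_values)
    best = 0.0
    for x in in_values + out_values:
        f_in = sum(v <= x for v in in_values) / len(in_values)
        f_out = sum(v <= x for v in out_values) / len(out_values)
        best = max(best, f_in - f_out)
    return best


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if len(items) <= 1:
        yield [items]
        return
    first = items[0]
    for smaller in set_partitions(items[1:]):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_max_modularity(graph: nx.Graph) -> float:
    """Global modularity maximum over every partition of the node set."""
    return max(
        nx.community.modularity(graph, [set(b) for b in part], weight="weight")
        for part in set_partitions(list(graph.nodes))
    )


def normal_equations_fit(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients via explicit normal equations."""
    return np.linalg.solve(design.T @ design, design.T @ y)


def random_weighted_graph(rng: np.random.Generator, n_nodes: int, p: float = 0.5) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                graph.add_edge(i, j, weight=float(rng.uniform(0.1, 1.0)))
    return graph
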