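"""County adjacency graphs and intrinsic CAR (ICAR) random fields.

A :class:`CountyGraph` is a thin wrapper around an undirected
:class:`networkx.Graph` whose nodes are county identifiers (zero-padded
FIPS-style strings) carrying three attributes used throughout the pipeline:
``appalachia`` (bool), ``rucc`` (USDA Rural-Urban Continuum Code, 1-9) and
``catchment`` (bool, cancer-center catchment membership).

The ICAR prior on a county field :math:`W` has improper joint density
:math:`p(W) \\propto \\exp(-\\tau/2 \\sum_{c \\sim d} (W_c - W_d)^2)`,
i.e. a Gaussian with precision :math:`\\tau L` where :math:`L` is the graph
Laplacian.  It is identified by a sum-to-zero constraint.  Sampling goes
through the eigendecomposition of :math:`L`: components of the field along
eigenvectors with eigenvalue :math:`\\lambda > 0` are independent
:math:`N(0, 1/(\\tau\\lambda))`; null-space (per-component constant)
directions are pinned to zero, except that isolated nodes receive an
exchangeable :math:`N(0, 1/\\tau)` draw.  The field is centered afterwards.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CountyGraph",
    "make_county_graph",
    "load_pa_fixture",
    "sample_icar_frailty",
    "icar_quadform",
]


class ConfigurationError(ValueError):
    """Raised for invalid layout/parameter choices."""


@dataclass
class CountyGraph:
    """Undirected county adjacency graph with region attributes.

    Attributes
    ----------
    graph : networkx.Graph
        Nodes are county id strings; node attributes ``appalachia``,
        ``rucc`` and ``catchment``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            if u == v:
                raise ValueError(f"self-loop at node {u!r}")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    def attrs(self) -> pd.DataFrame:
        """Node attribute table indexed by county id (sorted)."""
        rows = {
            c: {
                "appalachia": bool(d.get("appalachia", False)),
                "rucc": int(d.get("rucc", 1)),
                "catchment": bool(d.get("catchment", False)),
            }
            for c, d in self.graph.nodes(data=True)
        }
        return pd.DataFrame.from_dict(rows, orient="index").sort_index()

    def laplacian(self, order: list[str] | None = None) -> np.ndarray:
        order = order if order is not None else self.nodes
        return nx.laplacian_matrix(self.graph, nodelist=order).toarray().astype(float)

    def is_connected(self) -> bool:
        return self.n > 0 and nx.is_connected(self.graph)

    def subgraph(self, counties) -> "CountyGraph":
        return CountyGraph(self.graph.subgraph(counties).copy())


def _grid_graph(n_counties: int, seed: int) -> CountyGraph:
    # near-square rook lattice with ids g00000, g00001, ... row-major
    nrow = int(np.floor(np.sqrt(n_counties)))
    while n_counties % nrow and nrow > 1:
        nrow -= 1
    ncol = n_counties // nrow
    if nrow * ncol != n_counties:  # prime fall-back: 1 x n path
        nrow, ncol = 1, n_counties
    g = nx.Graph()
    ids = [f"g{i:05d}" for i in range(n_counties)]
    g.add_nodes_from(ids)
    for r in range(nrow):
        for c in range(ncol):
            i = r * ncol + c
            if c + 1 < ncol:
                g.add_edge(ids[i], ids[i + 1])
            if r + 1 < nrow:
                g.add_edge(ids[i], ids[i + ncol])
    rng = np.random.default_rng(seed)
    # deterministic attribute assignment: a contiguous appalachian block on the
    # left, metro RUCC codes sprinkled, catchment = central block
    for r in range(nrow):
        for c in range(ncol):
            i = r * ncol + c
            g.nodes[ids[i]]["appalachia"] = c < ncol // 2
            g.nodes[ids[i]]["rucc"] = int(rng.integers(1, 10))
            g.nodes[ids[i]]["catchment"] = (ncol // 4 <= c < 3 * ncol // 4)
    return CountyGraph(g)


def load_pa_fixture() -> CountyGraph:
    """Load the packaged 67-county Pennsylvania fixture graph.

    Queen-contiguity adjacency (approximate, curated) with Appalachia,
    RUCC and 28-county catchment attributes whose regional margins match
    the published Pennsylvania scheme (15 urban non-Appalachia, 22 urban
    Appalachia, 30 rural Appalachia; catchment split 9/9/10).
    """
    data = importlib.resources.files("geoaft.data")
    attrs = pd.read_csv(
        data / "pa_county_attributes.csv", comment="#", dtype={"fips": str}
    )
    g = nx.Graph()
    for row in attrs.itertuples(index=False):
        g.add_node(
            row.fips,
            name=row.name,
            appalachia=bool(row.appalachia),
            rucc=int(row.rucc),
            catchment=bool(row.catchment),
        )
    with (data / "pa_adjacency.txt").open() as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()
            g.add_edge(a, b)
    return CountyGraph(g)


def make_county_graph(
    n_counties: int = 67, layout: str = "grid", seed: int = 0
) -> CountyGraph:
    """Construct a county graph for simulation.

    Parameters
    ----------
    n_counties : int
        Number of counties (``grid`` layout only; >= 4).
    layout : {"grid", "pa_fixture"}
        ``grid`` builds a near-square rook lattice; ``pa_fixture`` loads the
        packaged 67-county Pennsylvania graph and ignores ``n_counties``.
    seed : int
        Drives deterministic attribute assignment for the grid layout.
    """
    if layout == "grid":
        if n_counties < 4:
            raise ConfigurationError("grid layout needs n_counties >= 4")
        return _grid_graph(n_counties, seed)
    if layout == "pa_fixture":
        return load_pa_fixture()
    raise ConfigurationError(f"unknown layout {layout!r}")


def _icar_factors(graph: CountyGraph, order: list[str]):
    """Eigendecomposition pieces for ICAR sampling, cached per call site."""
    L = graph.laplacian(order)
    lam, V = np.linalg.eigh(L)
    tol = 1e-9 * max(1.0, lam[-1] if len(lam) else 1.0)
    pos = lam > tol
    isolated = np.array([graph.graph.degree(c) == 0 for c in order])
    return lam, V, pos, isolated


def sample_icar_frailty(
    graph: CountyGraph,
    tau: float,
    seed: int | np.random.Generator = 0,
    size: int | None = None,
) -> np.ndarray:
    """Draw a sum-to-zero county field from the ICAR distribution.

    Returns an array aligned with ``graph.nodes`` (sorted ids); with
    ``size`` given, shape ``(size, n)``.  Isolated nodes are drawn
    independently N(0, 1/tau) before the global centering.
    """
    if graph.n == 0:
        raise ValueError("graph is empty")
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = graph.nodes
    lam, V, pos, isolated = _icar_factors(graph, order)
    m = 1 if size is None else size
    coef = np.zeros((m, graph.n))
    coef[:, pos] = rng.standard_normal((m, pos.sum())) / np.sqrt(tau * lam[pos])
    w = coef @ V.T
    if isolated.any():
        w[:, isolated] = rng.standard_normal((m, isolated.sum())) / np.sqrt(tau)
    w -= w.mean(axis=1, keepdims=True)
    return w[0] if size is None else w


def icar_quadform(graph: CountyGraph, w: np.ndarray, order: list[str] | None = None) -> float:
    """Pairwise-difference quadratic form sum_{c~d} (w_c - w_d)^2 = w' L w."""
    order = order if order is not None else graph.nodes
    L = graph.laplacian(order)
    return float(w @ L @ w)
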