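"""Fuzzification of learning-graph axes and the per-graph fused mass.

Crisp region boundaries would make the evidence jump discontinuously as a
candidate's features cross a bin edge.  Each axis therefore carries a
trapezoidal fuzzy partition: membership ramps linearly across a band
centred on every interior edge, and the memberships sum to exactly 1 at
every point (a partition of unity).  The mass a graph assigns to a query
point is then the membership-weighted sum of its region masses,

    m(S) = sum_ij  mu_i(x) * mu_j(y) * m_Rij(S)

which is automatically a valid mass function because both the axis
partitions and the region masses are normalised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .learning_graphs import LearningGraph, MassFunction

#: Default ramp width as a fraction of the local bin width.
DEFAULT_ALPHA = 0.25


@dataclass(frozen=True)
class FuzzyPartition:
    """Trapezoidal membership functions over one axis, one per bin.

    ``edges`` are the interior bin edges; ``half_widths[k]`` is the
    half-width of the linear ramp centred on ``edges[k]``.  Outer
    shoulders are flat to +-infinity, so every query point receives full
    total membership.  With all half-widths zero the partition reduces to
    crisp ``(lo, hi]`` indicators.
    """

    edges: np.ndarray
    half_widths: np.ndarray
    alpha: float

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def memberships(self, x: float) -> np.ndarray:
        """Membership of ``x`` in each bin; sums to 1 by construction."""
        # t[k]: fraction of x belonging to the right side of edge k
        t = np.empty(len(self.edges))
        for k, (e, h) in enumerate(zip(self.edges, self.half_widths)):
            if h == 0.0:
                t[k] = 0.0 if x <= e else 1.0
            else:
                t[k] = np.clip((x - (e - h)) / (2.0 * h), 0.0, 1.0)
        mu = np.empty(self.n_bins)
        for i in range(self.n_bins):
            left = t[i - 1] if i > 0 else 1.0
            right = 1.0 - t[i] if i < len(self.edges) else 0.0
            mu[i] = left * (right if i < len(self.edges) else 1.0)
        return mu


def build_partition(bin_edges, alpha: float = DEFAULT_ALPHA) -> FuzzyPartition:
    """Build a trapezoidal partition of unity over the given interior edges.

    Ramp width at each edge is ``alpha`` times the local bin width (the
    smaller of the two adjacent inter-edge gaps), so neighbouring ramps
    can never overlap for ``alpha <= 0.5`` and the partition-of-unity
    property holds exactly.  ``alpha = 0`` gives crisp regions.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1:
        raise ValueError("bin edges must be one-dimensional")
    if len(edges) > 1 and not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    if not 0.0 <= alpha <= 0.5:
        raise ValueError("alpha must lie in [0, 0.5]")

    gaps = np.diff(edges)
    half_widths = np.zeros(len(edges))
    for k in range(len(edges)):
        neighbours = []
        if k > 0:
            neighbours.append(gaps[k - 1])
        if k < len(gaps):
            neighbours.append(gaps[k])
        # single interior edge: both outer bins are unbounded, so there is
        # no data-driven width; fall back to a unit-scale ramp
        local = min(neighbours) if neighbours else 1.0
        half_widths[k] = 0.5 * alpha * local
    return FuzzyPartition(edges=edges, half_widths=half_widths, alpha=alpha)


def fuzzify_graph(graph: LearningGraph, alpha: float = DEFAULT_ALPHA) -> LearningGraph:
    """Attach fuzzy partitions to both axes of a learning graph (in place)."""
    graph.x_partition = build_partition(graph.x_edges, alpha)
    graph.y_partition = build_partition(graph.y_edges, alpha)
    return graph


def fuzzy_graph_mass(graph: LearningGraph, point: tuple[float, float]) -> MassFunction:
    """Mass a fuzzified graph assigns to a query point (x, y)."""
    if graph.x_partition is None or graph.y_partition is None:
        raise ValueError(
            f"graph {graph.graph_id} has no fuzzy partitions; call fuzzify_graph first"
        )
    x, y = point
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError(f"query point must be finite, got {point}")
    mu_x = graph.x_partition.memberships(x)
    mu_y = graph.y_partition.memberships(y)
    m_h1 = m_h2 = m_theta = 0.0
    for i in np.nonzero(mu_x)[0]:
        for j in np.nonzero(mu_y)[0]:
            w = mu_x[i] * mu_y[j]
            mass = graph.regions[i][j].mass
            m_h1 += w * mass.m_h1
            m_h2 += w * mass.m_h2
            m_theta += w * mass.m_theta
    return MassFunction(m_h1=m_h1, m_h2=m_h2, m_theta=m_theta)
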