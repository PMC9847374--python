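"""Learning graphs: 2-D feature grids of confidence regions with evidence masses.

The frame of discernment holds two singleton hypotheses — H1, "the motif is
an AuxRE", and H2, "the motif is not an AuxRE" — plus their union Theta,
which represents ignorance.  Each learning graph pairs two of the four
features (a1, a2, b1, b2); its plane is tiled into rectangular confidence
regions at empirical quantiles of the training points.  A region's AuxRE
fraction maps to one of four graded propositions:

    P4 - total confidence in the preferred hypothesis  (singleton mass 1)
    P3 - strong preference                             (singleton mass 0.67)
    P2 - low preference                                (singleton mass 0.33)
    P1 - total ignorance                               (singleton mass 0)

with the remaining mass always on Theta, never on the non-preferred
singleton.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import LABEL_POS, FeaturePoint

logger = logging.getLogger(__name__)


class Hypothesis(enum.Enum):
    H1 = "H1"  # the motif is an AuxRE
    H2 = "H2"  # the motif is not an AuxRE
    THETA = "THETA"  # H1 union H2: ignorance


@dataclass(frozen=True)
class MassFunction:
    """Basic belief assignment on {H1, H2, Theta}, summing to 1."""

    m_h1: float = 0.0
    m_h2: float = 0.0
    m_theta: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.m_h1, self.m_h2, self.m_theta):
            if v < -1e-12:
                raise ValueError(f"negative mass {v}")
        total = self.m_h1 + self.m_h2 + self.m_theta
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses sum to {total}, expected 1")

    def __getitem__(self, h: Hypothesis) -> float:
        return {
            Hypothesis.H1: self.m_h1,
            Hypothesis.H2: self.m_h2,
            Hypothesis.THETA: self.m_theta,
        }[h]

    @staticmethod
    def vacuous() -> "MassFunction":
        return MassFunction(m_theta=1.0)


#: Singleton mass attached to the preferred hypothesis at each level.
PROPOSITION_SCALE = {"P1": 0.0, "P2": 0.33, "P3": 0.67, "P4": 1.0}

#: AuxRE-fraction thresholds for P4/P3/P2 preference toward H1; the bands
#: below 0.45 are mirrored and prefer H2.  Overridable via config.
DEFAULT_THRESHOLDS = {"p4": 0.90, "p3": 0.70, "p2": 0.55, "p1": 0.45}


def proposition_mass(level: str, preferred: Hypothesis | None = None) -> MassFunction:
    """Mass function for a proposition level and its preferred hypothesis.

    The scale value goes on the preferred singleton, the remainder on
    Theta.  For P1 (total ignorance) the preferred hypothesis is ignored.
    """
    if level not in PROPOSITION_SCALE:
        raise ValueError(f"unknown proposition level {level!r}")
    s = PROPOSITION_SCALE[level]
    if level == "P1":
        return MassFunction.vacuous()
    if preferred not in (Hypothesis.H1, Hypothesis.H2):
        raise ValueError("P2-P4 require a preferred singleton hypothesis")
    if preferred is Hypothesis.H1:
        return MassFunction(m_h1=s, m_theta=1.0 - s)
    return MassFunction(m_h2=s, m_theta=1.0 - s)


def fraction_to_proposition(
    f: float, thresholds: dict[str, float] | None = None
) -> tuple[str, Hypothesis | None]:
    """Map a region's AuxRE fraction to (level, preferred hypothesis).

    Fractions of at least the ``p2`` threshold prefer H1 with increasing
    strength; fractions of at most ``1 - p2`` mirror toward H2; the band
    in between is total ignorance (P1, no preference).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fraction {f} outside [0, 1]")
    t = thresholds or DEFAULT_THRESHOLDS
    # eps keeps band assignment mirror-symmetric under the rounding of 1 - f
    eps = 1e-9
    if f >= t["p2"] - eps:
        g, preferred = f, Hypothesis.H1
    elif f <= t["p1"] + eps:
        g, preferred = 1.0 - f, Hypothesis.H2
    else:
        return "P1", None
    if g >= t["p4"] - eps:
        return "P4", preferred
    if g >= t["p3"] - eps:
        return "P3", preferred
    return "P2", preferred


@dataclass(frozen=True)
class ConfidenceRegion:
    """One rectangular cell of a learning graph.

    Bounds are half-open ``(lo, hi]`` per axis; outer cells extend to
    infinity.  ``auxre_fraction`` is Laplace-smoothed:
    ``(n_AuxRE + 1) / (n + 2)``, so an empty cell sits at 0.5 (ignorance).
    """

    graph_id: str
    cell: tuple[int, int]
    x_bounds: tuple[float, float]
    y_bounds: tuple[float, float]
    n_train: int
    auxre_fraction: float
    proposition: str
    preferred: Hypothesis | None
    mass: MassFunction


@dataclass
class LearningGraph:
    """A feature pair, its confidence-region grid, and fuzzy axis partitions.

    ``x_edges`` / ``y_edges`` are the interior bin edges; the grid has
    ``(len(x_edges) + 1) x (len(y_edges) + 1)`` cells.  Fuzzy partitions
    are attached after construction (see :mod:`auxre_fusion.fuzzy_mass`).
    """

    graph_id: str
    x_feature: str
    y_feature: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    regions: list[list[ConfidenceRegion]]
    x_partition: object | None = field(default=None, repr=False)
    y_partition: object | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.x_edges) + 1, len(self.y_edges) + 1

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Crisp cell lookup with the (lo, hi] convention."""
        i = int(np.searchsorted(self.x_edges, x, side="left"))
        j = int(np.searchsorted(self.y_edges, y, side="left"))
        return i, j

    def region_at(self, x: float, y: float) -> ConfidenceRegion:
        i, j = self.cell_index(x, y)
        return self.regions[i][j]


def _quantile_edges(values: np.ndarray, bins: int, axis_name: str) -> np.ndarray:
    """Interior bin edges at empirical quantiles, deduplicated.

    If the axis has too few distinct values to support ``bins`` cells the
    bin count is reduced with a warning rather than failing.
    """
    edges = np.quantile(values, np.arange(1, bins) / bins)
    edges = np.unique(edges)
    if len(edges) < bins - 1:
        logger.warning(
            "axis %s has too few distinct values for %d bins; using %d",
            axis_name,
            bins,
            len(edges) + 1,
        )
    return edges


def build_graph(
    graph_id: str,
    points: Sequence[tuple[FeaturePoint, str]],
    x_feature: str,
    y_feature: str,
    bins: int = 4,
    thresholds: dict[str, float] | None = None,
) -> LearningGraph:
    """Build one learning graph from labelled training feature points.

    Axis edges sit at empirical quantiles of all points (class-blind);
    each cell's Laplace-smoothed AuxRE fraction is mapped through the
    proposition bands to a mass function.  Deterministic for a given
    input multiset.
    """
    n_pos_total = sum(1 for _, lab in points if lab == LABEL_POS)
    if n_pos_total < 2 or len(points) - n_pos_total < 2:
        raise ValueError("need at least 2 training points per class")

    xs = np.array([fp.get(x_feature) for fp, _ in points])
    ys = np.array([fp.get(y_feature) for fp, _ in points])
    pos = np.array([lab == LABEL_POS for _, lab in points])

    x_edges = _quantile_edges(xs, bins, f"{graph_id}.{x_feature}")
    y_edges = _quantile_edges(ys, bins, f"{graph_id}.{y_feature}")
    nx, ny = len(x_edges) + 1, len(y_edges) + 1

    xi = np.searchsorted(x_edges, xs, side="left")
    yj = np.searchsorted(y_edges, ys, side="left")

    x_bounds = np.concatenate(([-np.inf], x_edges, [np.inf]))
    y_bounds = np.concatenate(([-np.inf], y_edges, [np.inf]))

    regions: list[list[ConfidenceRegion]] = []
    for i in range(nx):
        row = []
        for j in range(ny):
            in_cell = (xi == i) & (yj == j)
            n = int(in_cell.sum())
            n_pos = int((in_cell & pos).sum())
            frac = (n_pos + 1.0) / (n + 2.0)
            level, preferred = fraction_to_proposition(frac, thresholds)
            row.append(
                ConfidenceRegion(
                    graph_id=graph_id,
                    cell=(i, j),
                    x_bounds=(float(x_bounds[i]), float(x_bounds[i + 1])),
                    y_bounds=(float(y_bounds[j]), float(y_bounds[j + 1])),
                    n_train=n,
                    auxre_fraction=frac,
                    proposition=level,
                    preferred=preferred,
                    mass=proposition_mass(level, preferred),
                )
            )
        regions.append(row)

    return LearningGraph(
        graph_id=graph_id,
        x_feature=x_feature,
        y_feature=y_feature,
        x_edges=x_edges,
        y_edges=y_edges,
        regions=regions,
    )


#: Default feature pairing of the three learning graphs.
DEFAULT_GRAPH_PAIRS = {"G1": ("a1", "b1"), "G2": ("a1", "b2"), "G3": ("a2", "b1")}
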