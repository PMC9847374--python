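"""Dempster's rule of combination on the two-hypothesis frame, and decisions.

Evidence from the three learning graphs is pooled with the orthogonal sum:
conflicting focal products (H1 against H2) are discarded and the remainder
renormalised.  The fused mass is summarised by belief and plausibility
bounds for H1 and by the pignistic probability, which splits the ignorance
mass evenly between the singletons.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .learning_graphs import MassFunction

logger = logging.getLogger(__name__)

#: If 1 - K falls below this, the sources are treated as totally
#: conflicting and the combination degrades to full ignorance.
TOTAL_CONFLICT_EPS = 1e-9


def combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's orthogonal sum of two mass functions on {H1, H2, Theta}.

    Conflict ``K = m1(H1) m2(H2) + m1(H2) m2(H1)`` is removed by
    normalisation.  Total conflict (``1 - K`` below machine tolerance)
    yields the vacuous mass with a logged warning rather than an
    exception, so one pathological candidate cannot abort a scan.
    """
    k = m1.m_h1 * m2.m_h2 + m1.m_h2 * m2.m_h1
    denom = 1.0 - k
    if denom < TOTAL_CONFLICT_EPS:
        logger.warning("total conflict (K=%.12f) in Dempster combination", k)
        return MassFunction.vacuous()
    h1 = m1.m_h1 * m2.m_h1 + m1.m_h1 * m2.m_theta + m1.m_theta * m2.m_h1
    h2 = m1.m_h2 * m2.m_h2 + m1.m_h2 * m2.m_theta + m1.m_theta * m2.m_h2
    theta = m1.m_theta * m2.m_theta
    return MassFunction(m_h1=h1 / denom, m_h2=h2 / denom, m_theta=theta / denom)


def fuse_graphs(masses: Sequence[MassFunction]) -> MassFunction:
    """Fold the three per-graph masses into one by Dempster's rule."""
    if len(masses) != 3:
        raise ValueError(f"expected exactly 3 graph masses, got {len(masses)}")
    fused = masses[0]
    for m in masses[1:]:
        fused = combine(fused, m)
    return fused


def decision_scores(
    m: MassFunction, threshold: float = 0.5
) -> tuple[float, float, float, str]:
    """Belief, plausibility and pignistic probability of H1, plus the call.

    bel(H1) = m(H1); pl(H1) = m(H1) + m(Theta); betp(H1) = m(H1) +
    m(Theta)/2.  The candidate is labelled AuxRE when betp reaches the
    threshold; the boundary (exact ignorance at the default 0.5) resolves
    to AuxRE — the method is a detector, so sensitivity wins the tie.
    """
    bel = m.m_h1
    pl = m.m_h1 + m.m_theta
    betp = m.m_h1 + m.m_theta / 2.0
    label = "AuxRE" if betp >= threshold else "not-AuxRE"
    return bel, pl, betp, label
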