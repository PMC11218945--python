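"""Summary metrics reported alongside competition/commensalism predictions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: variants of the Chesson-style competitive-ability score; the printed
#: formula's grouping of mu_i - 1, alpha_ii and alpha_ij is ambiguous, so the
#: grouping is an explicit parameter and is recorded with the output.
CHESSON_VARIANTS = {
    "ratio_product": lambda mu, aii, aij: (mu - 1.0) / (aii * aij),
    "ratio_quotient": lambda mu, aii, aij: (mu - 1.0) * aii / aij,
    "intraspecific_only": lambda mu, aii, aij: (mu - 1.0) / aii,
}


@dataclass(frozen=True)
class GrowthPair:
    """Biomass flux of one species in monoculture and in co-culture."""

    v_mono: float
    v_co: float

    def __post_init__(self):
        if self.v_mono < 0 or self.v_co < 0:
            raise ValueError("biomass fluxes must be nonnegative")


def interaction_strength(g: GrowthPair) -> float:
    """Ratio of co-culture to monoculture growth rate.

    Above one signals a positive effect of the partner, below one a negative
    effect.  Undefined for a species that does not grow in monoculture.
    """
    if g.v_mono == 0:
        raise ValueError("interaction strength undefined for v_mono = 0")
    return g.v_co / g.v_mono


def chesson_score(
    mu: float, a_ii: float, a_ij: float, variant: str = "ratio_product"
) -> tuple[float, str]:
    """Chesson-style competitive-ability score of species *i*.

    ``mu`` is the monoculture growth rate, ``a_ii`` the intraspecific
    competition coefficient (against a near-isogenic strain) and ``a_ij`` the
    interspecific coefficient against strain *j*.  Returns ``(score,
    variant)`` so the grouping used is always recorded.
    """
    if a_ii <= 0 or a_ij <= 0:
        raise ValueError("competition coefficients must be positive")
    if variant not in CHESSON_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(CHESSON_VARIANTS)}")
    return CHESSON_VARIANTS[variant](mu, a_ii, a_ij), variant


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (zero-variance) input")
    return float(stats.pearsonr(x, y).statistic)


def score_summary(scores) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1 denominator) standard deviation."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two scores")
    return float(np.mean(scores)), float(np.std(scores, ddof=1))
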