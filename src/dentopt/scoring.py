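"""Pattern scoring: combined confidence + positional-relationship objective.

A complete assignment P of one candidate (or "missing") to each of the 32
tooth positions is scored as

    f(P) = (1/32) * sum_x [ w_c * mu_c(p_x) + w_p * mu_p(p_x) ]

where mu_c is the detector confidence of the chosen candidate and mu_p is a
positional-relationship score: the mean of a trapezoidal membership function
delta over the chosen candidates at neighboring positions x-2, x-1, x+1, x+2
(those that exist in 1..32).  delta looks only at the horizontal distance
between box centers and rewards distances inside anatomically plausible
ranges; it falls back to a neutral constant k when either side is missing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Candidate, N_TEETH, Pattern

__all__ = ["DeltaParams", "Weights", "delta", "positional_score", "pattern_score"]

#: Neighbor offsets entering the positional score, with the trapezoid order
#: (1 = adjacent tooth thresholds, 2 = next-nearest thresholds) for each.
_NEIGHBOR_OFFSETS = ((-2, 2), (-1, 1), (1, 1), (2, 2))


def _check_abcd(tup: tuple[float, float, float, float], name: str) -> None:
    a, b, c, d = tup
    if not (0 <= a < b < c < d):
        raise ValueError(f"{name} thresholds must satisfy 0 <= a < b < c < d, got {tup}")


@dataclass(frozen=True)
class DeltaParams:
    """Shape parameters of the trapezoidal horizontal-distance score.

    ``near`` holds the (a, b, c, d) pixel thresholds for adjacent positions
    (offset +-1), ``far`` those for next-nearest positions (offset +-2); the
    defaults were tuned on panoramic radiographs 1400-3100 px wide.  ``k`` is
    both the score at the trapezoid's ramp feet and the neutral value used
    when a neighbor (or the candidate itself) is missing.  ``scale``
    multiplies all thresholds, for detections on resized images.
    ``restrict_omega_to_jaw`` truncates the neighborhood at the upper/lower
    jaw boundary (positions 16|17) instead of applying the index arithmetic
    literally across it.
    """

    near: tuple[float, float, float, float] = (30.0, 47.0, 114.0, 130.0)
    far: tuple[float, float, float, float] = (80.0, 97.0, 164.0, 180.0)
    k: float = 0.35
    scale: float = 1.0
    restrict_omega_to_jaw: bool = False

    def __post_init__(self) -> None:
        _check_abcd(self.near, "near")
        _check_abcd(self.far, "far")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError(f"k must lie in [0, 1], got {self.k}")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def thresholds(self, order: int) -> tuple[float, float, float, float]:
        if order == 1:
            tup = self.near
        elif order == 2:
            tup = self.far
        else:
            raise ValueError(f"neighbor order must be 1 or 2, got {order}")
        if self.scale == 1.0:
            return tup
        s = self.scale
        return (tup[0] * s, tup[1] * s, tup[2] * s, tup[3] * s)


@dataclass(frozen=True)
class Weights:
    """Convex weights of the confidence (omega_c) and positional (omega_p) terms."""

    omega_c: float = 0.8
    omega_p: float = 0.2

    def __post_init__(self) -> None:
        if self.omega_c < 0 or self.omega_p < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.omega_c + self.omega_p - 1.0) > 1e-9:
            raise ValueError(
                f"weights must sum to 1, got {self.omega_c} + {self.omega_p}"
            )


def delta(p_x: Candidate, p_y: Candidate, order: int, params: DeltaParams) -> float:
    """Trapezoidal score of the horizontal center distance between two candidates.

    Returns k when either candidate is missing.  Otherwise, with
    D = |center_x(p_x) - center_x(p_y)| and thresholds (a, b, c, d) for the
    given neighbor order: 0 for D < a, a linear ramp from k to 1 on [a, b],
    1 on [b, c], a linear ramp from 1 down to k on [c, d], and 0 for D > d.
    The boundary points a, b, c, d close their adjacent ramp/plateau.
    """
    if p_x.is_missing or p_y.is_missing:
        return params.k
    a, b, c, d = params.thresholds(order)
    k = params.k
    dist = abs(p_x.box.center_x - p_y.box.center_x)
    if dist < a:
        return 0.0
    if dist <= b:
        return k + (1.0 - k) * (dist - a) / (b - a)
    if dist <= c:
        return 1.0
    if dist <= d:
        return 1.0 - (1.0 - k) * (dist - c) / (d - c)
    return 0.0


def _omega_indices(x: int, restrict_to_jaw: bool) -> list[tuple[int, int]]:
    """(neighbor position, order) pairs for position x, respecting range limits."""
    out = []
    for off, order in _NEIGHBOR_OFFSETS:
        y = x + off
        if not 1 <= y <= N_TEETH:
            continue
        if restrict_to_jaw and (x <= 16) != (y <= 16):
            continue
        out.append((y, order))
    return out


def positional_score(pattern: Pattern, tooth: int, params: DeltaParams) -> float:
    """mu_p: mean delta between position ``tooth`` and its in-range neighbors."""
    p_x = pattern[tooth]
    neighbors = _omega_indices(tooth, params.restrict_omega_to_jaw)
    total = 0.0
    for y, order in neighbors:
        total += delta(p_x, pattern[y], order, params)
    return total / len(neighbors)


def pattern_score(
    pattern: Pattern,
    weights: Weights,
    params: DeltaParams,
    missing_conf: float = 0.35,
) -> float:
    """f(P): mean over the 32 positions of w_c * mu_c + w_p * mu_p.

    ``missing_conf`` is the confidence surrogate mu_c assigned to missing
    assignments (rank 0); the default matches delta's neutral constant k.
    """
    if not 0.0 <= missing_conf <= 1.0:
        raise ValueError(f"missing_conf must lie in [0, 1], got {missing_conf}")
    total = 0.0
    for x in range(1, N_TEETH + 1):
        cand = pattern[x]
        mu_c = missing_conf if cand.is_missing else cand.confidence
        mu_p = positional_score(pattern, x, params)
        total += weights.omega_c * mu_c + weights.omega_p * mu_p
    return total / N_TEETH
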