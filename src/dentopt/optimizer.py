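"""Greedy pattern search over candidate assignments, plus an exhaustive oracle.

The search space for one image is the product over tooth positions of
(N(x) + 1) options (each position picks one detection or "missing").  The
greedy search initializes every position with its highest-confidence
candidate, then sweeps positions 1..32 substituting every alternative and
keeping strict improvements of the combined score; it stops when a full
sweep changes nothing.  The exhaustive search enumerates the entire product
space and serves as the ground-truth oracle in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .model import Candidate, CandidateSet, N_TEETH, Pattern
from .scoring import DeltaParams, Weights, pattern_score

__all__ = [
    "OptimizationResult",
    "SearchSpaceTooLarge",
    "initialize_pattern",
    "optimize_greedy",
    "optimize_exhaustive",
]


class SearchSpaceTooLarge(RuntimeError):
    """Exhaustive enumeration refused: the combination count exceeds the cap."""


@dataclass(frozen=True)
class OptimizationResult:
    pattern: Pattern
    score: float          # f of the returned pattern (the final S_max)
    sweeps: int           # full passes over the 32 positions
    evaluations: int      # pattern_score calls performed


def initialize_pattern(cs: CandidateSet) -> Pattern:
    """Step-1 pattern: the rank-1 (highest-confidence) candidate per position,
    or the missing candidate where nothing was detected."""
    entries = []
    for x in range(1, N_TEETH + 1):
        cands = cs.per_tooth[x]
        entries.append(cands[1] if len(cands) > 1 else cands[0])
    return Pattern(tuple(entries))


def optimize_greedy(
    cs: CandidateSet,
    weights: Weights = Weights(),
    params: DeltaParams = DeltaParams(),
    missing_conf: float = 0.35,
    sweep_mode: str = "immediate",
) -> OptimizationResult:
    """Coordinate-ascent refinement of the initial highest-confidence pattern.

    ``sweep_mode`` selects the update semantics, both of which terminate:

    - ``"immediate"`` (default): within a sweep, each strictly improving
      substitution updates the working pattern before the next position is
      examined (standard coordinate ascent).
    - ``"batch"``: each sweep evaluates all single substitutions against the
      sweep's starting pattern and applies only the best strictly improving
      one, then re-sweeps.

    Improvement must be strict, so the score increases monotonically and the
    search is deterministic and finite.
    """
    if sweep_mode not in ("immediate", "batch"):
        raise ValueError(f"sweep_mode must be 'immediate' or 'batch', got {sweep_mode!r}")

    pattern = initialize_pattern(cs)
    score = pattern_score(pattern, weights, params, missing_conf)
    evaluations = 1
    sweeps = 0

    while True:
        sweeps += 1
        improved = False
        if sweep_mode == "immediate":
            for x in range(1, N_TEETH + 1):
                current = pattern[x]
                for cand in cs.per_tooth[x]:
                    if cand is current:
                        continue
                    trial = pattern.replace(x, cand)
                    trial_score = pattern_score(trial, weights, params, missing_conf)
                    evaluations += 1
                    if trial_score > score:
                        pattern, score = trial, trial_score
                        current = cand
                        improved = True
        else:  # batch: best single substitution relative to the sweep start
            best_trial: tuple[float, Pattern] | None = None
            for x in range(1, N_TEETH + 1):
                current = pattern[x]
                for cand in cs.per_tooth[x]:
                    if cand is current:
                        continue
                    trial = pattern.replace(x, cand)
                    trial_score = pattern_score(trial, weights, params, missing_conf)
                    evaluations += 1
                    if trial_score > score and (
                        best_trial is None or trial_score > best_trial[0]
                    ):
                        best_trial = (trial_score, trial)
            if best_trial is not None:
                score, pattern = best_trial
                improved = True
        if not improved:
            break

    return OptimizationResult(pattern=pattern, score=score, sweeps=sweeps, evaluations=evaluations)


def optimize_exhaustive(
    cs: CandidateSet,
    weights: Weights = Weights(),
    params: DeltaParams = DeltaParams(),
    missing_conf: float = 0.35,
    max_combinations: int = 10**6,
) -> OptimizationResult:
    """Globally optimal pattern by full enumeration of the product space.

    Ties on the score are broken toward the lexicographically smallest rank
    vector, which the enumeration order (candidates rank 0..N(x), positions
    1..32) yields for free with a strict-improvement comparison.  Refuses to
    run when prod(N(x) + 1) exceeds ``max_combinations``.
    """
    size = cs.search_space_size()
    if size > max_combinations:
        raise SearchSpaceTooLarge(
            f"{size} candidate combinations exceed the cap of {max_combinations}"
        )

    # Positions with only the missing option contribute a single choice;
    # keep them fixed and enumerate the rest.
    variable = [x for x in range(1, N_TEETH + 1) if len(cs.per_tooth[x]) > 1]
    base = [cs.per_tooth[x][0] for x in range(1, N_TEETH + 1)]

    best_score = -1.0
    best_pattern: Pattern | None = None
    evaluations = 0
    for combo in itertools.product(*(cs.per_tooth[x] for x in variable)):
        entries = list(base)
        for x, cand in zip(variable, combo):
            entries[x - 1] = cand
        pattern = Pattern(tuple(entries))
        score = pattern_score(pattern, weights, params, missing_conf)
        evaluations += 1
        if score > best_score:
            best_score, best_pattern = score, pattern

    assert best_pattern is not None
    return OptimizationResult(
        pattern=best_pattern, score=best_score, sweeps=1, evaluations=evaluations
    )


def verify_score(result: OptimizationResult, weights: Weights, params: DeltaParams,
                 missing_conf: float = 0.35) -> bool:
    """Recheck that a result's stored score matches its pattern."""
    return abs(pattern_score(result.pattern, weights, params, missing_conf) - result.score) < 1e-12
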