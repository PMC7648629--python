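import numpy as np
import pytest

from dentopt.model import BoundingBox, Candidate, CandidateSet, Pattern, index_candidates


def make_box(cx: float, cy: float = 500.0, w: float = 60.0, h: float = 110.0) -> BoundingBox:
    return BoundingBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def make_candidate(tooth: int, cx: float, confidence: float, rank: int = 1) -> Candidate:
    return Candidate(tooth=tooth, box=make_box(cx), confidence=confidence, rank=rank)


def pattern_from(assignments: dict[int, Candidate]) -> Pattern:
    """Complete a pattern with missing candidates at unspecified positions."""
    return Pattern(
        tuple(assignments.get(x, Candidate.missing(x)) for x in range(1, 33))
    )


def random_small_instance(rng: np.random.Generator, n_teeth: int = 6,
                          max_candidates: int = 3) -> CandidateSet:
    """Random candidate set confined to positions 1..n_teeth.

    True-ish centers sit 80 px apart; candidates scatter around them so the
    positional score meaningfully discriminates.  Other positions carry only
    the missing option, keeping the exhaustive oracle tractable.
    """
    records = []
    for tooth in range(1, n_teeth + 1):
        base_cx = 200.0 + 80.0 * (tooth - 1)
        for _ in range(int(rng.integers(0, max_candidates + 1))):
            cx = base_cx + rng.normal(0.0, 40.0)
            records.append((tooth, make_box(cx), float(rng.uniform(0.2, 1.0))))
    return index_candidates(records, image_id="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
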