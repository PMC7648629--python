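"""Core domain types for tooth-numbered bounding-box candidates.

The dentition is indexed with the Universal Tooth Numbering (UTN) system:
positions 1-16 run across the upper jaw (upper right third molar = 1 to
upper left third molar = 16) and 17-32 across the lower jaw (lower left
third molar = 17 to lower right third molar = 32).  A detector emits, per
image, zero or more *candidates* for each position: an axis-aligned
bounding box plus a confidence score in [0, 1].  Every position also
carries an implicit rank-0 "missing tooth" candidate so that downstream
optimization can declare a position empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

N_TEETH = 32

__all__ = [
    "N_TEETH",
    "BoundingBox",
    "Candidate",
    "CandidateSet",
    "Pattern",
    "ValidationError",
    "utn_to_fdi",
    "fdi_to_utn",
    "is_upper_jaw",
    "index_candidates",
]


class ValidationError(ValueError):
    """Raised when input records violate the candidate-format contract."""


def _check_utn(utn: int) -> int:
    if not isinstance(utn, (int,)) or isinstance(utn, bool) or not 1 <= utn <= 32:
        raise ValidationError(f"tooth position must be an integer in 1..32, got {utn!r}")
    return utn


def is_upper_jaw(utn: int) -> bool:
    """True for maxillary positions (UTN 1-16)."""
    return _check_utn(utn) <= 16


def utn_to_fdi(utn: int) -> int:
    """Convert a Universal Tooth Number (1-32) to the two-digit FDI code.

    FDI codes are quadrant digit (1 = upper right, 2 = upper left,
    3 = lower left, 4 = lower right) followed by position 1-8 counted
    outward from the midline.  E.g. UTN 1 (upper right third molar) is
    FDI 18; UTN 9 (upper left central incisor) is FDI 21.
    """
    _check_utn(utn)
    if utn <= 8:
        return 10 + (9 - utn)
    if utn <= 16:
        return 20 + (utn - 8)
    if utn <= 24:
        return 30 + (25 - utn)
    return 40 + (utn - 24)


_FDI_TO_UTN = {utn_to_fdi(u): u for u in range(1, 33)}


def fdi_to_utn(fdi: int) -> int:
    """Inverse of :func:`utn_to_fdi`; raises for codes outside the permanent dentition."""
    try:
        return _FDI_TO_UTN[fdi]
    except KeyError:
        raise ValidationError(f"not a permanent-dentition FDI code: {fdi!r}") from None


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, x rightward, y downward, corners inclusive."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"box must have positive area: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @property
    def center_x(self) -> float:
        return 0.5 * (self.x_min + self.x_max)

    @property
    def center_y(self) -> float:
        return 0.5 * (self.y_min + self.y_max)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_xywh(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.width, self.height)

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BoundingBox":
        return cls(x, y, x + w, y + h)


@dataclass(frozen=True)
class Candidate:
    """One detector output (or the explicit missing-tooth option) for one position.

    Rank 0 is reserved for the missing-tooth candidate, which carries no box
    and no confidence.  Ranks >= 1 are detector outputs ordered by
    non-increasing confidence within the tooth position.
    """

    tooth: int
    box: BoundingBox | None = None
    confidence: float | None = None
    rank: int = 0

    def __post_init__(self) -> None:
        _check_utn(self.tooth)
        if self.rank == 0:
            if self.box is not None or self.confidence is not None:
                raise ValidationError("rank-0 (missing) candidate must have no box/confidence")
        else:
            if self.rank < 0:
                raise ValidationError(f"rank must be non-negative, got {self.rank}")
            if self.box is None or self.confidence is None:
                raise ValidationError("detected candidate needs both box and confidence")
            if not 0.0 <= self.confidence <= 1.0:
                raise ValidationError(
                    f"confidence must lie in [0, 1], got {self.confidence} (tooth {self.tooth})"
                )

    @property
    def is_missing(self) -> bool:
        return self.rank == 0

    @classmethod
    def missing(cls, tooth: int) -> "Candidate":
        return cls(tooth=tooth, box=None, confidence=None, rank=0)


@dataclass
class CandidateSet:
    """All candidates for one image, grouped by tooth position.

    ``per_tooth[x]`` lists the options for position x: the rank-0 missing
    candidate first, then detections with ranks 1..N(x) in non-increasing
    confidence order.  Every position 1-32 is always present.
    """

    image_id: str
    per_tooth: dict[int, list[Candidate]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for x in range(1, N_TEETH + 1):
            self.per_tooth.setdefault(x, [Candidate.missing(x)])

    def n_candidates(self, tooth: int) -> int:
        """N(x): number of detected (non-missing) candidates at a position."""
        return len(self.per_tooth[_check_utn(tooth)]) - 1

    def detections(self) -> list[Candidate]:
        """All detected candidates across positions, in tooth then rank order."""
        return [c for x in range(1, N_TEETH + 1) for c in self.per_tooth[x] if not c.is_missing]

    def search_space_size(self) -> int:
        """Number of complete assignment patterns, prod over x of (N(x) + 1)."""
        size = 1
        for x in range(1, N_TEETH + 1):
            size *= len(self.per_tooth[x])
        return size

    def validate(self) -> None:
        for x in range(1, N_TEETH + 1):
            cands = self.per_tooth[x]
            if not cands or not cands[0].is_missing:
                raise ValidationError(f"tooth {x}: rank-0 missing candidate must come first")
            confs = [c.confidence for c in cands[1:]]
            for i, c in enumerate(cands):
                if c.tooth != x:
                    raise ValidationError(f"tooth {x}: candidate labelled {c.tooth}")
                if c.rank != i:
                    raise ValidationError(f"tooth {x}: rank {c.rank} at slot {i}")
            if any(confs[i] < confs[i + 1] for i in range(len(confs) - 1)):
                raise ValidationError(f"tooth {x}: confidences not non-increasing")


@dataclass(frozen=True)
class Pattern:
    """A complete assignment: exactly one candidate (possibly missing) per position."""

    assignment: tuple[Candidate, ...]

    def __post_init__(self) -> None:
        if len(self.assignment) != N_TEETH:
            raise ValidationError(f"pattern needs {N_TEETH} entries, got {len(self.assignment)}")
        for x, cand in enumerate(self.assignment, start=1):
            if cand.tooth != x:
                raise ValidationError(f"slot {x} holds candidate for tooth {cand.tooth}")

    def __getitem__(self, tooth: int) -> Candidate:
        return self.assignment[_check_utn(tooth) - 1]

    def replace(self, tooth: int, cand: Candidate) -> "Pattern":
        _check_utn(tooth)
        if cand.tooth != tooth:
            raise ValidationError(f"candidate for tooth {cand.tooth} placed at slot {tooth}")
        entries = list(self.assignment)
        entries[tooth - 1] = cand
        return Pattern(tuple(entries))

    def selected_detections(self) -> list[Candidate]:
        """The non-missing assignments, i.e. the refined detection list."""
        return [c for c in self.assignment if not c.is_missing]

    def rank_vector(self) -> tuple[int, ...]:
        return tuple(c.rank for c in self.assignment)


def index_candidates(
    raw_detections: Iterable[tuple[int, BoundingBox, float]],
    image_id: str = "",
) -> CandidateSet:
    """Build a :class:`CandidateSet` from raw (tooth, box, confidence) records.

    Within each position, detections are sorted by descending confidence
    (stable, so equal confidences keep their input order) and assigned ranks
    1..N(x); the rank-0 missing candidate is prepended everywhere.  Invalid
    records are collected and reported together.
    """
    records = list(raw_detections)
    problems = []
    for i, rec in enumerate(records):
        tooth, box, conf = rec
        if not isinstance(tooth, int) or isinstance(tooth, bool) or not 1 <= tooth <= 32:
            problems.append(f"record {i}: tooth label {tooth!r} outside 1..32")
        if not isinstance(box, BoundingBox):
            problems.append(f"record {i}: box is not a BoundingBox")
        if not 0.0 <= conf <= 1.0:
            problems.append(f"record {i}: confidence {conf!r} outside [0, 1]")
    if problems:
        raise ValidationError("invalid detection records:\n  " + "\n  ".join(problems))

    per_tooth: dict[int, list[Candidate]] = {x: [Candidate.missing(x)] for x in range(1, N_TEETH + 1)}
    for x in range(1, N_TEETH + 1):
        mine = [(tooth, box, conf) for tooth, box, conf in records if tooth == x]
        mine.sort(key=lambda r: -r[2])  # stable: ties keep input order
        for rank, (_, box, conf) in enumerate(mine, start=1):
            per_tooth[x].append(Candidate(tooth=x, box=box, confidence=conf, rank=rank))
    return CandidateSet(image_id=image_id, per_tooth=per_tooth)
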