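"""Synthetic detector-output simulator for the candidate optimizer.

Stands in for a CNN tooth detector: lays out a two-row dental arch (upper
positions 1-16, lower 17-32) whose adjacent horizontal spacings fall on the
plateau of the positional trapezoid, then corrupts the ground truth with the
detector's characteristic failure modes — missed detections, displaced
double detections of a single tooth, neighbor label swaps, spurious boxes,
and confidence jitter.  Everything is driven by a single seed and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model import BoundingBox, CandidateSet, N_TEETH, index_candidates

__all__ = ["SimConfig", "SyntheticCase", "generate_arch", "corrupt_detections",
           "generate_case", "generate_dataset", "assign_folds"]


@dataclass(frozen=True)
class SimConfig:
    """Geometry, noise rates and confidence distributions of the simulator.

    The arch geometry keeps adjacent same-row tooth centers inside the
    near-trapezoid plateau (spacing draws are clipped to (47, 114) px), so a
    fully present ground-truth row scores a positional value of 1 between
    row-internal neighbors.  Correct detections jitter the ground-truth box
    by at most 10% of its size, which keeps their IOU above the 0.5 matching
    threshold; duplicates are displaced by 0.5-1.0 box widths so they fall
    below it.  Confidence ranges overlap (correct: uniform on ``conf_true``,
    erroneous: uniform on ``conf_false``) so confidence alone cannot
    separate true from false candidates and the positional term matters.
    """

    image_width: int = 2000
    image_height: int = 1000
    adjacent_spacing_mean: float = 80.0
    adjacent_spacing_sd: float = 8.0
    spacing_clip: tuple[float, float] = (47.0, 114.0)
    tooth_width_range: tuple[float, float] = (55.0, 80.0)
    tooth_height_range: tuple[float, float] = (90.0, 140.0)
    p_missing: float = 0.08          # tooth absent from the mouth
    p_missdetect: float = 0.02       # present tooth yields no correct candidate
    p_duplicate: float = 0.15        # displaced double detection of a tooth
    p_label_swap: float = 0.05       # extra copy carrying a neighbor's label
    p_spurious: float = 1.0          # Poisson mean of spurious boxes per image
    conf_true: tuple[float, float] = (0.7, 1.0)
    conf_false: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_missing", "p_missdetect", "p_duplicate", "p_label_swap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_spurious < 0:
            raise ValueError("p_spurious must be non-negative")
        if self.adjacent_spacing_mean <= 0 or self.adjacent_spacing_sd < 0:
            raise ValueError("spacing parameters must be positive")

    def noiseless(self) -> "SimConfig":
        """Copy with every detector noise process switched off (teeth may
        still be anatomically missing per ``p_missing``)."""
        return SimConfig(
            **{
                **asdict(self),
                "p_missdetect": 0.0,
                "p_duplicate": 0.0,
                "p_label_swap": 0.0,
                "p_spurious": 0.0,
            }
        )


@dataclass
class SyntheticCase:
    image_id: str
    ground_truth: dict[int, BoundingBox]   # only anatomically present teeth
    candidates: CandidateSet


def _row_centers(start_x: float, n: int, direction: int, config: SimConfig,
                 rng: np.random.Generator) -> list[float]:
    lo, hi = config.spacing_clip
    centers = [start_x]
    for _ in range(n - 1):
        step = float(np.clip(
            rng.normal(config.adjacent_spacing_mean, config.adjacent_spacing_sd), lo, hi
        ))
        centers.append(centers[-1] + direction * step)
    return centers


def generate_arch(config: SimConfig, rng: np.random.Generator) -> dict[int, BoundingBox]:
    """Ground-truth boxes for the anatomically present teeth of one mouth.

    Upper positions 1-16 run left to right across the image, lower positions
    17-32 run back right to left directly beneath, so position 17 sits under
    position 16 — matching how the numbering wraps around the mouth.
    """
    margin = 0.5 * (config.image_width - 15 * config.adjacent_spacing_mean)
    upper = _row_centers(margin, 16, +1, config, rng)
    lower = _row_centers(upper[-1] + rng.normal(0.0, 5.0), 16, -1, config, rng)
    y_upper = 0.35 * config.image_height
    y_lower = 0.65 * config.image_height

    gt: dict[int, BoundingBox] = {}
    for utn in range(1, N_TEETH + 1):
        if rng.random() < config.p_missing:
            continue
        cx = upper[utn - 1] if utn <= 16 else lower[utn - 17]
        cy = (y_upper if utn <= 16 else y_lower) + rng.normal(0.0, 5.0)
        w = rng.uniform(*config.tooth_width_range)
        h = rng.uniform(*config.tooth_height_range)
        gt[utn] = BoundingBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
    return gt


def _jitter(box: BoundingBox, frac: float, rng: np.random.Generator) -> BoundingBox:
    dx = rng.uniform(-frac, frac) * box.width
    dy = rng.uniform(-frac, frac) * box.height
    return BoundingBox(box.x_min + dx, box.y_min + dy, box.x_max + dx, box.y_max + dy)


def corrupt_detections(gt: dict[int, BoundingBox], config: SimConfig,
                       rng: np.random.Generator, image_id: str = "") -> CandidateSet:
    """Emit noisy candidates for a ground-truth arch.

    Each present tooth yields a lightly jittered correct candidate (IOU with
    its ground truth stays >= 0.5) unless the detector misses it; double
    detections are displaced horizontally by 0.5-1.0 box widths, label-swap
    copies sit on the true box but carry an adjacent position's label, and
    spurious boxes appear uniformly over the image with random labels.
    """
    records: list[tuple[int, BoundingBox, float]] = []
    for tooth in sorted(gt):
        box = gt[tooth]
        if rng.random() >= config.p_missdetect:
            records.append((tooth, _jitter(box, 0.10, rng), float(rng.uniform(*config.conf_true))))
        if rng.random() < config.p_duplicate:
            shift = rng.uniform(0.5, 1.0) * box.width * (1 if rng.random() < 0.5 else -1)
            dup = BoundingBox(box.x_min + shift, box.y_min, box.x_max + shift, box.y_max)
            records.append((tooth, dup, float(rng.uniform(*config.conf_false))))
        if rng.random() < config.p_label_swap:
            neighbor = tooth + (1 if rng.random() < 0.5 else -1)
            neighbor = min(max(neighbor, 1), N_TEETH)
            if neighbor != tooth:
                records.append(
                    (neighbor, _jitter(box, 0.05, rng), float(rng.uniform(*config.conf_false)))
                )
    for _ in range(rng.poisson(config.p_spurious)):
        w = rng.uniform(*config.tooth_width_range)
        h = rng.uniform(*config.tooth_height_range)
        cx = rng.uniform(w / 2, config.image_width - w / 2)
        cy = rng.uniform(h / 2, config.image_height - h / 2)
        records.append(
            (
                int(rng.integers(1, N_TEETH + 1)),
                BoundingBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
                float(rng.uniform(*config.conf_false)),
            )
        )
    return index_candidates(records, image_id=image_id)


def generate_case(config: SimConfig, case_seed: int, image_id: str) -> SyntheticCase:
    """One fully seeded synthetic image: arch plus noisy candidates."""
    rng = np.random.default_rng(case_seed)
    gt = generate_arch(config, rng)
    candidates = corrupt_detections(gt, config, rng, image_id=image_id)
    return SyntheticCase(image_id=image_id, ground_truth=gt, candidates=candidates)


def generate_dataset(config: SimConfig, n_images: int) -> tuple[list[SyntheticCase], dict]:
    """Generate ``n_images`` independent cases with per-image seeds seed+i.

    Returns the cases plus a manifest (full config and the per-image seeds)
    from which the dataset can be regenerated bit-identically.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    cases = []
    seeds = []
    for i in range(n_images):
        case_seed = config.seed + i
        image_id = f"sim_{i:05d}"
        cases.append(generate_case(config, case_seed, image_id))
        seeds.append(case_seed)
    manifest = {
        "config": asdict(config),
        "n_images": n_images,
        "image_seeds": seeds,
        "image_ids": [c.image_id for c in cases],
    }
    return cases, manifest


def assign_folds(image_ids: list[str], n_folds: int) -> dict[str, list[str]]:
    """Split image ids into K contiguous, disjoint, near-equal folds K1..Kn."""
    if not 1 <= n_folds <= len(image_ids):
        raise ValueError("need 1 <= n_folds <= number of images")
    bounds = np.linspace(0, len(image_ids), n_folds + 1).astype(int)
    return {
        f"K{i + 1}": list(image_ids[bounds[i]:bounds[i + 1]]) for i in range(n_folds)
    }
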