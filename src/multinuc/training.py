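"""Hill-climbing optimisation of the pixel-to-tile map.

Given training images with class labels (one class per target shape), the
trainable object is the injective pixel-to-tile map theta.  The loss for a
candidate theta sums, over training images, a softmax-margin term on per-shape
log nucleation scores,

    loss_i = -( log r_on - log sum_off r_off ),

computed with either the fast Window Nucleation Model (WNM) or the Stochastic
Greedy Model (SGM), plus optional penalties: a site-preference term (weighting
SGM nucleation participation against user-preferred regions of the on-target
shape, e.g. window positions that worked in flag experiments) and a
reserved-tile term counting assignments to reserved tiles (zero by
construction for maps produced here, where reserved exclusion is a hard move
constraint).  The exact heuristic weighting is configuration, not a constant.

Optimisation is plain hill climbing: random moves (swap the tiles of two
pixels, or swap an assigned tile with an unassigned one), accepted only on
strict improvement, so the loss trajectory is non-increasing by construction.
The standard schedule runs many cheap WNM-driven steps and then refines the
WNM optimum with the costlier SGM loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .energetics import EnergyParams
from .nucleation import sgm_estimate_rate, wnm_log_score
from .patterns import PixelImage, ThetaMap, image_to_concentrations
from .tileset import TileSystem

__all__ = [
    "TrainingProblem",
    "TrainingResult",
    "training_loss",
    "hill_climb",
    "train_theta",
]


@dataclass(frozen=True)
class TrainingProblem:
    """A classification task for the nucleation trainer.

    ``images[i]`` belongs to class ``labels[i]``; every label must name a
    layout of ``system``.  ``site_weights`` optionally maps a shape name to a
    per-location preference weight in [0, 1] (1 = preferred nucleation site);
    it is scored against SGM participation maps and ignored under WNM.
    """

    system: TileSystem
    params: EnergyParams
    images: tuple[PixelImage, ...]
    labels: tuple[str, ...]
    reserved: frozenset[str] = frozenset()
    method: Literal["wnm", "sgm"] = "wnm"
    wnm_k: int = 2
    sgm_paths: int = 10
    sgm_seed: int = 0
    base_nm: float = 16.67
    lambda_site: float = 0.0
    lambda_reserved: float = 1.0
    site_weights: Mapping[str, Mapping[tuple[int, int], float]] | None = None

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("one label per image required")
        shapes = set(self.system.shape_names)
        bad = set(self.labels) - shapes
        if bad:
            raise ValueError(f"labels {sorted(bad)} name no layout in the system")
        if not self.images:
            raise ValueError("need at least one training image")
        shape0 = self.images[0].shape
        if any(img.shape != shape0 for img in self.images):
            raise ValueError("all training images must share one pixel grid")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images[0].shape


def _image_log_scores(
    theta: ThetaMap, problem: TrainingProblem, image: PixelImage
) -> tuple[dict[str, float], dict[str, dict]]:
    pattern = image_to_concentrations(image, theta, problem.system, problem.base_nm)
    scores: dict[str, float] = {}
    participation: dict[str, dict] = {}
    if problem.method == "wnm":
        for layout in problem.system.layouts:
            scores[layout.name] = wnm_log_score(
                layout, pattern, problem.params, problem.wnm_k
            )
    else:
        rng = np.random.default_rng(problem.sgm_seed)
        for layout in problem.system.layouts:
            est = sgm_estimate_rate(
                layout,
                pattern,
                problem.params,
                n_paths=problem.sgm_paths,
                rng=rng,
            )
            scores[layout.name] = est.log_rate
            participation[layout.name] = est.participation
    return scores, participation


def _site_penalty(
    problem: TrainingProblem, label: str, participation: Mapping[tuple[int, int], float]
) -> float:
    """1 - (preference-weighted participation mass), in [0, 1]."""
    if problem.site_weights is None or label not in problem.site_weights:
        return 0.0
    weights = problem.site_weights[label]
    total = sum(participation.values())
    if total == 0:
        return 1.0
    overlap = sum(p * weights.get(loc, 0.0) for loc, p in participation.items())
    return 1.0 - overlap / total


def training_loss(theta: ThetaMap, problem: TrainingProblem) -> float:
    """Summed softmax-margin loss over the training set (lower is better)."""
    loss = problem.lambda_reserved * len(set(theta.assignments.values()) & theta.reserved)
    for image, label in zip(problem.images, problem.labels):
        scores, participation = _image_log_scores(theta, problem, image)
        on = scores[label]
        off = [v for name, v in scores.items() if name != label]
        loss += -(on - logsumexp(off)) if off else -on
        if problem.method == "sgm" and problem.lambda_site:
            loss += problem.lambda_site * _site_penalty(
                problem, label, participation.get(label, {})
            )
    return float(loss)


@dataclass
class TrainingResult:
    """Outcome of a training run."""

    theta: ThetaMap
    loss_trajectory: list[float]
    predictions: list[str | None] = field(default_factory=list)
    margins: list[float] = field(default_factory=list)
    method: str = "wnm"
    n_accepted: int = 0

    @property
    def loss(self) -> float:
        return self.loss_trajectory[-1]

    @property
    def accuracy(self) -> float:
        """Fraction of training images classified to their labelled shape."""
        if not self.predictions or not self._labels:
            return math.nan
        return float(np.mean([p == t for p, t in zip(self.predictions, self._labels)]))

    _labels: tuple[str, ...] = ()


def _evaluate(theta: ThetaMap, problem: TrainingProblem) -> tuple[list, list]:
    """Predicted shape and margin per training image at a fixed theta."""
    preds: list[str | None] = []
    margins: list[float] = []
    for image in problem.images:
        scores, _ = _image_log_scores(theta, problem, image)
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and abs(ranked[0][1] - ranked[1][1]) <= 1e-9:
            preds.append(None)
            margins.append(0.0)
        else:
            preds.append(ranked[0][0])
            margins.append(
                ranked[0][1] - logsumexp([v for _, v in ranked[1:]])
                if len(ranked) > 1
                else 0.0
            )
    return preds, margins


def _random_move(
    theta: ThetaMap, rng: np.random.Generator
) -> ThetaMap | None:
    pixels = sorted(theta.assignments)
    assignable_unused = [t for t in theta.unassigned if t not in theta.reserved]
    can_swap_pixels = len(pixels) >= 2
    can_swap_pool = bool(assignable_unused) and bool(pixels)
    if not can_swap_pixels and not can_swap_pool:
        return None
    if can_swap_pixels and (not can_swap_pool or rng.random() < 0.5):
        i, j = rng.choice(len(pixels), size=2, replace=False)
        return theta.swap_pixels(pixels[i], pixels[j])
    pix = pixels[int(rng.integers(len(pixels)))]
    tile = assignable_unused[int(rng.integers(len(assignable_unused)))]
    return theta.swap_with_unassigned(pix, tile)


def hill_climb(
    theta0: ThetaMap,
    problem: TrainingProblem,
    rng: np.random.Generator,
    n_steps: int = 200,
) -> TrainingResult:
    """Strict-improvement hill climbing over theta moves.

    Each step proposes one random move and accepts it iff the loss strictly
    decreases; the recorded trajectory is therefore non-increasing.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    theta = theta0
    loss = training_loss(theta, problem)
    trajectory = [loss]
    accepted = 0
    for _ in range(n_steps):
        move = _random_move(theta, rng)
        if move is None:
            break
        new_loss = training_loss(move, problem)
        if new_loss < loss:
            theta, loss = move, new_loss
            accepted += 1
        trajectory.append(loss)
    preds, margins = _evaluate(theta, problem)
    result = TrainingResult(
        theta=theta,
        loss_trajectory=trajectory,
        predictions=preds,
        margins=margins,
        method=problem.method,
        n_accepted=accepted,
    )
    result._labels = problem.labels
    return result


def train_theta(
    problem: TrainingProblem,
    rng: np.random.Generator,
    wnm_steps: int = 200,
    sgm_steps: int = 0,
    restarts: int = 1,
    theta0: ThetaMap | None = None,
) -> TrainingResult:
    """WNM-driven hill climb, optionally refined under the SGM loss.

    Runs ``restarts`` independent WNM hill climbs (random initial maps unless
    ``theta0`` is given) and keeps the best; if ``sgm_steps > 0`` the WNM
    optimum is then refined with the SGM-based loss and the result is scored
    under SGM.
    """
    wnm_problem = replace(problem, method="wnm")
    best: TrainingResult | None = None
    for _ in range(max(1, restarts)):
        start = (
            theta0
            if theta0 is not None
            else ThetaMap.random(
                problem.system.tiles, problem.image_shape, rng, problem.reserved
            )
        )
        result = hill_climb(start, wnm_problem, rng, n_steps=wnm_steps)
        if best is None or result.loss < best.loss:
            best = result
    assert best is not None
    if sgm_steps > 0:
        sgm_problem = replace(problem, method="sgm")
        refined = hill_climb(best.theta, sgm_problem, rng, n_steps=sgm_steps)
        return refined
    return best
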