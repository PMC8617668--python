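"""Multi-model detection ensembling with Affirmative/Consensus/Unanimous voting.

Detections from k models (e.g. the folds of a cross-validated detector) are
first clustered into groups that plausibly refer to the same object, then a
voting rule decides which groups survive:

* **affirmative** — any single model's detection suffices (vote >= 1);
* **consensus**  — a strict majority must agree (vote > k/2, so >= 4 of 6);
* **unanimous**  — every model must agree (vote == k).

Grouping is greedy: pool all detections of a frame, take the highest-
confidence unassigned one as a seed, and absorb every unassigned detection
from a *different* model whose IoU with the seed clears ``group_iou``.  The
one-per-model rule keeps a single model from double-voting for one object.
Each surviving group is emitted as its highest-confidence member's box with
confidence equal to the mean over members.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import Detection, iou

STRATEGIES = ("affirmative", "consensus", "unanimous")


@dataclass
class EnsembleConfig:
    strategy: str = "affirmative"
    group_iou: float = 0.5
    k: int = 6

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        if not (0.0 < self.group_iou <= 1.0):
            raise ValueError("group_iou must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class DetectionGroup:
    """Detections from distinct models clustered onto one putative object."""

    members: list[Detection]

    @property
    def vote_count(self) -> int:
        return len({m.source_id for m in self.members})

    @property
    def representative(self) -> Detection:
        return max(self.members, key=lambda d: d.confidence)

    @property
    def mean_confidence(self) -> float:
        return sum(d.confidence for d in self.members) / len(self.members)


def group_detections(
    per_model: list[list[Detection]],
    group_iou: float = 0.5,
) -> list[DetectionGroup]:
    """Greedily cluster one frame's detections from k models into groups.

    Model identity is taken from each detection's ``source_id``; detections
    arriving in the i-th inner list with an empty source_id are tagged
    ``model_i`` so anonymous inputs still vote correctly.  Every detection
    ends up in exactly one group.
    """
    pool: list[Detection] = []
    for i, dets in enumerate(per_model):
        for d in dets:
            if d.source_id == "":
                d = Detection(d.box, d.confidence, d.frame_index, f"model_{i}")
            pool.append(d)
    order = sorted(range(len(pool)), key=lambda i: -pool[i].confidence)
    assigned = [False] * len(pool)
    groups: list[DetectionGroup] = []
    for si in order:
        if assigned[si]:
            continue
        seed = pool[si]
        assigned[si] = True
        members = [seed]
        models_in = {seed.source_id}
        for oi in order:
            if assigned[oi]:
                continue
            cand = pool[oi]
            if cand.source_id in models_in or cand.frame_index != seed.frame_index:
                continue
            if iou(cand.box, seed.box) >= group_iou:
                assigned[oi] = True
                members.append(cand)
                models_in.add(cand.source_id)
        groups.append(DetectionGroup(members))
    return groups


def vote(groups: list[DetectionGroup], config: EnsembleConfig) -> list[Detection]:
    """Apply the configured voting rule and emit one detection per kept group."""
    if config.strategy == "affirmative":
        min_votes = 1
    elif config.strategy == "consensus":
        min_votes = config.k // 2 + 1  # strict majority
    else:  # unanimous
        min_votes = config.k
    out = []
    for g in groups:
        if g.vote_count >= min_votes:
            rep = g.representative
            out.append(
                Detection(rep.box, g.mean_confidence, rep.frame_index, "ensemble")
            )
    return out


def ensemble_detections(
    per_model: list[list[Detection]],
    config: EnsembleConfig | None = None,
) -> list[Detection]:
    """Group per-frame and vote across a whole sequence in one call."""
    config = config or EnsembleConfig()
    frames = sorted(
        {d.frame_index for dets in per_model for d in dets}
    )
    out: list[Detection] = []
    for t in frames:
        per_model_t = [[d for d in dets if d.frame_index == t] for dets in per_model]
        out.extend(vote(group_detections(per_model_t, config.group_iou), config))
    return out
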