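"""Simulated participants: distorted timeline responses with known parameters.

A :class:`ParticipantModel` specifies how a synthetic participant distorts
what they saw.  Recalled object times within an episode are an affine
distortion of truth around the episode centroid,

    recalled_i = centroid + global_scaling_bias * (true_i - centroid)
                 + translation_bias + N(0, pattern_noise_sd),

clipped to the episode bounds, with adjacent items' placements swapped with
probability ``order_swap_prob`` (swapping placed times keeps timing and
order errors coupled, as in a drag-and-drop interface).  Episode placements
within a run use the same construction with the episode-level bias and
noise.  Recognition and association tests are simple Bernoulli responders
with configurable hit/false-alarm/accuracy rates.

The identity participant (biases 1/0, sds 0, swap 0) reproduces the truth
exactly, which anchors every downstream metric's zero point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .design import EpisodeSchedule, ExperimentDesign, recognition_pool
from .metrics import score_recognition

__all__ = ["ParticipantModel", "ParticipantResponses", "simulate_responses",
           "simulate_population"]


@dataclass(frozen=True)
class ParticipantModel:
    """Generative parameters of one simulated participant.

    ``global_scaling_bias`` < 1 compresses recalled within-episode intervals,
    > 1 expands them; ``episode_scaling_bias`` plays the same role for
    episode placements within a run.  Noise sds are in seconds.
    """

    global_scaling_bias: float = 1.0
    translation_bias: float = 0.0
    pattern_noise_sd: float = 0.0
    order_swap_prob: float = 0.0
    episode_scaling_bias: float = 1.0
    episode_noise_sd: float = 0.0
    recognition_hit_rate: float = 1.0
    recognition_fa_rate: float = 0.0
    association_accuracy: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern_noise_sd < 0 or self.episode_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for p in (self.order_swap_prob, self.recognition_hit_rate,
                  self.recognition_fa_rate, self.association_accuracy):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.global_scaling_bias <= 0 or self.episode_scaling_bias <= 0:
            raise ValueError("scaling biases must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ParticipantResponses:
    """All test responses of one (simulated or real) participant.

    ``object_placements`` maps (run, episode) to recalled object times in
    seconds from episode start, index-aligned with the schedule's object
    ids.  ``episode_placements`` maps run to recalled episode positions in
    seconds from run start, index-aligned with episode order.
    """

    participant_id: str
    object_placements: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    episode_placements: dict[int, np.ndarray] = field(default_factory=dict)
    recognition_selected: list[int] = field(default_factory=list)
    recognition_scores: np.ndarray | None = None
    association_correct: dict[tuple[int, int], int] = field(default_factory=dict)
    timeline_test_times: dict[tuple[int, int], float] = field(default_factory=dict)
    age: float = np.nan
    sex: str = ""
    prior_fmri: int = 0
    strategy_scores: list[int] | None = None


def _distort(true: np.ndarray, scaling: float, shift: float, noise_sd: float,
             bounds: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    centroid = true.mean()
    out = centroid + scaling * (true - centroid) + shift
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=true.size)
    return np.clip(out, bounds[0], bounds[1])


def _swap_adjacent(times: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Exchange placed times of adjacent items (in true order) with prob."""
    out = times.copy()
    for i in range(out.size - 1):
        if prob > 0 and rng.random() < prob:
            out[i], out[i + 1] = out[i + 1], out[i]
    return out


def simulate_responses(schedules: list[EpisodeSchedule],
                       participant: ParticipantModel,
                       design: ExperimentDesign | None = None,
                       participant_id: str = "sub-01",
                       rng=None) -> ParticipantResponses:
    """Simulate one participant's full response set on the given schedules."""
    rng = np.random.default_rng(
        participant.rng_seed if rng is None else rng)
    p = participant
    resp = ParticipantResponses(participant_id=participant_id)

    by_run: dict[int, list[EpisodeSchedule]] = {}
    for s in schedules:
        by_run.setdefault(s.run_index, []).append(s)
    for run in by_run:
        by_run[run].sort(key=lambda s: s.episode_index)

    for s in schedules:
        true_rel = s.relative_onsets()
        recalled = _distort(true_rel, p.global_scaling_bias, p.translation_bias,
                            p.pattern_noise_sd, (0.0, s.duration), rng)
        recalled = _swap_adjacent(recalled, p.order_swap_prob, rng)
        resp.object_placements[(s.run_index, s.episode_index)] = recalled
        resp.timeline_test_times[(s.run_index, s.episode_index)] = float(
            s.planning_duration + s.execution_duration)

    for run, run_scheds in by_run.items():
        true_pos = np.array([s.stimulus_midpoint for s in run_scheds])
        run_end = run_scheds[-1].post_oddeven_onset + 10.0
        resp.episode_placements[run] = _distort(
            true_pos, p.episode_scaling_bias, 0.0, p.episode_noise_sd,
            (0.0, run_end), rng)

    # recognition: Bernoulli selection of targets (hit rate) and lures (FA rate)
    if design is not None:
        targets, lures = recognition_pool(design, schedules)
        sel = [oid for oid in targets if rng.random() < p.recognition_hit_rate]
        sel += [oid for oid in lures if rng.random() < p.recognition_fa_rate]
        resp.recognition_selected = sel
        if sel:
            resp.recognition_scores = score_recognition(
                sel, targets, lures, rng=rng)
        # association: correct with prob association_accuracy, else a random
        # other presented object
        all_ids = np.array(targets)
        for s in schedules:
            truth = s.object_ids[-1]
            if rng.random() < p.association_accuracy:
                choice = truth
            else:
                choice = int(rng.choice(all_ids[all_ids != truth]))
            resp.association_correct[(s.run_index, s.episode_index)] = int(
                choice == truth)

    # participant covariates
    resp.age = float(rng.integers(18, 42))
    resp.sex = "M" if rng.random() < 0.7 else "F"
    resp.prior_fmri = int(rng.random() < 0.25)
    resp.strategy_scores = list(rng.integers(1, 10, size=22))
    return resp


def simulate_population(n_participants: int,
                        seed: int = 0,
                        scaling_sd: float = 0.15,
                        noise_base: float = 0.35,
                        noise_coupling: float = 0.6,
                        episode_noise_base: float = 8.0,
                        swap_base: float = 0.05,
                        hit_rate: float = 0.8,
                        fa_rate: float = 0.1,
                        association_accuracy: float = 0.5) -> list[ParticipantModel]:
    """Draw a heterogeneous population of participant models.

    Scaling biases are log-normal around 1 (sd ``scaling_sd`` on the log
    scale).  When ``noise_coupling`` > 0, participants who compress time
    (scaling bias < 1) also place items with less pattern noise:
    ``pattern_noise_sd = noise_base * (1 + noise_coupling * (bias - 1))``,
    floored at a tenth of ``noise_base``.  This couples compression to more
    accurate relative-timing and order memory, the regime the behavioral
    models are designed to detect.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_participants):
        bias = float(np.exp(rng.normal(0.0, scaling_sd)))
        ep_bias = float(np.exp(rng.normal(0.0, scaling_sd)))
        noise = max(0.1 * noise_base,
                    noise_base * (1.0 + noise_coupling * (bias - 1.0)))
        out.append(ParticipantModel(
            global_scaling_bias=bias,
            translation_bias=float(rng.normal(0.0, 0.2)),
            pattern_noise_sd=noise,
            order_swap_prob=swap_base,
            episode_scaling_bias=ep_bias,
            episode_noise_sd=episode_noise_base,
            recognition_hit_rate=hit_rate,
            recognition_fa_rate=fa_rate,
            association_accuracy=association_accuracy,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return out
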