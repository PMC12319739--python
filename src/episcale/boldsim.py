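"""Synthetic BOLD data with planted pattern integration/differentiation.

Each object event carries a latent spatial activation pattern over the
in-mask voxels.  Within an episode, the object patterns are mixtures of a
shared episode pattern and object-unique patterns; the mixture weight rises
as the episode's simulated within-episode scaling (from the participant's
timeline response) falls below 1, scaled by ``integration_strength`` --
temporally compressed episodes therefore have more mutually similar object
patterns.  Episode patterns are spread along a fixed direction in pattern
space in proportion to the episode's between-episode expansion magnitude
times ``differentiation_strength`` -- episodes that were pushed apart in
time on the recalled run timeline get more distinct patterns.  At zero
strength both effects vanish and the data are null.

The voxel time series is the event design convolved with the canonical
double-gamma HRF, weighted by the latent patterns, plus AR(1) Gaussian
noise; optionally a few frames receive large global perturbations to
exercise DVARS scrubbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .design import EpisodeSchedule, ExperimentDesign
from .glm import _convolve_events, events_from_schedules
from .metrics import decompose, item_measures
from .participants import ParticipantResponses

__all__ = ["BoldSimSpec", "BoldSimResult", "simulate_bold", "compact_design"]


@dataclass(frozen=True)
class BoldSimSpec:
    """Parameters of the BOLD simulator (defaults match the acquisition:
    TR 2.57 s, 3 mm isotropic voxels)."""

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size: float = 3.0
    tr: float = 2.57
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    integration_strength: float = 1.0
    differentiation_strength: float = 1.0
    n_motion_spikes: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must be in (-1, 1)")
        if int(np.prod(self.grid_shape)) < 10:
            raise ValueError("grid too small for a 10-voxel searchlight")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BoldSimResult:
    """Simulated 4-D series per run, the brain mask, and the events table."""

    runs: dict[int, np.ndarray]            # run -> frames x nx x ny x nz
    frame_times: dict[int, np.ndarray]
    mask: np.ndarray
    events: pd.DataFrame                   # with absolute per-run onsets
    spike_frames: dict[int, np.ndarray]
    episode_scaling: np.ndarray            # simulated Scaling_P1 per episode
    episode_expansion: np.ndarray          # Episode scaling_P2^Exp per episode
    spec: BoldSimSpec


def compact_design(n_runs: int = 1, episodes_per_run: int = 8,
                   objects_per_episode: int = 5, seed: int = 0,
                   n_lures: int = 16) -> ExperimentDesign:
    """A scaled-down experiment design for simulation studies.

    Keeps the episode-internal interval structure of the full paradigm but
    shortens the consolidation and test periods so that a run fits in a few
    hundred frames.
    """
    n_targets = n_runs * episodes_per_run * objects_per_episode
    return ExperimentDesign(
        n_runs=n_runs, episodes_per_run=episodes_per_run,
        objects_per_episode=objects_per_episode,
        cross_fixation=4.0, odd_even=4.0,
        timeline_duration_mean=10.0, timeline_duration_sd=1.0,
        planning_duration=3.0,
        recognition_pool=n_targets + n_lures,
        recognition_targets=n_targets, rng_seed=seed)


def _episode_distortion_measures(schedules: list[EpisodeSchedule],
                                 responses: ParticipantResponses
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-episode (Scaling_P1, Episode scaling_P2^Exp) from the responses."""
    scaling = []
    by_run: dict[int, list[EpisodeSchedule]] = {}
    for s in schedules:
        by_run.setdefault(s.run_index, []).append(s)
    exp_by_key = {}
    for run, scheds in by_run.items():
        scheds.sort(key=lambda s: s.episode_index)
        placed = responses.episode_placements.get(run)
        if placed is not None and len(scheds) >= 2:
            true_pos = np.array([s.stimulus_midpoint for s in scheds])
            im = item_measures(true_pos, placed)
            for s, e in zip(scheds, im.item_scaling_exp):
                exp_by_key[(run, s.episode_index)] = float(e)
    expansion = []
    for s in schedules:
        placed = responses.object_placements.get((s.run_index, s.episode_index))
        if placed is None:
            scaling.append(1.0)
        else:
            dec = decompose(s.relative_onsets(), placed)
            scaling.append(1.0 if np.isnan(dec.scaling) else dec.scaling)
        expansion.append(exp_by_key.get((s.run_index, s.episode_index), 0.0))
    return np.asarray(scaling), np.asarray(expansion)


def simulate_bold(schedules: list[EpisodeSchedule],
                  responses: ParticipantResponses,
                  spec: BoldSimSpec) -> BoldSimResult:
    """Simulate one participant's 4-D functional data from their schedules
    and timeline responses, with planted integration/differentiation tied to
    the response-derived scaling measures."""
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.grid_shape)
    mask = np.ones(shape, dtype=bool)
    n_vox = int(np.prod(shape))

    scaling, expansion = _episode_distortion_measures(schedules, responses)
    n_episodes = len(schedules)
    n_objects = len(schedules[0].object_ids)

    # latent patterns over in-mask voxels
    direction = rng.standard_normal(n_vox)
    direction /= np.linalg.norm(direction)
    episode_patterns = np.empty((n_episodes, n_vox))
    object_patterns = np.empty((n_episodes, n_objects, n_vox))
    for k in range(n_episodes):
        unique = rng.standard_normal(n_vox)
        episode_patterns[k] = (spec.differentiation_strength * expansion[k]
                               * np.sqrt(n_vox) * direction + unique)
        # logistic mixture weight: 0.5 at no distortion or zero strength,
        # -> 1 with compression (patterns integrate), -> 0 with expansion
        w = float(1.0 / (1.0 + np.exp(-spec.integration_strength
                                      * (1.0 - scaling[k]))))
        for j in range(n_objects):
            obj_unique = rng.standard_normal(n_vox)
            object_patterns[k, j] = (np.sqrt(w) * episode_patterns[k]
                                     + np.sqrt(1.0 - w) * obj_unique)

    events = events_from_schedules(schedules)
    runs: dict[int, np.ndarray] = {}
    frame_times: dict[int, np.ndarray] = {}
    spikes: dict[int, np.ndarray] = {}
    run_ids = sorted({s.run_index for s in schedules})
    ep_index = {(s.run_index, s.episode_index): k
                for k, s in enumerate(schedules)}
    for run in run_ids:
        run_scheds = [s for s in schedules if s.run_index == run]
        run_end = max(s.post_oddeven_onset for s in run_scheds) + 10.0
        n_frames = int(np.ceil(run_end / spec.tr))
        ft = np.arange(n_frames) * spec.tr
        Y = np.zeros((n_frames, n_vox))
        for s in run_scheds:
            k = ep_index[(s.run_index, s.episode_index)]
            for j, onset in enumerate(s.object_onsets):
                reg = _convolve_events([onset], [s.object_duration], ft,
                                       spec.tr)
                Y += reg[:, None] * object_patterns[k, j][None, :]
        noise = rng.standard_normal((n_frames, n_vox)) * spec.noise_sd
        if spec.ar1_coef != 0.0:
            noise = sp_signal.lfilter([1.0], [1.0, -spec.ar1_coef], noise,
                                      axis=0)
        Y += noise + 100.0
        if spec.n_motion_spikes > 0:
            # sustained head displacement: the signal shifts at the spike
            # frame and stays shifted, so DVARS is abnormal at exactly that
            # frame (spaced >= 2 frames apart to keep transitions distinct)
            candidates = np.arange(1, n_frames - 1, 2)
            frames = rng.choice(candidates, size=spec.n_motion_spikes,
                                replace=False)
            amp = 20.0 * max(spec.noise_sd, 0.1)
            for f in frames:
                Y[int(f):] += amp * rng.choice([-1.0, 1.0])
            spikes[run] = np.sort(frames)
        else:
            spikes[run] = np.array([], dtype=int)
        runs[run] = Y.reshape((n_frames,) + shape)
        frame_times[run] = ft
    return BoldSimResult(runs=runs, frame_times=frame_times, mask=mask,
                         events=events, spike_frames=spikes,
                         episode_scaling=scaling,
                         episode_expansion=expansion, spec=spec)
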