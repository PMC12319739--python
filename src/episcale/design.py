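"""Experiment design and ground-truth schedule generation.

The paradigm emulated here presents participants with short "episodes": a
green boundary screen, five unique objects at irregular temporal intervals,
and a red boundary screen.  Each run contains 16 such episodes, each followed
by a cross-fixation period, an odd-even distractor task, a timeline placement
test for that episode, and a second odd-even task.  Three runs give 48
episodes (240 object events) per participant.

The six inter-stimulus gaps within an episode (green->o1, o1->o2, ...,
o5->red) are drawn from two uniform ranges -- three short gaps from
(0.1, 2.0) s and three long gaps from (2.1, 3.5) s -- assigned to gap
positions by a uniformly random permutation, so that every episode carries a
unique temporal pattern while stimulus-period durations stay in a band
suitable for blocked fMRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["ExperimentDesign", "EpisodeSchedule", "generate_schedule",
           "schedules_to_frame", "frame_to_schedules", "recognition_pool"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameters of the episodic timeline experiment.

    Durations are in seconds.  Defaults reproduce the reference paradigm:
    3 runs x 16 episodes x 5 objects, 0.6 s object/boundary presentations,
    three gaps per episode from each of the short (0.1-2.0 s) and long
    (2.1-3.5 s) ranges, 10 s cross-fixation and odd-even periods, and a
    385-item recognition pool containing the 240 presented objects.
    """

    n_runs: int = 3
    episodes_per_run: int = 16
    objects_per_episode: int = 5
    object_duration: float = 0.6
    boundary_duration: float = 0.6
    short_interval_range: tuple[float, float] = (0.1, 2.0)
    long_interval_range: tuple[float, float] = (2.1, 3.5)
    n_short: int = 3
    n_long: int = 3
    cross_fixation: float = 10.0
    odd_even: float = 10.0
    timeline_duration_mean: float = 50.5
    timeline_duration_sd: float = 13.0
    planning_duration: float = 5.0
    recognition_pool: int = 385
    recognition_targets: int = 240
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo_s, hi_s = self.short_interval_range
        lo_l, hi_l = self.long_interval_range
        if not (lo_s < hi_s and lo_l < hi_l):
            raise ValueError("interval ranges must have min < max")
        if hi_s > lo_l:
            raise ValueError("short and long interval ranges must not overlap")
        if self.n_short + self.n_long != self.objects_per_episode + 1:
            raise ValueError(
                "n_short + n_long must equal objects_per_episode + 1 "
                "(one gap per inter-stimulus interval)")
        if self.recognition_targets > self.recognition_pool:
            raise ValueError("recognition pool smaller than target count")
        n_objects = self.n_runs * self.episodes_per_run * self.objects_per_episode
        if self.recognition_targets != n_objects:
            raise ValueError(
                f"recognition_targets ({self.recognition_targets}) must equal the "
                f"number of presented objects ({n_objects})")

    @property
    def n_episodes(self) -> int:
        return self.n_runs * self.episodes_per_run

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EpisodeSchedule:
    """Ground-truth timing of one episode, in seconds from run start.

    ``object_onsets`` are presentation onsets; ``green_onset``/``red_onset``
    bracket the stimulus period.  The trailing period onsets are carried for
    first-level design-matrix construction.
    """

    run_index: int                  # 1-based
    episode_index: int              # 1-based within run
    green_onset: float
    red_onset: float
    object_onsets: list[float]
    object_ids: list[int]
    object_duration: float = 0.6
    boundary_duration: float = 0.6
    cross_onset: float = 0.0
    oddeven_onset: float = 0.0
    timeline_onset: float = 0.0
    planning_duration: float = 0.0
    execution_duration: float = 0.0
    post_oddeven_onset: float = 0.0

    @property
    def episode_start(self) -> float:
        return self.green_onset

    @property
    def episode_end(self) -> float:
        """End of the red boundary screen."""
        return self.red_onset + self.boundary_duration

    @property
    def duration(self) -> float:
        return self.episode_end - self.episode_start

    @property
    def stimulus_midpoint(self) -> float:
        return 0.5 * (self.episode_start + self.episode_end)

    def relative_onsets(self) -> np.ndarray:
        """Object onsets in seconds from episode start (green onset)."""
        return np.asarray(self.object_onsets) - self.green_onset

    def gaps(self) -> np.ndarray:
        """The six inter-stimulus gaps green->o1...o5->red."""
        edges = ([self.green_onset + self.boundary_duration]
                 + [t + self.object_duration for t in self.object_onsets])
        nxt = list(self.object_onsets) + [self.red_onset]
        return np.asarray(nxt) - np.asarray(edges)


def generate_schedule(design: ExperimentDesign) -> list[EpisodeSchedule]:
    """Generate ground-truth schedules for every episode of the experiment.

    Returns ``design.n_runs * design.episodes_per_run`` schedules in
    presentation order.  Deterministic under ``design.rng_seed``.
    """
    rng = np.random.default_rng(design.rng_seed)
    n_gaps = design.objects_per_episode + 1
    schedules: list[EpisodeSchedule] = []
    next_id = 1
    for run in range(1, design.n_runs + 1):
        t = 0.0
        for ep in range(1, design.episodes_per_run + 1):
            is_long = np.zeros(n_gaps, dtype=bool)
            is_long[rng.permutation(n_gaps)[: design.n_long]] = True
            gaps = np.where(
                is_long,
                rng.uniform(*design.long_interval_range, size=n_gaps),
                rng.uniform(*design.short_interval_range, size=n_gaps),
            )
            green = t
            onsets = []
            cursor = green + design.boundary_duration
            for g in gaps[:-1]:
                cursor += g
                onsets.append(cursor)
                cursor += design.object_duration
            red = cursor + gaps[-1]
            ids = list(range(next_id, next_id + design.objects_per_episode))
            next_id += design.objects_per_episode

            cross = red + design.boundary_duration
            oddeven = cross + design.cross_fixation
            timeline = oddeven + design.odd_even
            total_tl = max(
                design.planning_duration + 1.0,
                rng.normal(design.timeline_duration_mean, design.timeline_duration_sd),
            )
            planning = design.planning_duration
            execution = total_tl - planning
            post = timeline + total_tl
            t = post + design.odd_even

            schedules.append(EpisodeSchedule(
                run_index=run, episode_index=ep,
                green_onset=green, red_onset=red,
                object_onsets=onsets, object_ids=ids,
                object_duration=design.object_duration,
                boundary_duration=design.boundary_duration,
                cross_onset=cross, oddeven_onset=oddeven,
                timeline_onset=timeline,
                planning_duration=planning, execution_duration=execution,
                post_oddeven_onset=post,
            ))
    return schedules


def recognition_pool(design: ExperimentDesign,
                     schedules: list[EpisodeSchedule]) -> tuple[list[int], list[int]]:
    """Return (target_ids, lure_ids) for the recognition test pool."""
    targets = [oid for s in schedules for oid in s.object_ids]
    n_lures = design.recognition_pool - design.recognition_targets
    start = max(targets) + 1
    lures = list(range(start, start + n_lures))
    return targets, lures


def schedules_to_frame(schedules: list[EpisodeSchedule]) -> pd.DataFrame:
    """Long-format table, one row per object event, for TSV serialization."""
    rows = []
    for s in schedules:
        for j, (onset, oid) in enumerate(zip(s.object_onsets, s.object_ids), start=1):
            rows.append(dict(
                run=s.run_index, episode=s.episode_index, object=j,
                object_id=oid, onset=onset,
                green_onset=s.green_onset, red_onset=s.red_onset,
                object_duration=s.object_duration,
                boundary_duration=s.boundary_duration,
                cross_onset=s.cross_onset, oddeven_onset=s.oddeven_onset,
                timeline_onset=s.timeline_onset,
                planning_duration=s.planning_duration,
                execution_duration=s.execution_duration,
                post_oddeven_onset=s.post_oddeven_onset,
            ))
    return pd.DataFrame(rows)


def frame_to_schedules(frame: pd.DataFrame) -> list[EpisodeSchedule]:
    """Inverse of :func:`schedules_to_frame`."""
    required = {"run", "episode", "object", "object_id", "onset",
                "green_onset", "red_onset"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"schedule table missing columns: {sorted(missing)}")
    schedules = []
    for (run, ep), grp in frame.groupby(["run", "episode"], sort=True):
        grp = grp.sort_values("object")
        first = grp.iloc[0]
        schedules.append(EpisodeSchedule(
            run_index=int(run), episode_index=int(ep),
            green_onset=float(first.green_onset),
            red_onset=float(first.red_onset),
            object_onsets=[float(x) for x in grp.onset],
            object_ids=[int(x) for x in grp.object_id],
            object_duration=float(first.get("object_duration", 0.6)),
            boundary_duration=float(first.get("boundary_duration", 0.6)),
            cross_onset=float(first.get("cross_onset", 0.0)),
            oddeven_onset=float(first.get("oddeven_onset", 0.0)),
            timeline_onset=float(first.get("timeline_onset", 0.0)),
            planning_duration=float(first.get("planning_duration", 0.0)),
            execution_duration=float(first.get("execution_duration", 0.0)),
            post_oddeven_onset=float(first.get("post_oddeven_onset", 0.0)),
        ))
    schedules.sort(key=lambda s: (s.run_index, s.episode_index))
    return schedules
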