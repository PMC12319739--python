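"""Temporal distortion and order metrics for timeline placement responses.

A participant reconstructs the times of items (objects within an episode, or
episodes within a run) on an empty timeline.  The recalled point pattern is
compared with the true pattern through a three-step 1-D rigid + scale
alignment:

1. *Translation*: the recalled pattern is shifted so its centroid matches the
   true centroid (the RMSD-optimal 1-D translation).  The reported
   translation is the inverse of the applied shift, i.e. the signed centroid
   offset recalled - true.
2. *Scaling*: a least-squares scale maps the centered recalled pattern onto
   the centered true pattern.  The reported scaling factor is expressed in
   "memory" orientation -- recalled spread relative to true spread -- so
   values below 1 mean the participant compressed the intervals in memory
   and values above 1 mean expansion.
3. *Temporal pattern score*: after translation and scaling, each aligned
   recalled position is matched to the *closest* true position; the squared
   residuals are summed and negated, so 0 is perfect and more negative is
   worse.

Item-level measures (absolute deviation per item, local gap-ratio scaling)
and rank-based order scores complement the pattern-level decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import EpisodeSchedule, ExperimentDesign

__all__ = [
    "TemporalDecomposition", "ItemMeasures", "decompose", "item_measures",
    "order_score", "windowed_between_measures", "score_recognition",
    "score_association", "build_measure_table", "FIXED4_WINDOWS",
    "FIXED5_WINDOWS", "expanding_windows",
]

#: Non-overlapping windows of four consecutive episodes within a 16-episode run.
FIXED4_WINDOWS: tuple[tuple[int, int], ...] = ((1, 4), (5, 8), (9, 12), (13, 16))
#: Five-episode window variant (as analyzed: 1-5, 6-10 and 12-16).
FIXED5_WINDOWS: tuple[tuple[int, int], ...] = ((1, 5), (6, 10), (12, 16))


def expanding_windows(n_episodes: int = 16, start: int = 5) -> tuple[tuple[int, int], ...]:
    """Expanding windows 1-start, 1-(start+1), ..., 1-n_episodes."""
    return tuple((1, k) for k in range(start, n_episodes + 1))


@dataclass(frozen=True)
class TemporalDecomposition:
    """Translation / scaling / pattern-error decomposition of one response.

    ``scaling`` < 1 indicates temporal compression in memory, > 1 expansion;
    ``scaling_compr``/``scaling_exp`` are the one-sided magnitudes
    max(0, 1-scaling) and max(0, scaling-1).  ``pattern_score`` is the
    negated residual sum of squares (seconds^2), 0 for a perfect relative
    pattern.  ``degenerate`` flags responses with zero spread, for which the
    scale is undefined (scaling is NaN, residuals computed at scale 1).
    """

    translation: float
    scaling: float
    pattern_score: float
    degenerate: bool = False

    @property
    def scaling_compr(self) -> float:
        if math.isnan(self.scaling):
            return math.nan
        return max(0.0, 1.0 - self.scaling)

    @property
    def scaling_exp(self) -> float:
        if math.isnan(self.scaling):
            return math.nan
        return max(0.0, self.scaling - 1.0)


@dataclass(frozen=True)
class ItemMeasures:
    """Per-item deviation and local scaling, plus rank-order deviations."""

    item_translation: np.ndarray   # |recalled_i - true_i|, seconds
    item_scaling: np.ndarray       # recalled min-neighbor gap / true min-neighbor gap
    order_deviation: np.ndarray    # |recalled rank - true rank| per item

    @property
    def item_scaling_compr(self) -> np.ndarray:
        return np.maximum(0.0, 1.0 - self.item_scaling)

    @property
    def item_scaling_exp(self) -> np.ndarray:
        return np.maximum(0.0, self.item_scaling - 1.0)

    @property
    def mean_order_deviation(self) -> float:
        return float(np.mean(self.order_deviation))


def _closest_residuals(aligned: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Residual of each aligned position to the closest true position.

    Ties at equal distance resolve toward the earlier true position.
    """
    diff = np.abs(aligned[:, None] - true[None, :])
    # stable argmin returns the first (earliest) index on ties
    idx = np.argmin(diff, axis=1)
    return aligned - true[idx]


def decompose(true_times, recalled_times, bounds=None) -> TemporalDecomposition:
    """Decompose a recalled point pattern into translation, scaling and
    residual pattern error relative to the true pattern.

    Parameters
    ----------
    true_times, recalled_times : array-like of seconds, equal length >= 2,
        matched by item identity (position i corresponds across arrays).
    bounds : optional (lo, hi); when given, all times must lie within.

    Returns
    -------
    TemporalDecomposition
    """
    t = np.asarray(true_times, dtype=float)
    r = np.asarray(recalled_times, dtype=float)
    if t.ndim != 1 or t.shape != r.shape:
        raise ValueError("true and recalled patterns must be 1-D and equal length")
    if t.size < 2:
        raise ValueError("need at least two items to decompose")
    if bounds is not None:
        lo, hi = bounds
        if np.any((t < lo) | (t > hi)) or np.any((r < lo) | (r > hi)):
            raise ValueError("times outside the timeline bounds")

    ct = t - t.mean()
    cr = r - r.mean()
    translation = float(r.mean() - t.mean())   # inverse of the applied shift

    denom = float(np.dot(cr, cr))
    if denom == 0.0:
        resid = _closest_residuals(cr + t.mean(), t)
        return TemporalDecomposition(
            translation=translation, scaling=math.nan,
            pattern_score=-float(np.dot(resid, resid)), degenerate=True)

    s_fit = float(np.dot(ct, cr)) / denom      # least-squares recalled -> true
    if s_fit <= 0:
        # anti-correlated response: the LS scale is non-physical; report the
        # spread ratio magnitude and leave the residuals at the fitted scale
        scaling = float(np.sqrt(np.dot(cr, cr) / np.dot(ct, ct)))
    else:
        scaling = 1.0 / s_fit
    aligned = t.mean() + s_fit * cr
    resid = _closest_residuals(aligned, t)
    return TemporalDecomposition(
        translation=translation, scaling=scaling,
        pattern_score=-float(np.dot(resid, resid)))


def _min_neighbor_gaps(times: np.ndarray) -> np.ndarray:
    """Smallest gap from each item to its temporal neighbor(s).

    Neighbors are defined in the temporal order of the given times; the first
    and last items have a single neighbor.
    """
    order = np.argsort(times, kind="stable")
    sorted_times = times[order]
    gaps = np.diff(sorted_times)
    n = times.size
    best = np.empty(n)
    for pos in range(n):
        cands = []
        if pos > 0:
            cands.append(gaps[pos - 1])
        if pos < n - 1:
            cands.append(gaps[pos])
        best[order[pos]] = min(cands)
    return best


def order_score(true_times, recalled_times) -> tuple[np.ndarray, float]:
    """Rank-order deviation per item and its mean.

    Ranks are obtained by sorting placement times (stable: ties keep
    placement order).  The deviation for item i is |recalled rank - true
    rank|; 0 is a perfectly remembered order.
    """
    t = np.asarray(true_times, dtype=float)
    r = np.asarray(recalled_times, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("true and recalled patterns must be 1-D and equal length")
    rank_t = np.empty(t.size, dtype=int)
    rank_t[np.argsort(t, kind="stable")] = np.arange(1, t.size + 1)
    rank_r = np.empty(r.size, dtype=int)
    rank_r[np.argsort(r, kind="stable")] = np.arange(1, r.size + 1)
    dev = np.abs(rank_r - rank_t)
    return dev, float(dev.mean())


def item_measures(true_times, recalled_times) -> ItemMeasures:
    """Per-item absolute deviation, local gap-ratio scaling, and rank deviation.

    ``item_scaling[i]`` is the smallest gap from recalled item i to its
    recalled temporal neighbor(s), divided by the same quantity in the true
    pattern; > 1 means the participant locally expanded time around the item.
    """
    t = np.asarray(true_times, dtype=float)
    r = np.asarray(recalled_times, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("true and recalled patterns must be 1-D and equal length")
    if t.size < 2:
        raise ValueError("item-level scaling needs at least two items")
    true_gap = _min_neighbor_gaps(t)
    rec_gap = _min_neighbor_gaps(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaling = np.where(true_gap > 0, rec_gap / true_gap, np.nan)
    dev, _ = order_score(t, r)
    return ItemMeasures(
        item_translation=np.abs(r - t),
        item_scaling=scaling,
        order_deviation=dev,
    )


def windowed_between_measures(run_true, run_recalled, windows) -> dict[tuple[int, int], TemporalDecomposition]:
    """Apply :func:`decompose` to windows of consecutive episode placements.

    ``windows`` is an iterable of 1-based inclusive (start, stop) episode
    index pairs, e.g. ``FIXED4_WINDOWS`` or ``expanding_windows()``.
    """
    t = np.asarray(run_true, dtype=float)
    r = np.asarray(run_recalled, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("true and recalled run patterns must match")
    out = {}
    for start, stop in windows:
        if not (1 <= start < stop <= t.size):
            raise ValueError(f"window ({start}, {stop}) outside 1..{t.size}")
        sl = slice(start - 1, stop)
        out[(start, stop)] = decompose(t[sl], r[sl])
    return out


def score_recognition(selected_ids, target_ids, lure_ids, *, n_draws: int = 50,
                      draw_size: int = 5, rng=None) -> np.ndarray:
    """Recognition-test sampling score: hit counts over repeated draws.

    From the set of items the participant selected (targets and lures mixed),
    ``draw_size`` items are sampled without replacement and the number of
    non-lures counted; repeated ``n_draws`` times.  Returns the per-draw hit
    counts (length ``n_draws``).
    """
    rng = np.random.default_rng(rng)
    selected = list(selected_ids)
    if len(selected) == 0:
        raise ValueError("empty recognition selection")
    targets = set(target_ids)
    lures = set(lure_ids)
    unknown = set(selected) - targets - lures
    if unknown:
        raise ValueError(f"selected ids outside the pool: {sorted(unknown)[:5]}")
    selected_arr = np.asarray(selected)
    is_target = np.isin(selected_arr, list(targets))
    counts = np.empty(n_draws, dtype=int)
    replace = len(selected) < draw_size
    for d in range(n_draws):
        idx = rng.choice(len(selected), size=draw_size, replace=replace)
        counts[d] = int(is_target[idx].sum())
    return counts


def score_association(grouping_response: dict, true_grouping: dict) -> pd.DataFrame:
    """Binary correctness of the object-association test per episode.

    Both arguments map (run, episode) to the id of the held-out fifth object;
    a response is correct when it names the true member of the episode.
    """
    rows = []
    for key, truth in true_grouping.items():
        run, episode = key
        resp = grouping_response.get(key)
        rows.append(dict(run=run, episode=episode,
                         correct=int(resp == truth),
                         missing=int(resp is None)))
    return pd.DataFrame(rows).sort_values(["run", "episode"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# trial-level measure table

_WINDOW_OF_EPISODE = {ep: w for w in FIXED4_WINDOWS for ep in range(w[0], w[1] + 1)}


def build_measure_table(schedules: list[EpisodeSchedule], responses,
                        design: ExperimentDesign | None = None) -> pd.DataFrame:
    """Assemble the long-format trial table feeding models and null tests.

    One row per (participant, run, episode) with the within-episode
    decomposition, item-level aggregates, order scores, the fixed
    four-episode-window between-episode decomposition mapped onto member
    episodes, per-episode placement measures, recognition and association
    scores, and design covariates.  ``responses`` is an iterable of
    :class:`~episcale.participants.ParticipantResponses`.

    Missing trials are emitted as flagged rows (``missing = 1``) rather than
    silently dropped.
    """
    by_run: dict[int, list[EpisodeSchedule]] = {}
    for s in schedules:
        by_run.setdefault(s.run_index, []).append(s)
    for run in by_run:
        by_run[run].sort(key=lambda s: s.episode_index)

    rows = []
    for resp in responses:
        # between-episode measures per run
        run_measures: dict[int, dict] = {}
        for run, run_scheds in by_run.items():
            true_pos = np.array([s.stimulus_midpoint for s in run_scheds])
            placed = resp.episode_placements.get(run)
            if placed is None:
                run_measures[run] = None
                continue
            placed = np.asarray(placed, dtype=float)
            full = decompose(true_pos, placed)
            windows = windowed_between_measures(true_pos, placed, FIXED4_WINDOWS) \
                if len(run_scheds) >= 16 else {}
            im = item_measures(true_pos, placed)
            dev, _ = order_score(true_pos, placed)
            run_measures[run] = dict(full=full, windows=windows, items=im, order=dev)

        rec_mean = float(np.mean(resp.recognition_scores)) \
            if getattr(resp, "recognition_scores", None) is not None else np.nan

        for s in schedules:
            key = (s.run_index, s.episode_index)
            true_rel = s.relative_onsets()
            placed = resp.object_placements.get(key)
            row = dict(
                participant=resp.participant_id,
                run=s.run_index, episode=s.episode_index,
                missing=int(placed is None),
            )
            if placed is not None:
                dec = decompose(true_rel, np.asarray(placed, dtype=float),
                                bounds=(0.0, s.duration))
                im = item_measures(true_rel, placed)
                row.update(
                    translation_p1=dec.translation,
                    translation_p1_abs=abs(dec.translation),
                    scaling_p1=dec.scaling,
                    scaling_p1_compr=dec.scaling_compr,
                    scaling_p1_exp=dec.scaling_exp,
                    pattern_p1=dec.pattern_score,
                    degenerate_p1=int(dec.degenerate),
                    object_translation_p1=float(im.item_translation.mean()),
                    object_scaling_p1=float(np.nanmean(im.item_scaling)),
                    order_o1=im.mean_order_deviation,
                )
            rm = run_measures.get(s.run_index)
            if rm is not None:
                idx = s.episode_index - 1
                row.update(
                    translation_p2=rm["full"].translation,
                    scaling_p2=rm["full"].scaling,
                    scaling_p2_compr=rm["full"].scaling_compr,
                    scaling_p2_exp=rm["full"].scaling_exp,
                    pattern_p2=rm["full"].pattern_score,
                    episode_translation_p2=float(rm["items"].item_translation[idx]),
                    episode_scaling_p2=float(rm["items"].item_scaling[idx]),
                    episode_scaling_p2_compr=float(rm["items"].item_scaling_compr[idx]),
                    episode_scaling_p2_exp=float(rm["items"].item_scaling_exp[idx]),
                    order_o2=float(rm["order"][idx]),
                )
                win = _WINDOW_OF_EPISODE.get(s.episode_index)
                if win is not None and win in rm["windows"]:
                    wdec = rm["windows"][win]
                    row.update(
                        pattern_p2_w4=wdec.pattern_score,
                        translation_p2_w4=wdec.translation,
                        scaling_p2_w4=wdec.scaling,
                    )
            assoc = getattr(resp, "association_correct", {}).get(key)
            row["association"] = np.nan if assoc is None else float(assoc)
            row["recognition"] = rec_mean
            # covariates derivable from the design
            gaps = s.gaps()
            row.update(
                episode_duration=s.duration,
                stimulus_span=float(true_rel[-1] - true_rel[0]),
                interval_variability=float(np.std(gaps, ddof=0)),
                run_number=s.run_index,
                episode_number=s.episode_index,
                timeline_test_time=float(
                    resp.timeline_test_times.get(key, np.nan))
                if getattr(resp, "timeline_test_times", None) else np.nan,
            )
            # participant covariates
            row.update(
                age=getattr(resp, "age", np.nan),
                sex=getattr(resp, "sex", ""),
                prior_fmri=getattr(resp, "prior_fmri", 0),
            )
            strategies = getattr(resp, "strategy_scores", None)
            if strategies is not None:
                for q, v in enumerate(strategies, start=1):
                    row[f"strategy_{q:02d}"] = v
            rows.append(row)
    return pd.DataFrame(rows)
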