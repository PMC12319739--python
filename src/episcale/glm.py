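"""First-level GLM for the simulated functional series.

Two design variants mirror the two analysis stages:

* *model one* -- one regressor per object event (240 in the full design)
  plus single regressors for the cross-fixation period, the odd-even period
  after it, the timeline-test planning period, and the timeline-test
  execution period, plus an intercept: 245 columns.
* *model two* -- one regressor per episode for each of the five modeled
  periods (stimulus, cross-fixation, post-fixation odd-even, timeline
  planning, timeline execution), plus an intercept: 241 columns for the
  full 48-episode design.

The odd-even period after the timeline test is left unmodeled and serves as
the implicit baseline.  Events are boxcars of their stated durations
convolved with a canonical double-gamma hemodynamic response.  Frames with
abnormal DVARS (frame-to-frame RMS signal change) receive one spike
regressor each.  Estimation is ordinary least squares per voxel; residuals
are retained for multivariate noise normalization downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DesignMatrix", "GlmResult", "canonical_hrf", "build_design",
           "compute_dvars", "dvars_outliers", "add_spike_regressors",
           "fit_glm", "events_from_schedules"]

MODEL_ONE_PERIODS = ("cross_fixation", "odd_even_post_fixation",
                     "timeline_planning", "timeline_execution")


@dataclass
class DesignMatrix:
    """Named first-level design; ``matrix`` is frames x regressors."""

    matrix: np.ndarray
    columns: list[str]
    frame_times: np.ndarray
    model_variant: str

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.columns,
                            index=self.frame_times)


@dataclass
class GlmResult:
    """OLS estimates: per-regressor betas, residual series, flagged frames."""

    betas: np.ndarray          # regressors x voxels
    residuals: np.ndarray      # frames x voxels
    columns: list[str]
    scrub_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.columns.index(name)]


def canonical_hrf(tr: float, duration: float = 32.0,
                  oversampling: int = 16) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at ``tr``.

    Difference of two gamma densities (response peak delay 6 s, undershoot
    delay 16 s, dispersions 1 s, undershoot ratio 1/6), truncated at
    ``duration`` seconds and normalized to unit peak.
    """
    dt = tr / oversampling
    t = np.arange(0, duration, dt)
    peak = stats.gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    h = h / h.max()
    return h[::oversampling].copy() if oversampling > 1 else h


def _convolve_events(onsets, durations, frame_times, tr,
                     oversampling: int = 16) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the frame times."""
    dt = tr / oversampling
    t_end = frame_times[-1] + tr
    n_fine = int(np.ceil(t_end / dt)) + 1
    box = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(np.round(onset / dt))
        i1 = max(i0 + 1, int(np.round((onset + dur) / dt)))
        if i0 >= n_fine:
            continue
        box[i0:min(i1, n_fine)] = 1.0
    hrf_t = np.arange(0, 32.0, dt)
    h = stats.gamma.pdf(hrf_t, a=6.0, scale=1.0) \
        - stats.gamma.pdf(hrf_t, a=16.0, scale=1.0) / 6.0
    h = h / h.max()
    conv = np.convolve(box, h)[:n_fine]
    idx = np.round(np.asarray(frame_times) / dt).astype(int)
    return conv[np.clip(idx, 0, n_fine - 1)]


def events_from_schedules(schedules) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type, run, episode,
    object) from a list of episode schedules."""
    rows = []
    for s in schedules:
        for j, onset in enumerate(s.object_onsets, start=1):
            rows.append(dict(onset=onset, duration=s.object_duration,
                             trial_type="object", run=s.run_index,
                             episode=s.episode_index, object=j))
        rows.append(dict(onset=s.cross_onset,
                         duration=s.oddeven_onset - s.cross_onset,
                         trial_type="cross_fixation", run=s.run_index,
                         episode=s.episode_index, object=0))
        rows.append(dict(onset=s.oddeven_onset,
                         duration=s.timeline_onset - s.oddeven_onset,
                         trial_type="odd_even_post_fixation", run=s.run_index,
                         episode=s.episode_index, object=0))
        rows.append(dict(onset=s.timeline_onset, duration=s.planning_duration,
                         trial_type="timeline_planning", run=s.run_index,
                         episode=s.episode_index, object=0))
        rows.append(dict(onset=s.timeline_onset + s.planning_duration,
                         duration=s.execution_duration,
                         trial_type="timeline_execution", run=s.run_index,
                         episode=s.episode_index, object=0))
    return pd.DataFrame(rows).sort_values("onset").reset_index(drop=True)


def build_design(events: pd.DataFrame, variant: str,
                 frame_times, tr: float | None = None) -> DesignMatrix:
    """Build the model-one or model-two design matrix from an events table.

    ``variant`` is ``"one"`` (per-object event regressors + four period
    regressors + intercept) or ``"two"`` (per-episode regressors for each
    of the five periods + intercept).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if tr is None:
        tr = float(np.median(np.diff(frame_times)))
    events = events.copy()
    if "run" in events.columns and events["run"].nunique() > 1:
        # concatenate runs on one session timeline (32 s gap for HRF decay)
        offset = 0.0
        for run in sorted(events["run"].unique()):
            sel = events["run"] == run
            run_end = float((events.loc[sel, "onset"]
                             + events.loc[sel, "duration"]).max())
            events.loc[sel, "onset"] += offset
            offset += run_end + 32.0
    cols: list[str] = []
    regs: list[np.ndarray] = []

    def add(name, sub):
        sub = sub.sort_values("onset")
        onsets = sub["onset"].to_numpy(dtype=float)
        durs = sub["duration"].to_numpy(dtype=float)
        if np.any(onsets[1:] < (onsets[:-1] + durs[:-1]) - 1e-9):
            raise ValueError(f"overlapping events in regressor {name!r}")
        cols.append(name)
        regs.append(_convolve_events(onsets, durs, frame_times, tr))

    obj = events[events.trial_type == "object"]
    if variant == "one":
        for _, row in obj.sort_values("onset").iterrows():
            add(f"object_r{int(row.run)}e{int(row.episode):02d}o{int(row.object)}",
                pd.DataFrame([row]))
        for period in MODEL_ONE_PERIODS:
            sub = events[events.trial_type == period]
            if len(sub):
                add(period, sub)
    elif variant == "two":
        periods = ("object",) + MODEL_ONE_PERIODS
        for period in periods:
            sub = events[events.trial_type == period]
            for (run, ep), grp in sub.groupby(["run", "episode"], sort=True):
                name = "stimulus" if period == "object" else period
                add(f"{name}_r{int(run)}e{int(ep):02d}", grp)
    else:
        raise ValueError("variant must be 'one' or 'two'")

    cols.append("intercept")
    regs.append(np.ones_like(frame_times))
    return DesignMatrix(matrix=np.column_stack(regs), columns=cols,
                        frame_times=frame_times, model_variant=variant)


def compute_dvars(series: np.ndarray) -> np.ndarray:
    """DVARS per frame: RMS over voxels of the frame-to-frame difference.

    ``series`` is frames x voxels (or any shape with time first).  The first
    frame has no predecessor; its DVARS is 0 by convention.
    """
    series = np.asarray(series, dtype=float)
    flat = series.reshape(series.shape[0], -1)
    d = np.zeros(flat.shape[0])
    d[1:] = np.sqrt(np.mean(np.diff(flat, axis=0) ** 2, axis=1))
    return d


def dvars_outliers(dvars: np.ndarray) -> np.ndarray:
    """Outlier frames by the box-plot rule: DVARS > Q3 + 1.5 IQR.

    The rule is evaluated on frames 1..T-1 (frame 0 has no DVARS value).
    Returns the flagged frame indices.
    """
    d = np.asarray(dvars, dtype=float)[1:]
    q1, q3 = np.percentile(d, [25, 75])
    thresh = q3 + 1.5 * (q3 - q1)
    return np.where(np.asarray(dvars) > thresh)[0]


def add_spike_regressors(design: DesignMatrix,
                         frames: np.ndarray) -> DesignMatrix:
    """Append one indicator regressor per flagged frame."""
    if len(frames) == 0:
        return design
    mats = [design.matrix]
    cols = list(design.columns)
    n = design.matrix.shape[0]
    for f in frames:
        spike = np.zeros((n, 1))
        spike[int(f), 0] = 1.0
        mats.append(spike)
        cols.append(f"spike_{int(f):04d}")
    return DesignMatrix(matrix=np.hstack(mats), columns=cols,
                        frame_times=design.frame_times,
                        model_variant=design.model_variant)


def fit_glm(series: np.ndarray, design: DesignMatrix,
            scrub: bool = True) -> GlmResult:
    """Ordinary least squares per voxel.

    With ``scrub=True``, DVARS outlier frames get spike regressors before
    fitting.  Raises on a rank-deficient design, naming a dependent column.
    """
    series = np.asarray(series, dtype=float)
    Y = series.reshape(series.shape[0], -1)
    scrub_frames = np.array([], dtype=int)
    if scrub:
        scrub_frames = dvars_outliers(compute_dvars(Y))
        design = add_spike_regressors(design, scrub_frames)
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("series and design have different frame counts")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = design.columns[int(np.argmin(np.abs(np.diag(r))))]
        raise ValueError(
            f"rank-deficient design ({rank}/{X.shape[1]}); "
            f"column {bad!r} is linearly dependent")
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ betas
    return GlmResult(betas=betas, residuals=residuals,
                     columns=list(design.columns), scrub_frames=scrub_frames)
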