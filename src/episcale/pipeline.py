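"""End-to-end convenience pipeline: simulate -> GLM -> searchlight RSA ->
group inference.  Used by the worked examples, the test suite, and the
acceptance script; every stage is also usable on its own."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boldsim import BoldSimSpec, BoldSimResult, simulate_bold
from .design import ExperimentDesign, generate_schedule
from .glm import build_design, events_from_schedules, fit_glm
from .participants import ParticipantModel, simulate_responses
from .rsa import (GroupClusterResult, between_episode_model,
                  between_episode_pairs, build_searchlights,
                  group_cluster_mass, smooth_map, subject_rho_map,
                  within_episode_model, within_episode_pairs)

__all__ = ["SubjectRsaData", "run_subject_glm", "subject_map",
           "simulate_group_study"]


@dataclass
class SubjectRsaData:
    """Condition betas and residuals of one subject, in condition order.

    ``condition_cov`` is the design-induced covariance multiplier of the
    condition betas, block-diagonal over runs: ``(X'X)^-1`` restricted to
    the event regressors.  The pairwise noise multiplier derived from it
    (``C_ii + C_jj - 2 C_ij``) is a deterministic function of the events'
    millisecond timing and is used as the temporal-proximity covariate in
    the within-episode partial correlation.
    """

    betas: np.ndarray          # conditions x in-mask voxels
    residuals: np.ndarray      # frames x in-mask voxels
    bold: BoldSimResult
    schedules: list
    mode: str
    condition_cov: np.ndarray | None = None


def run_subject_glm(schedules, bold: BoldSimResult, mode: str) -> SubjectRsaData:
    """Fit the first-level GLM per run and collect the event betas.

    ``mode`` is ``"within"`` (model one: per-object event betas, ordered
    run/episode/object) or ``"between"`` (model two: per-episode stimulus
    betas).  Residual frames from all runs are concatenated for the noise
    covariance.
    """
    variant = "one" if mode == "within" else "two"
    prefix = "object_" if mode == "within" else "stimulus_"
    mask_flat = bold.mask.reshape(-1)
    beta_rows, resid_rows, cov_blocks = [], [], []
    events = bold.events
    for run in sorted(bold.runs):
        ev = events[events.run == run]
        dm = build_design(ev, variant, bold.frame_times[run], tr=bold.spec.tr)
        series = bold.runs[run].reshape(bold.runs[run].shape[0], -1)
        series = series[:, mask_flat]
        res = fit_glm(series, dm)
        for name in res.columns:
            if name.startswith(prefix):
                beta_rows.append(res.beta(name))
        resid_rows.append(res.residuals)
        idx = [i for i, c in enumerate(res.columns) if c.startswith(prefix)]
        xtx_inv = np.linalg.inv(dm.matrix.T @ dm.matrix)
        cov_blocks.append(xtx_inv[np.ix_(idx, idx)])
    n_cond = sum(b.shape[0] for b in cov_blocks)
    cond_cov = np.zeros((n_cond, n_cond))
    at = 0
    for blk in cov_blocks:
        k = blk.shape[0]
        cond_cov[at:at + k, at:at + k] = blk
        at += k
    return SubjectRsaData(betas=np.vstack(beta_rows),
                          residuals=np.vstack(resid_rows),
                          bold=bold, schedules=schedules, mode=mode,
                          condition_cov=cond_cov)


def subject_map(data: SubjectRsaData, searchlights, mask_shape) -> np.ndarray:
    """Searchlight model-correlation map (Fisher z) for one subject."""
    scheds = data.schedules
    n_episodes = len(scheds)
    n_objects = len(scheds[0].object_ids)
    if data.mode == "within":
        pairs = within_episode_pairs(n_episodes, n_objects)
        model = within_episode_model(data.bold.episode_scaling, pairs,
                                     n_objects)
        # temporal-proximity covariate: the design-induced noise multiplier
        # of each pair's beta difference (a deterministic function of the
        # inter-object millisecond timing within the run)
        C = data.condition_cov
        covariate = (C[pairs[:, 0], pairs[:, 0]]
                     + C[pairs[:, 1], pairs[:, 1]]
                     - 2.0 * C[pairs[:, 0], pairs[:, 1]])
    else:
        pairs = between_episode_pairs(n_episodes)
        model = between_episode_model(data.bold.episode_expansion, pairs)
        covariate = None
    return subject_rho_map(data.betas, data.residuals, searchlights,
                           mask_shape, pairs, model, covariate)


def simulate_group_study(n_subjects: int, design: ExperimentDesign,
                         spec: BoldSimSpec, mode: str, seed: int = 0,
                         participant_noise_sd: float = 0.6,
                         n_perm: int = 1024,
                         smooth_fwhm: float = 6.0) -> GroupClusterResult:
    """Simulate a full group study and run the searchlight RSA inference.

    Each subject gets their own schedule realization and noisy timeline
    responses; BOLD data are simulated with the planted effect strengths in
    ``spec``; model one/two GLMs, searchlight RDMs, model correlations,
    smoothing and sign-flip cluster-mass inference follow.
    """
    rng = np.random.default_rng(seed)
    mask = np.ones(spec.grid_shape, dtype=bool)
    searchlights, _ = build_searchlights(
        mask, voxel_size_mm=spec.voxel_size)
    maps = []
    for si in range(n_subjects):
        d = ExperimentDesign(**{**design.to_dict(),
                                "rng_seed": int(rng.integers(2**31 - 1))})
        scheds = generate_schedule(d)
        pm = ParticipantModel(
            global_scaling_bias=float(np.exp(rng.normal(0.0, 0.15))),
            pattern_noise_sd=participant_noise_sd,
            episode_scaling_bias=float(np.exp(rng.normal(0.0, 0.15))),
            episode_noise_sd=8.0,
            rng_seed=int(rng.integers(2**31 - 1)))
        resp = simulate_responses(scheds, pm, d, participant_id=f"sub-{si:02d}")
        bspec = BoldSimSpec(**{**spec.to_dict(),
                               "rng_seed": int(rng.integers(2**31 - 1))})
        bold = simulate_bold(scheds, resp, bspec)
        data = run_subject_glm(scheds, bold, mode)
        m = subject_map(data, searchlights, spec.grid_shape)
        maps.append(smooth_map(m, mask, fwhm_mm=smooth_fwhm,
                               voxel_size_mm=spec.voxel_size))
    return group_cluster_mass(np.stack(maps), mask, n_perm=n_perm,
                              seed=int(rng.integers(2**31 - 1)))
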