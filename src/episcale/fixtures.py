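"""Serialization of synthetic fixtures: TSV tables, NIfTI volumes, JSON
parameters.  Used for regression tests and for the command-line interface;
fixed seeds give byte-identical tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .boldsim import BoldSimResult, BoldSimSpec
from .design import ExperimentDesign, frame_to_schedules, schedules_to_frame
from .participants import ParticipantModel, ParticipantResponses

__all__ = ["write_fixture_bundle", "read_fixture_bundle",
           "responses_to_frames", "frames_to_responses"]


def responses_to_frames(responses: list[ParticipantResponses]) -> dict[str, pd.DataFrame]:
    """Long-format tables for a set of participant responses."""
    obj_rows, ep_rows, rec_rows, assoc_rows, cov_rows = [], [], [], [], []
    for r in responses:
        for (run, ep), times in sorted(r.object_placements.items()):
            for j, t in enumerate(times, start=1):
                obj_rows.append(dict(participant=r.participant_id, run=run,
                                     episode=ep, object=j, recalled_time=t))
        for run, pos in sorted(r.episode_placements.items()):
            for ep, t in enumerate(pos, start=1):
                ep_rows.append(dict(participant=r.participant_id, run=run,
                                    episode=ep, recalled_time=t))
        for oid in r.recognition_selected:
            rec_rows.append(dict(participant=r.participant_id, object_id=oid))
        for (run, ep), ok in sorted(r.association_correct.items()):
            assoc_rows.append(dict(participant=r.participant_id, run=run,
                                   episode=ep, correct=ok))
        cov_rows.append(dict(participant=r.participant_id, age=r.age,
                             sex=r.sex, prior_fmri=r.prior_fmri,
                             **{f"strategy_{q:02d}": v for q, v in
                                enumerate(r.strategy_scores or [], start=1)}))
    return dict(objects=pd.DataFrame(obj_rows),
                episodes=pd.DataFrame(ep_rows),
                recognition=pd.DataFrame(rec_rows),
                association=pd.DataFrame(assoc_rows),
                covariates=pd.DataFrame(cov_rows))


def frames_to_responses(frames: dict[str, pd.DataFrame]) -> list[ParticipantResponses]:
    """Inverse of :func:`responses_to_frames` (recognition scores are not
    reconstructed; they are recomputed when needed)."""
    obj = frames["objects"]
    required = {"participant", "run", "episode", "object", "recalled_time"}
    if not required <= set(obj.columns):
        raise ValueError(f"objects table missing columns: "
                         f"{sorted(required - set(obj.columns))}")
    out: dict[str, ParticipantResponses] = {}

    def get(pid) -> ParticipantResponses:
        if pid not in out:
            out[pid] = ParticipantResponses(participant_id=pid)
        return out[pid]

    for (pid, run, ep), grp in obj.groupby(["participant", "run", "episode"]):
        grp = grp.sort_values("object")
        get(pid).object_placements[(int(run), int(ep))] = \
            grp.recalled_time.to_numpy(dtype=float)
    eps = frames.get("episodes")
    if eps is not None and len(eps):
        for (pid, run), grp in eps.groupby(["participant", "run"]):
            grp = grp.sort_values("episode")
            get(pid).episode_placements[int(run)] = \
                grp.recalled_time.to_numpy(dtype=float)
    rec = frames.get("recognition")
    if rec is not None and len(rec):
        for pid, grp in rec.groupby("participant"):
            get(pid).recognition_selected = [int(x) for x in grp.object_id]
    assoc = frames.get("association")
    if assoc is not None and len(assoc):
        for pid, grp in assoc.groupby("participant"):
            for _, row in grp.iterrows():
                get(pid).association_correct[
                    (int(row.run), int(row.episode))] = int(row.correct)
    cov = frames.get("covariates")
    if cov is not None and len(cov):
        for _, row in cov.iterrows():
            r = get(row.participant)
            r.age = float(row.get("age", np.nan))
            r.sex = str(row.get("sex", ""))
            r.prior_fmri = int(row.get("prior_fmri", 0))
            strat = [int(row[c]) for c in cov.columns
                     if c.startswith("strategy_")]
            r.strategy_scores = strat or None
    return list(out.values())


def write_fixture_bundle(path, design: ExperimentDesign, schedules,
                         responses: list[ParticipantResponses] | None = None,
                         participants: list[ParticipantModel] | None = None,
                         bold: BoldSimResult | None = None) -> Path:
    """Serialize a synthetic dataset to ``path`` (TSV + NIfTI + JSON)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    schedules_to_frame(schedules).to_csv(path / "schedules.tsv", sep="\t",
                                         index=False)
    params = dict(design=design.to_dict())
    if participants is not None:
        params["participants"] = [p.to_dict() for p in participants]
    if responses is not None:
        for name, frame in responses_to_frames(responses).items():
            frame.to_csv(path / f"responses_{name}.tsv", sep="\t", index=False)
    if bold is not None:
        params["bold"] = bold.spec.to_dict()
        affine = np.diag([bold.spec.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(bold.mask.astype(np.uint8), affine),
                 path / "mask.nii")
        for run, vol in bold.runs.items():
            img = nib.Nifti1Image(
                np.moveaxis(vol, 0, -1).astype(np.float32), affine)
            nib.save(img, path / f"bold_run-{run}.nii")
        bold.events.to_csv(path / "events.tsv", sep="\t", index=False)
    with open(path / "parameters.json", "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
    return path


def read_fixture_bundle(path) -> dict:
    """Read a bundle written by :func:`write_fixture_bundle`."""
    path = Path(path)
    with open(path / "parameters.json") as fh:
        params = json.load(fh)
    design_kwargs = dict(params["design"])
    for key in ("short_interval_range", "long_interval_range"):
        design_kwargs[key] = tuple(design_kwargs[key])
    design = ExperimentDesign(**design_kwargs)
    schedules = frame_to_schedules(
        pd.read_csv(path / "schedules.tsv", sep="\t"))
    out = dict(design=design, schedules=schedules, params=params)
    obj_path = path / "responses_objects.tsv"
    if obj_path.exists():
        frames = {}
        for name in ("objects", "episodes", "recognition", "association",
                     "covariates"):
            p = path / f"responses_{name}.tsv"
            if p.exists() and p.stat().st_size > 1:
                try:
                    frames[name] = pd.read_csv(p, sep="\t")
                except pd.errors.EmptyDataError:
                    continue
        out["responses"] = frames_to_responses(frames)
    if (path / "mask.nii").exists():
        out["mask"] = np.asarray(
            nib.load(path / "mask.nii").dataobj).astype(bool)
        runs = {}
        for p in sorted(path.glob("bold_run-*.nii")):
            run = int(p.stem.split("-")[-1])
            runs[run] = np.moveaxis(np.asarray(nib.load(p).dataobj), -1, 0)
        out["bold_runs"] = runs
        out["events"] = pd.read_csv(path / "events.tsv", sep="\t")
    return out
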