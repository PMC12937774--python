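"""Session directory layout: one EDF per subject plus plain-text metadata.

    <dir>/library.json            stimulus library
    <dir>/subjects.csv            subject_id,group
    <dir>/truth.csv               subject_id,group,stim_id,category_id,delta
    <dir>/<subject>.edf           continuous recording, trials back to back
    <dir>/<subject>_events.csv    trial_index,stim_id,onset_sample

``onset_sample`` is the 0-based sample index of stimulus onset, i.e. trial
start + 2 s of pre-stimulation baseline.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd

from . import edfio
from .simulate import Cohort, TrialRecording
from .stimuli import StimulusSpec, load_library, save_library

PRE_S = 2.0
TRIAL_S = 9.0


def write_session(cohort: Cohort, directory,
                  subject_ids: list[str] | None = None) -> None:
    """Write a cohort as a session directory (streams one trial at a time)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_library(cohort.library, directory / "library.json")
    cohort.ground_truth().to_csv(directory / "truth.csv", index=False)
    with open(directory / "subjects.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "group"])
        for p in cohort.profiles:
            w.writerow([p.subject_id, p.group])

    fs = cohort.config.fs
    names = list(cohort.config.channel_names)
    ids = subject_ids if subject_ids is not None else cohort.subject_ids
    for subject_id in ids:
        with edfio.EdfWriter(directory / f"{subject_id}.edf", fs, names) as w, \
                open(directory / f"{subject_id}_events.csv", "w", newline="") as ef:
            ew = csv.writer(ef)
            ew.writerow(["trial_index", "stim_id", "onset_sample"])
            for trial_idx, trial in enumerate(cohort.iter_trials(subject_id)):
                w.append(trial.data)
                onset = int(trial_idx * TRIAL_S * fs + PRE_S * fs)
                ew.writerow([trial_idx, trial.stim_id, onset])


@dataclass
class Session:
    """A session directory opened for reading; subjects load lazily."""

    directory: Path
    library: list[StimulusSpec]
    subjects: pd.DataFrame  # subject_id, group

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])

    def group(self, subject_id: str) -> str:
        row = self.subjects[self.subjects["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(f"unknown subject: {subject_id}")
        return str(row["group"].iloc[0])

    def events(self, subject_id: str) -> pd.DataFrame:
        path = self.directory / f"{subject_id}_events.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing events file: {path}")
        return pd.read_csv(path)

    def iter_trials(self, subject_id: str) -> Iterator[TrialRecording]:
        edf_path = self.directory / f"{subject_id}.edf"
        if not edf_path.exists():
            raise FileNotFoundError(
                f"missing EDF recording for subject {subject_id}: {edf_path}")
        data, fs, names = edfio.read_edf(edf_path)
        n_trial = int(TRIAL_S * fs)
        for _, row in self.events(subject_id).iterrows():
            start = int(row["onset_sample"]) - int(PRE_S * fs)
            yield TrialRecording(subject_id=subject_id,
                                 stim_id=int(row["stim_id"]),
                                 data=data[:, start:start + n_trial],
                                 fs=fs, channel_names=tuple(names))

    def truth(self) -> pd.DataFrame | None:
        path = self.directory / "truth.csv"
        return pd.read_csv(path) if path.exists() else None


def read_session(directory) -> Session:
    directory = Path(directory)
    lib_path = directory / "library.json"
    if not lib_path.exists():
        raise FileNotFoundError(f"missing stimulus library: {lib_path}")
    subj_path = directory / "subjects.csv"
    if not subj_path.exists():
        raise FileNotFoundError(f"missing subject table: {subj_path}")
    return Session(directory=directory, library=load_library(lib_path),
                   subjects=pd.read_csv(subj_path))
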