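"""Minimal BIDS-style EDF export and import for EEG cohorts.

Writing uses a small native EDF encoder (16-bit samples, physical range
declared in the header, 1 s data records); reading goes through MNE's EDF
reader.  The directory layout mirrors the public resting-state dementia
accession::

    <root>/participants.tsv              # participant_id, Group
    <root>/sub-XXX/eeg/sub-XXX_task-eyesclosed_eeg.edf
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS_1020, default_montage
from .synth import EEGRecording

logger = logging.getLogger(__name__)

#: participants.tsv group codes accepted on read (the public accession uses
#: single letters; synthetic cohorts write full names).
DEFAULT_GROUP_CODES = {
    "A": "AD", "F": "FTD", "C": "HC",
    "AD": "AD", "FTD": "FTD", "HC": "HC",
}


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def write_edf(path: Path, recording: EEGRecording) -> None:
    """Write one recording as a plain (non-plus) 16-bit EDF file."""
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = recording.signal.shape[0]
    n_records = recording.n_samples // fs  # whole 1 s records; remainder dropped
    if n_records < 1:
        raise ValueError("recording shorter than one 1 s data record")

    phys_max = float(np.ceil(max(1.0, np.abs(recording.signal).max() * 1.01)))
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768

    header = b"".join(
        [
            _pad("0", 8),
            _pad(recording.subject_id, 80),
            _pad(f"Startdate 01-JAN-2000 {recording.group}", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (n_ch + 1)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    names = recording.montage.channel_names

    def field(values, width):
        return b"".join(_pad(str(v), width) for v in values)

    header += field([f"EEG {n}" for n in names], 16)
    header += field(["" for _ in names], 80)            # transducer
    header += field(["uV" for _ in names], 8)
    header += field([f"{phys_min:.0f}" for _ in names], 8)
    header += field([f"{phys_max:.0f}" for _ in names], 8)
    header += field([dig_min for _ in names], 8)
    header += field([dig_max for _ in names], 8)
    header += field(["" for _ in names], 80)            # prefiltering
    header += field([fs for _ in names], 8)
    header += field(["" for _ in names], 32)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    data = recording.signal[:, : n_records * fs]
    digital = np.round((data - phys_min) * scale + dig_min).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            chunk = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(chunk.tobytes())  # channel-major within each record


def read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file via MNE; returns (signal in uV, fs, channel names)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), names


def write_cohort_bids(cohort: list[EEGRecording], directory) -> pd.DataFrame:
    """Write per-subject EDFs plus participants.tsv; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = [r.subject_id for r in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in cohort")

    rows = []
    for rec in cohort:
        sub_dir = directory / rec.subject_id / "eeg"
        sub_dir.mkdir(parents=True, exist_ok=True)
        edf_path = sub_dir / f"{rec.subject_id}_task-eyesclosed_eeg.edf"
        write_edf(edf_path, rec)
        rows.append(
            {
                "participant_id": rec.subject_id,
                "Group": rec.group,
                "path": str(edf_path.relative_to(directory)),
            }
        )
    manifest = pd.DataFrame(rows, columns=["participant_id", "Group", "path"])
    manifest[["participant_id", "Group"]].to_csv(
        directory / "participants.tsv", sep="\t", index=False
    )
    return manifest


def read_bids_cohort(
    directory, group_codes: dict[str, str] = DEFAULT_GROUP_CODES
) -> list[EEGRecording]:
    """Read a BIDS-layout EDF cohort; subjects with missing channels are
    rejected (with a logged reason) rather than aborting the run."""
    directory = Path(directory)
    participants = directory / "participants.tsv"
    if not participants.exists():
        raise FileNotFoundError(f"missing participants table: {participants}")
    table = pd.read_csv(participants, sep="\t")
    montage = default_montage()

    cohort: list[EEGRecording] = []
    for _, row in table.iterrows():
        sid, code = str(row["participant_id"]), str(row["Group"])
        if code not in group_codes:
            raise ValueError(f"unknown group code {code!r} for {sid}")
        edf_dir = directory / sid / "eeg"
        matches = sorted(edf_dir.glob("*.edf"))
        if not matches:
            logger.warning("rejecting %s: no EDF file under %s", sid, edf_dir)
            continue
        signal, fs, names = read_edf(matches[0])
        missing = [n for n in CHANNELS_1020 if n not in names]
        if missing:
            logger.warning("rejecting %s: missing channels %s", sid, missing)
            continue
        order = [names.index(n) for n in CHANNELS_1020]
        cohort.append(
            EEGRecording(
                subject_id=sid,
                group=group_codes[code],
                fs=fs,
                signal=signal[order],
                montage=montage,
            )
        )
    return cohort
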