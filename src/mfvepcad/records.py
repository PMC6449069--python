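"""Data model and on-disk formats for multifocal VEP recordings.

A multifocal visual-evoked potential (mfVEP) recording stimulates 60
dartboard sectors of the visual field and extracts, per sector, one evoked
response on each of 6 bipolar occipital channels.  One eye's recording is a
60 x 6 x 600 array of microvolt samples at 1200 Hz (500 ms epochs).

No interchange format exists for mfVEP exports, so records are stored as a
raw little-endian float32 array (row-major, sector x channel x sample) next
to a JSON sidecar carrying the metadata, and a cohort is indexed by a CSV
manifest with columns ``subject_id,eye,label,path``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

N_SECTORS = 60
N_CHANNELS = 6
N_SAMPLES = 600
DEFAULT_FS = 1200.0
DEFAULT_EPOCH_MS = 500.0

EYES = ("OD", "OS")

#: Six eye-level diagnostic classes, ordered by increasing diagnostic certainty
#: (controls, radiologically isolated syndrome, clinically isolated syndrome
#: with/without optic neuritis, definite MS with/without optic neuritis).
EYE_CLASSES = ("Controls", "RIS", "CIS-ON", "CIS-non-ON", "MS-ON", "MS-non-ON")

#: Four subject-level classes (optic-neuritis status is an eye property and is
#: merged away at the subject level).
SUBJECT_CLASSES = ("Controls", "RIS", "CIS", "MS")

_EYE_TO_SUBJECT = {
    "Controls": "Controls",
    "RIS": "RIS",
    "CIS-ON": "CIS",
    "CIS-non-ON": "CIS",
    "MS-ON": "MS",
    "MS-non-ON": "MS",
}


def to_subject_class(eye_class: str) -> str:
    """Map a 6-level eye class onto the 4-level subject class."""
    try:
        return _EYE_TO_SUBJECT[eye_class]
    except KeyError:
        raise FormatError(f"unknown eye class label: {eye_class!r}") from None


@dataclass
class MfVEPRecord:
    """One eye's mfVEP recording block plus identifying metadata.

    Attributes
    ----------
    subject_id : str
        Cohort-unique subject identifier.
    eye : {"OD", "OS"}
        Right (oculus dexter) or left (oculus sinister) eye.
    label : str
        One of :data:`EYE_CLASSES`.
    signal : ndarray, shape (60, 6, 600)
        Microvolt samples; ``signal[s, c, i]`` is sample ``i`` of channel
        ``c`` for visual-field sector ``s`` (sector index 0 == sector 1).
    fs : float
        Sampling rate in Hz.
    epoch_ms : float
        Epoch duration in ms; ``fs * epoch_ms / 1000`` must equal the
        number of samples.
    """

    subject_id: str
    eye: str
    label: str
    signal: np.ndarray
    fs: float = DEFAULT_FS
    epoch_ms: float = DEFAULT_EPOCH_MS

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.eye not in EYES:
            raise FormatError(f"eye must be OD or OS, got {self.eye!r}")
        if self.label not in EYE_CLASSES:
            raise FormatError(f"unknown label {self.label!r}; expected one of {EYE_CLASSES}")
        if self.signal.shape != (N_SECTORS, N_CHANNELS, N_SAMPLES):
            raise FormatError(
                f"signal shape must be {(N_SECTORS, N_CHANNELS, N_SAMPLES)}, "
                f"got {self.signal.shape}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise FormatError("signal contains non-finite values")
        n_expected = self.fs * self.epoch_ms / 1000.0
        if round(n_expected) != N_SAMPLES:
            raise FormatError(
                f"fs*epoch_ms/1000 = {n_expected} does not match {N_SAMPLES} samples"
            )

    @property
    def subject_class(self) -> str:
        return to_subject_class(self.label)

    def copy_with_signal(self, signal: np.ndarray) -> "MfVEPRecord":
        return MfVEPRecord(self.subject_id, self.eye, self.label, signal,
                           fs=self.fs, epoch_ms=self.epoch_ms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MfVEPRecord):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.eye == other.eye
            and self.label == other.label
            and self.fs == other.fs
            and self.epoch_ms == other.epoch_ms
            and np.array_equal(self.signal, other.signal)
        )


def write_record(record: MfVEPRecord, path: str | Path) -> Path:
    """Write a record as raw float32 (little-endian, row-major) + JSON sidecar.

    The sidecar is ``<path>.json``.  The byte layout is deterministic: two
    writes of the same record produce identical files.
    """
    record.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(record.signal, dtype="<f4")
    path.write_bytes(data.tobytes())
    meta = {
        "format": "mfvepcad-record",
        "version": 1,
        "subject_id": record.subject_id,
        "eye": record.eye,
        "label": record.label,
        "fs": record.fs,
        "epoch_ms": record.epoch_ms,
        "shape": [N_SECTORS, N_CHANNELS, N_SAMPLES],
        "dtype": "<f4",
    }
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return path


def read_record(path: str | Path) -> MfVEPRecord:
    """Read a record written by :func:`write_record`, validating shape and metadata."""
    path = Path(path)
    sidecar = path.with_name(path.name + ".json")
    if not path.exists():
        raise FormatError(f"record file not found: {path}")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {sidecar}: {exc}") from exc
    for key in ("subject_id", "eye", "label", "fs", "epoch_ms", "shape", "dtype"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing field {key!r}")
    raw = np.frombuffer(path.read_bytes(), dtype=meta["dtype"])
    expected = int(np.prod(meta["shape"]))
    if raw.size != expected:
        raise FormatError(
            f"{path}: expected {expected} samples for shape {meta['shape']}, got {raw.size}"
        )
    signal = raw.reshape(tuple(meta["shape"])).astype(np.float64)
    if tuple(meta["shape"]) != (N_SECTORS, N_CHANNELS, N_SAMPLES):
        raise FormatError(f"{path}: shape {meta['shape']} violates the 60x6x600 contract")
    return MfVEPRecord(
        subject_id=meta["subject_id"],
        eye=meta["eye"],
        label=meta["label"],
        signal=signal,
        fs=float(meta["fs"]),
        epoch_ms=float(meta["epoch_ms"]),
    )


@dataclass
class CohortManifest:
    """Index of a cohort: one row per eye with the path to its record file."""

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("subject_id", "eye", "label", "path")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        self.table = self.table.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t = self.table
        bad_eye = ~t["eye"].isin(EYES)
        if bad_eye.any():
            raise FormatError(f"invalid eye values: {t.loc[bad_eye, 'eye'].unique()}")
        bad_label = ~t["label"].isin(EYE_CLASSES)
        if bad_label.any():
            raise FormatError(f"invalid labels: {t.loc[bad_label, 'label'].unique()}")
        for sid, grp in t.groupby("subject_id"):
            if len(grp) > 2:
                raise FormatError(f"subject {sid} has {len(grp)} eyes (max 2)")
            if len(grp) == 2 and grp["eye"].nunique() != 2:
                raise FormatError(f"subject {sid} has two records for the same eye")
            sclasses = {to_subject_class(lbl) for lbl in grp["label"]}
            if len(sclasses) != 1:
                raise FormatError(
                    f"subject {sid}: eyes map to different subject classes {sorted(sclasses)}"
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)
        return path

    def load_records(self, root: str | Path | None = None) -> list[MfVEPRecord]:
        """Read every record listed in the manifest (paths relative to ``root``)."""
        root = Path(root) if root is not None else Path(".")
        out = []
        for _, row in self.table.iterrows():
            p = Path(row["path"])
            rec = read_record(p if p.is_absolute() else root / p)
            if (rec.subject_id, rec.eye, rec.label) != (row["subject_id"], row["eye"], row["label"]):
                raise FormatError(
                    f"manifest row {row['subject_id']}/{row['eye']} disagrees with "
                    f"record metadata at {row['path']}"
                )
            out.append(rec)
        return out

    def __len__(self) -> int:
        return len(self.table)
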