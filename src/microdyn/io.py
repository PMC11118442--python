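"""EEG containers and file I/O.

The central container is :class:`EEGRecording`, a channels x samples matrix in
microvolts with its sampling rate and channel names.  Two on-disk formats are
supported: standard EDF (read through :mod:`mne`) and a plain delimited text
matrix whose first line is ``# fs=<Hz>``, second line the channel names, and
each following line one channel's samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, ParameterError, StructureError

GROUP_LABELS = ("HC", "FTD", "AD", "synthetic")


@dataclass
class EEGRecording:
    """Multichannel EEG segment.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        One unique name per row of ``data``.
    subject_id
        Free-form identifier.
    group_label
        One of ``HC``, ``FTD``, ``AD`` or ``synthetic``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = ""
    group_label: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = list(self.channel_names)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 2:
            raise ParameterError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("data contains NaN or Inf")
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.data.shape[0] < 2:
            raise ParameterError("need at least 2 channels")
        if len(self.channel_names) != self.data.shape[0]:
            raise StructureError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise StructureError("channel names are not unique")
        if self.group_label not in GROUP_LABELS:
            raise ParameterError(f"unknown group label {self.group_label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        """Copy of this recording with new samples (and optionally new fs)."""
        return replace(self, data=np.asarray(data, float),
                       fs=self.fs if fs is None else fs,
                       channel_names=list(self.channel_names))


def load_eeg(path, format: str = "delimited_matrix", subject_id: str = "",
             group_label: str = "synthetic") -> EEGRecording:
    """Read an EEG recording from ``path``.

    ``format`` is ``"edf"`` (standard European Data Format, via mne) or
    ``"delimited_matrix"`` (the text dialect documented in this module).
    """
    if format == "edf":
        return _load_edf(path, subject_id, group_label)
    if format in ("delimited_matrix", "tsv", "csv"):
        return _load_delimited(path, subject_id, group_label)
    raise ParameterError(f"unknown format {format!r}")


def _load_edf(path, subject_id, group_label) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of types on bad files
        raise FormatError(f"could not read EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return EEGRecording(data=data_uv, fs=float(raw.info["sfreq"]),
                        channel_names=list(raw.ch_names),
                        subject_id=subject_id, group_label=group_label)


def _load_delimited(path, subject_id, group_label) -> EEGRecording:
    try:
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    except OSError as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    if len(lines) < 3:
        raise FormatError(f"{path}: need a fs line, a header and data rows")
    if not lines[0].lstrip("# ").startswith("fs="):
        raise FormatError(f"{path}: first line must be '# fs=<Hz>'")
    try:
        fs = float(lines[0].split("=", 1)[1])
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable fs line {lines[0]!r}") from exc
    delim = "\t" if "\t" in lines[1] else ","
    names = [c.strip() for c in lines[1].split(delim)]
    rows = []
    for ln in lines[2:]:
        try:
            rows.append([float(v) for v in ln.split(delim)])
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable data line") from exc
    if len(rows) != len(names):
        raise StructureError(
            f"{path}: {len(names)} channel names but {len(rows)} data rows")
    n = len(rows[0])
    if any(len(r) != n for r in rows):
        raise StructureError(f"{path}: ragged rows")
    return EEGRecording(data=np.array(rows, float), fs=fs, channel_names=names,
                        subject_id=subject_id, group_label=group_label)


def save_eeg(rec: EEGRecording, path, delimiter: str = "\t") -> None:
    """Write a recording in the delimited text dialect read by load_eeg."""
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write(delimiter.join(rec.channel_names) + "\n")
        for row in rec.data:
            fh.write(delimiter.join(f"{v:.10g}" for v in row) + "\n")
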