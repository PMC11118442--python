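"""Resting-state EEG preprocessing chain.

The chain is: zero-phase band filtering (0.3 Hz high-pass, 70 Hz low-pass,
49.8-50.2 Hz mains notch, all 5th-order Butterworth applied forward-backward),
anti-aliased polyphase downsampling to 250 Hz, average re-referencing, and
extraction of a fixed-length analysis segment (180 s by default).

Zero-phase filtering is used throughout so that the topographic timing the
microstate segmentation depends on is not shifted by group delay.  Artifact
removal by independent-component rejection is inherently manual and is exposed
only as a pass-through hook (:func:`remove_artifacts`) accepting externally
cleaned data.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import BoundsError, ParameterError
from .io import EEGRecording

HIGHPASS_HZ = 0.3
LOWPASS_HZ = 70.0
NOTCH_BAND_HZ = (49.8, 50.2)
FILTER_ORDER = 5
DEFAULT_FS = 250.0
DEFAULT_SEGMENT_S = 180.0


def apply_filters(rec: EEGRecording) -> EEGRecording:
    """Band-limit a recording to 0.3-70 Hz and notch out 50 Hz mains.

    All three filters are Butterworth designs applied with ``sosfiltfilt``
    (forward-backward, zero phase).  Requires ``fs > 140`` Hz so the 70 Hz
    low-pass cutoff stays below Nyquist.
    """
    if rec.fs <= 2 * LOWPASS_HZ:
        raise ParameterError(
            f"fs={rec.fs} Hz too low for a {LOWPASS_HZ} Hz low-pass")
    hp = signal.butter(FILTER_ORDER, HIGHPASS_HZ, "highpass", fs=rec.fs,
                       output="sos")
    lp = signal.butter(FILTER_ORDER, LOWPASS_HZ, "lowpass", fs=rec.fs,
                       output="sos")
    notch = signal.butter(2, NOTCH_BAND_HZ, "bandstop", fs=rec.fs,
                          output="sos")
    out = rec.data
    for sos in (hp, lp, notch):
        out = signal.sosfiltfilt(sos, out, axis=1)
    return rec.with_data(out)


def resample_to(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Downsample with polyphase anti-aliasing FIR decimation."""
    if target_fs > rec.fs:
        raise ParameterError(
            f"no upsampling: target {target_fs} Hz > source {rec.fs} Hz")
    if target_fs == rec.fs:
        return rec.with_data(rec.data.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                               axis=1)
    return rec.with_data(out, fs=float(target_fs))


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference so the mean across channels is zero at every sample."""
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def select_segment(rec: EEGRecording, duration_s: float = DEFAULT_SEGMENT_S,
                   offset_s: float = 0.0) -> EEGRecording:
    """Cut a contiguous ``duration_s`` window starting at ``offset_s``."""
    start = int(round(offset_s * rec.fs))
    n = int(round(duration_s * rec.fs))
    if start < 0 or start + n > rec.n_samples:
        raise BoundsError(
            f"window [{offset_s}, {offset_s + duration_s}] s outside the "
            f"{rec.duration_s:.3f} s recording")
    return rec.with_data(rec.data[:, start:start + n])


def remove_artifacts(rec: EEGRecording) -> EEGRecording:
    """Artifact-removal hook.

    Component-based artifact rejection requires visual curation and is out of
    scope; this hook passes data through unchanged so externally cleaned
    recordings slot into the pipeline at the same point.
    """
    return rec


def preprocess(rec: EEGRecording, target_fs: float = DEFAULT_FS,
               duration_s: float | None = DEFAULT_SEGMENT_S,
               offset_s: float = 0.0) -> EEGRecording:
    """Full chain: filter, downsample, average-reference, cut segment.

    ``duration_s=None`` keeps the whole (filtered, re-referenced) recording.
    """
    out = apply_filters(rec)
    out = resample_to(out, target_fs)
    out = average_reference(out)
    out = remove_artifacts(out)
    if duration_s is not None:
        out = select_segment(out, duration_s, offset_s)
    return out
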