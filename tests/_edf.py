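"""Minimal EDF writer for generating synthetic test fixtures.

Only used to produce small, valid EDF files at test time (no installed
package writes EDF; reading goes through mne).  Supports one physical
range for all channels and whole-second records.
"""

from __future__ import annotations

import numpy as np


def write_edf(path, data_uv: np.ndarray, fs: int,
              channel_names: list[str], phys_amp: float = 200.0) -> None:
    """Write ``data_uv`` (channels x samples, microvolts) as EDF.

    Samples are quantized to int16 over the symmetric physical range
    ``[-phys_amp, +phys_amp]`` microvolts; the sample count is truncated to
    whole 1-second records.
    """
    data_uv = np.asarray(data_uv, float)
    n_ch, n_samp = data_uv.shape
    fs = int(fs)
    n_records = n_samp // fs
    if n_records < 1:
        raise ValueError("need at least one full second of data")
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header_bytes = 256 * (1 + n_ch)
    head = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate 01-JAN-2000 X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(header_bytes), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    fields = [
        [pad(name, 16) for name in channel_names],
        [pad("", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{-phys_amp:g}", 8)] * n_ch,
        [pad(f"{phys_amp:g}", 8)] * n_ch,
        [pad(str(dig_min), 8)] * n_ch,
        [pad(str(dig_max), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(fs), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    scale = (dig_max - dig_min) / (2.0 * phys_amp)
    digital = np.clip((data_uv + phys_amp) * scale + dig_min,
                      dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(head)
        for block in fields:
            fh.write(b"".join(block))
        for r in range(n_records):
            chunk = digital[:, r * fs:(r + 1) * fs]
            fh.write(chunk.tobytes())
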