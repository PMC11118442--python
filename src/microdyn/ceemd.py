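"""Complementary ensemble empirical mode decomposition (CEEMD).

EMD decomposes a series into intrinsic mode functions (IMFs) by iteratively
sifting: cubic-spline envelopes are fit through the local maxima and minima,
their mean is subtracted, and the process repeats until a Cauchy-type
stopping criterion is met.  CEEMD stabilizes EMD against mode mixing by
decomposing an ensemble of copies with paired +noise/-noise white-noise
realizations added, then averaging IMFs index-wise; because the noise enters
in complementary pairs, the averaged decomposition still sums exactly to the
source signal.

Numerical choices: sifting stops when the normalized squared change between
consecutive sift iterates drops below 0.2 (capped at 50 sifts per IMF);
extraction stops when the residue has fewer than 3 extrema; spline end
effects are controlled by mirroring two extrema beyond each boundary.  The
noise amplitude is ``noise_std_rel`` times the channel's standard deviation
(0.1 by default), with 100 complementary pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ParameterError
from .io import EEGRecording

SD_THRESHOLD = 0.2
MAX_SIFTS = 50
DEFAULT_NOISE_STD_REL = 0.1
DEFAULT_N_ENSEMBLE = 100


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima; plateaus collapse to one
    extremum at the plateau edge."""
    d = np.diff(x)
    s = np.sign(d)
    # forward-fill zero slopes so plateaus inherit the preceding trend
    nz = np.nonzero(s)[0]
    if nz.size == 0:
        return np.empty(0, int), np.empty(0, int)
    filled = s.copy()
    idx = np.where(s != 0, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    valid = idx >= 0
    filled[valid] = s[idx[valid]]
    sc = np.diff(filled)
    maxima = np.nonzero(sc < 0)[0] + 1
    minima = np.nonzero(sc > 0)[0] + 1
    return maxima, minima


def _envelope(idx: np.ndarray, x: np.ndarray, n: int) -> np.ndarray | None:
    """Cubic-spline envelope through extrema, mirror-extended at both ends."""
    if idx.size < 2:
        return None
    k = min(2, idx.size)
    t = idx.astype(float)
    v = x[idx]
    # mirror extrema about the first and last sample
    tl = -t[:k][::-1]
    vl = v[:k][::-1]
    tr = 2.0 * (n - 1) - t[-k:][::-1]
    vr = v[-k:][::-1]
    tt = np.concatenate([tl, t, tr])
    vv = np.concatenate([vl, v, vr])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    tt, vv = tt[keep], vv[keep]
    if tt.size < 2:
        return None
    if tt.size < 4:
        return np.interp(np.arange(n), tt, vv)
    return CubicSpline(tt, vv)(np.arange(n))


def emd(x: np.ndarray, max_imfs: int | None = None,
        sd_threshold: float = SD_THRESHOLD,
        max_sifts: int = MAX_SIFTS) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose a 1-D series into IMFs plus a residue.

    Returns ``(imfs, residue)`` with ``sum(imfs) + residue == x`` to float
    rounding.  A constant or monotone input yields no IMFs.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("emd expects a 1-D series")
    if x.size < 10:
        raise ParameterError("series too short for EMD")
    if not np.all(np.isfinite(x)):
        raise ParameterError("series contains NaN or Inf")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    n = x.size
    while max_imfs is None or len(imfs) < max_imfs:
        mx, mn = _local_extrema(residue)
        if mx.size + mn.size < 3:
            break
        h = residue.copy()
        for _ in range(max_sifts):
            mx, mn = _local_extrema(h)
            upper = _envelope(mx, h, n)
            lower = _envelope(mn, h, n)
            if upper is None or lower is None:
                break
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            sd = float(np.sum(mean_env * mean_env)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        residue = residue - h
    return imfs, residue


def ceemd(x: np.ndarray, noise_std_rel: float = DEFAULT_NOISE_STD_REL,
          n_ensemble: int = DEFAULT_N_ENSEMBLE, seed: int = 0,
          max_imfs: int | None = None
          ) -> tuple[list[np.ndarray], np.ndarray]:
    """Complementary-ensemble EMD of a 1-D series.

    For each of ``n_ensemble`` white-noise realizations ``N_i`` (sd =
    ``noise_std_rel`` x sd(x)), both ``x + N_i`` and ``x - N_i`` are
    decomposed by :func:`emd`; the j-th output IMF is the mean of the j-th
    IMFs over all ``2 * n_ensemble`` decompositions (shorter decompositions
    padded with zero IMFs), and likewise for the residue.  Deterministic for
    a given seed.
    """
    x = np.asarray(x, dtype=float)
    if n_ensemble < 1:
        raise ParameterError("n_ensemble must be >= 1")
    rng = np.random.default_rng(seed)
    sd = noise_std_rel * float(np.std(x))
    imf_stacks: list[list[np.ndarray]] = []
    residues: list[np.ndarray] = []

    def _accumulate(sig: np.ndarray) -> None:
        imfs, res = emd(sig, max_imfs=max_imfs)
        for j, imf in enumerate(imfs):
            if j >= len(imf_stacks):
                imf_stacks.append([])
            imf_stacks[j].append(imf)
        residues.append(res)

    for _ in range(n_ensemble):
        noise = rng.standard_normal(x.size) * sd
        _accumulate(x + noise)
        _accumulate(x - noise)

    n_dec = 2 * n_ensemble
    out_imfs = [np.sum(stack, axis=0) / n_dec for stack in imf_stacks]
    out_res = np.sum(residues, axis=0) / n_dec
    return out_imfs, out_res


@dataclass
class IMFSet:
    """Channel-aligned IMFs of a multichannel recording.

    ``imfs[j]`` is the (channels x samples) matrix of the j-th mode, index 0
    being the highest-frequency mode; ``residue`` completes the
    reconstruction: ``sum(imfs) + residue == source``.
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    noise_std_rel: float
    n_ensemble: int
    seed: int
    fs: float
    channel_names: list[str]

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out

    def imf_recording(self, index: int, like: EEGRecording) -> EEGRecording:
        """Wrap IMF ``index`` (1-based, as modes are conventionally numbered)
        as an EEGRecording for downstream microstate analysis."""
        if not 1 <= index <= self.n_imfs:
            raise ParameterError(f"IMF index {index} outside 1..{self.n_imfs}")
        return like.with_data(self.imfs[index - 1])


def ceemd_recording(rec: EEGRecording,
                    noise_std_rel: float = DEFAULT_NOISE_STD_REL,
                    n_ensemble: int = DEFAULT_N_ENSEMBLE, seed: int = 0,
                    max_imfs: int | None = None) -> IMFSet:
    """Channel-wise CEEMD with a common IMF count.

    Channels that decompose into fewer modes than the per-recording maximum
    are padded with zero IMFs so mode indices align across channels.
    """
    child_seeds = np.random.SeedSequence(seed).spawn(rec.n_channels)
    per_channel: list[tuple[list[np.ndarray], np.ndarray]] = []
    for c in range(rec.n_channels):
        x = rec.data[c]
        if np.allclose(x, 0.0):
            per_channel.append(([], np.zeros_like(x)))
            continue
        rng_seed = child_seeds[c]
        imfs, res = ceemd(x, noise_std_rel, n_ensemble,
                          seed=rng_seed, max_imfs=max_imfs)
        per_channel.append((imfs, res))
    n_imfs = max((len(im) for im, _ in per_channel), default=0)
    shape = rec.data.shape
    imf_mats = [np.zeros(shape) for _ in range(n_imfs)]
    res_mat = np.zeros(shape)
    for c, (imfs, res) in enumerate(per_channel):
        for j, imf in enumerate(imfs):
            imf_mats[j][c] = imf
        res_mat[c] = res
    return IMFSet(imfs=imf_mats, residue=res_mat,
                  noise_std_rel=noise_std_rel, n_ensemble=n_ensemble,
                  seed=seed, fs=rec.fs,
                  channel_names=list(rec.channel_names))


def spectral_centroid(x: np.ndarray, fs: float) -> float:
    """Power-weighted mean frequency of a 1-D series (Hz)."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    total = spec.sum()
    if total == 0:
        return 0.0
    return float((freqs * spec).sum() / total)
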