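"""Synthetic multichannel EEG with known microstate structure.

The generator emulates the assumptions behind topographic microstate
analysis: a small set of fixed scalp maps, piecewise-constant activation with
durations in the 30-100 ms regime, slow amplitude (GFP) modulation, and an
additive 1/f^alpha noise floor.  Because the generating templates, label
sequence, and transition structure are known exactly, clustering, backfitting,
sequence statistics and score prediction can all be validated against ground
truth without any external data.

State durations follow a gamma law with shape 4 (unimodal, bounded away from
zero) rather than an exponential, matching the segment-duration regime that
the 30 ms label smoothing step assumes.  Pink noise is synthesized by
spectral shaping of white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import EEGRecording

#: gamma shape for state durations; scale is mean/shape
DURATION_GAMMA_SHAPE = 4.0


def uniform_transition_matrix(k: int) -> np.ndarray:
    """Row-stochastic matrix with zero diagonal and equal off-diagonal mass."""
    p = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(p, 0.0)
    return p


def cycle_transition_matrix(k: int) -> np.ndarray:
    """Deterministic cycle 0 -> 1 -> ... -> k-1 -> 0."""
    p = np.zeros((k, k))
    for i in range(k):
        p[i, (i + 1) % k] = 1.0
    return p


def structured_transition_matrix(k: int, structure: float) -> np.ndarray:
    """Interpolate between uniform (structure=0) and a pure cycle (1)."""
    if not 0.0 <= structure <= 1.0:
        raise ParameterError("structure must lie in [0, 1]")
    return (structure * cycle_transition_matrix(k)
            + (1.0 - structure) * uniform_transition_matrix(k))


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording.

    ``transition_matrix=None`` means uniform off-diagonal transitions.
    ``snr`` is the linear ratio of signal RMS to noise RMS; ``noise_exponent``
    is the spectral slope alpha of the 1/f^alpha background.
    """

    n_channels: int = 19
    k_states: int = 4
    fs: float = 250.0
    duration_s: float = 180.0
    mean_state_duration_ms: float = 80.0
    transition_matrix: np.ndarray | None = None
    snr: float = 3.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_states < 2:
            raise ParameterError("k_states must be >= 2")
        if self.snr <= 0:
            raise ParameterError("snr must be positive")
        if self.transition_matrix is not None:
            p = np.asarray(self.transition_matrix, float)
            if p.shape != (self.k_states, self.k_states):
                raise ParameterError("transition_matrix must be k x k")
            if np.any(np.diag(p) != 0):
                raise ParameterError("transition_matrix diagonal must be 0")
            if not np.allclose(p.sum(axis=1), 1.0):
                raise ParameterError("transition_matrix rows must sum to 1")
            self.transition_matrix = p

    def resolved_transition_matrix(self) -> np.ndarray:
        if self.transition_matrix is None:
            return uniform_transition_matrix(self.k_states)
        return self.transition_matrix


def make_templates(spec: SyntheticSpec) -> np.ndarray:
    """Draw ``k_states`` average-referenced, unit-GFP, mutually orthogonal
    template maps (orthogonality in the zero-mean channel subspace, so all
    pairwise spatial correlations are zero)."""
    k, c = spec.k_states, spec.n_channels
    if k > c - 1:
        raise ParameterError(
            f"cannot place {k} orthogonal zero-mean maps on {c} channels")
    rng = np.random.default_rng(spec.seed)
    basis = []
    while len(basis) < k:
        v = rng.standard_normal(c)
        v -= v.mean()
        for b in basis:
            v -= (v @ b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    t = np.array(basis)
    # unit GFP: spatial SD over channels = 1  =>  ||row|| = sqrt(C)
    return t * np.sqrt(c)


def make_label_sequence(spec: SyntheticSpec,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-sample state labels from a semi-Markov chain.

    Durations (ms) are gamma(shape 4) with mean ``mean_state_duration_ms``;
    the successor state is drawn from the transition matrix row.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = spec.resolved_transition_matrix()
    n_total = int(round(spec.duration_s * spec.fs))
    scale_ms = spec.mean_state_duration_ms / DURATION_GAMMA_SHAPE
    labels = np.empty(n_total, dtype=np.int64)
    state = int(rng.integers(spec.k_states))
    pos = 0
    while pos < n_total:
        dur_ms = rng.gamma(DURATION_GAMMA_SHAPE, scale_ms)
        n = max(1, int(round(dur_ms * spec.fs / 1000.0)))
        labels[pos:pos + n] = state
        pos += n
        state = int(rng.choice(spec.k_states, p=p[state]))
    return labels


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                alpha: float) -> np.ndarray:
    """Spatially white, temporally 1/f^alpha noise via spectral shaping."""
    c, n = shape
    white = rng.standard_normal((c, n))
    spec_w = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    gain = np.ones_like(freqs)
    gain[1:] = freqs[1:] ** (-alpha / 2.0)
    gain[0] = 0.0  # no DC
    noise = np.fft.irfft(spec_w * gain, n=n, axis=1)
    return noise / noise.std()


def synthesize_eeg(templates: np.ndarray, labels: np.ndarray,
                   spec: SyntheticSpec,
                   rng: np.random.Generator | None = None,
                   subject_id: str = "synthetic",
                   group_label: str = "synthetic") -> EEGRecording:
    """Render labels into channel data: a(t) * template[label(t)] + noise.

    ``a(t)`` is a smooth positive amplitude envelope (slow sinusoidal GFP
    modulation); noise is average-referenced 1/f^alpha, scaled so the global
    signal/noise RMS ratio equals ``spec.snr``.
    """
    if labels.max() >= templates.shape[0]:
        raise ParameterError("label alphabet exceeds template count")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n = len(labels)
    t = np.arange(n) / spec.fs
    phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.4 * np.sin(2 * np.pi * 0.3 * t + phase)
    sig = envelope * templates[labels].T  # (C, n)
    if np.isfinite(spec.snr):
        noise = _pink_noise(rng, sig.shape, spec.noise_exponent)
        noise -= noise.mean(axis=0, keepdims=True)  # keep average reference
        noise *= np.sqrt(np.mean(sig ** 2)) / (spec.snr * noise.std())
        data = sig + noise
    else:
        data = sig
    return EEGRecording(data=data, fs=spec.fs,
                        channel_names=[f"CH{i + 1:02d}"
                                       for i in range(sig.shape[0])],
                        subject_id=subject_id, group_label=group_label)


#: per-group range of the transition-structure parameter used by make_cohort
GROUP_STRUCTURE = {"HC": (0.70, 0.90), "FTD": (0.35, 0.55),
                   "AD": (0.05, 0.25)}

#: default linear score model: score = intercept + structure_coef * structure
DEFAULT_SCORE_MODEL = {"intercept": 18.0, "structure_coef": 14.0,
                       "noise_sd": 1.0}


@dataclass
class Cohort:
    """Synthetic study cohort: recordings, ground-truth labels, score table."""

    records: list
    labels: list
    table: pd.DataFrame  # subject_id, group, score, structure, duration_ms


def make_cohort(n_per_group: dict[str, int],
                base_spec: SyntheticSpec | None = None,
                score_model: dict | None = None,
                seed: int = 0,
                synthesize: bool = True) -> Cohort:
    """Generate a cohort whose transition structure differs by group.

    Each subject gets a transition matrix interpolated between a cycle and
    uniform by a per-subject ``structure`` parameter drawn from the group's
    range, and a cognitive score that is a stated linear function of that
    parameter plus Gaussian noise.  ``synthesize=False`` skips rendering the
    channel data (labels and scores only), for sequence-level experiments.
    """
    if base_spec is None:
        base_spec = SyntheticSpec()
    if score_model is None:
        score_model = dict(DEFAULT_SCORE_MODEL)
    unknown = set(n_per_group) - set(GROUP_STRUCTURE)
    if unknown:
        raise ParameterError(f"unknown groups {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    # one template set shared by the whole cohort, as canonical maps are
    shared_templates = make_templates(
        SyntheticSpec(n_channels=base_spec.n_channels,
                      k_states=base_spec.k_states, seed=seed))
    records, labels, rows = [], [], []
    for group in sorted(n_per_group):
        lo, hi = GROUP_STRUCTURE[group]
        for i in range(n_per_group[group]):
            structure = rng.uniform(lo, hi)
            dur = base_spec.mean_state_duration_ms * rng.uniform(0.9, 1.1)
            sub_spec = SyntheticSpec(
                n_channels=base_spec.n_channels, k_states=base_spec.k_states,
                fs=base_spec.fs, duration_s=base_spec.duration_s,
                mean_state_duration_ms=dur,
                transition_matrix=structured_transition_matrix(
                    base_spec.k_states, structure),
                snr=base_spec.snr, noise_exponent=base_spec.noise_exponent,
                seed=int(rng.integers(2 ** 31)))
            lab = make_label_sequence(sub_spec, rng)
            sid = f"{group}{i + 1:03d}"
            score = (score_model["intercept"]
                     + score_model["structure_coef"] * structure
                     + rng.normal(0.0, score_model["noise_sd"]))
            if synthesize:
                records.append(synthesize_eeg(shared_templates, lab,
                                              sub_spec, rng,
                                              subject_id=sid,
                                              group_label=group))
            labels.append(lab)
            rows.append({"subject_id": sid, "group": group, "score": score,
                         "structure": structure, "duration_ms": dur})
    return Cohort(records=records, labels=labels,
                  table=pd.DataFrame(rows))
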