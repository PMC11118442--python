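"""EEG microstate segmentation and temporal statistics.

Topographies at global-field-power (GFP) peaks are clustered into K template
maps with a polarity-invariant modified K-means: assignment maximizes the
squared spatial correlation between a map and its template, and each template
is updated to the dominant spatial pattern (first principal direction) of its
assigned maps.  Templates are then backfit to every frame by winner-takes-all
absolute spatial correlation, weakly fitting frames are left unlabeled, and
short label runs are reassigned by global map dissimilarity (GMD) so that no
microstate survives below the minimum plausible duration.

Conventions: maps are always average-referenced before correlation; GFP is
the population spatial standard deviation; all ties break toward the lowest
class index for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_uppercase

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import EmptyResultError, ParameterError
from .io import EEGRecording

UNLABELED = -1
DEFAULT_K = 4
DEFAULT_RESTARTS = 50
DEFAULT_MAX_ITER = 1000
DEFAULT_TOL = 1e-6
DEFAULT_MIN_PEAK_DISTANCE_MS = 10.0
DEFAULT_MAX_PEAKS = 2000
DEFAULT_REJECT_BELOW = 0.5
DEFAULT_MIN_DURATION_MS = 30.0


@dataclass
class MicrostateModel:
    """K template maps plus fit metadata."""

    templates: np.ndarray  # (K, C), rows average-referenced
    labels_order: list[str]
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, float)
        if self.templates.ndim != 2 or self.templates.shape[0] < 1:
            raise ParameterError("templates must be a K x C matrix")
        if np.any(gfp_of_maps(self.templates) <= 0):
            raise ParameterError("every template must have positive GFP")

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


@dataclass
class LabelSequence:
    """Per-sample microstate labels with winner correlations.

    ``labels`` holds class indices, or :data:`UNLABELED` (-1) where the best
    template correlated below the rejection threshold.
    """

    labels: np.ndarray
    fs: float
    correlations: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.correlations = np.asarray(self.correlations, float)
        if self.labels.shape != self.correlations.shape:
            raise ParameterError("labels and correlations must align")
        if np.any((self.correlations < 0) | (self.correlations > 1 + 1e-12)):
            raise ParameterError("correlations must lie in [0, 1]")


def _demean(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=-1, keepdims=True)


def gfp_of_maps(maps: np.ndarray) -> np.ndarray:
    """GFP of each row: population SD across channels after re-referencing."""
    d = _demean(np.asarray(maps, float))
    return np.sqrt(np.mean(d * d, axis=-1))


def gfp(rec: EEGRecording) -> np.ndarray:
    """Global field power series: spatial SD across channels per sample."""
    d = rec.data - rec.data.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(d * d, axis=0))


def spatial_correlation(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between two stacks of maps.

    Accepts (C,), (N, C) against (C,) or (M, C); returns scalar, (N,), or
    (N, M).  Zero-variance maps correlate 0 with everything.
    """
    a_1d = np.ndim(maps_a) == 1
    b_1d = np.ndim(maps_b) == 1
    a = np.atleast_2d(_demean(np.asarray(maps_a, float)))
    b = np.atleast_2d(_demean(np.asarray(maps_b, float)))
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    na[na == 0] = np.inf
    nb[nb == 0] = np.inf
    out = (a / na) @ (b / nb).T
    if a_1d and b_1d:
        return float(out[0, 0])
    if b_1d:
        return out[:, 0]
    if a_1d:
        return out[0, :]
    return out


def extract_gfp_peaks(rec: EEGRecording,
                      min_peak_distance_ms: float = DEFAULT_MIN_PEAK_DISTANCE_MS,
                      max_peaks: int = DEFAULT_MAX_PEAKS,
                      sd_exclusion: float = 1.0) -> np.ndarray:
    """Frame indices of GFP peaks used for clustering.

    Local maxima separated by at least ``min_peak_distance_ms``; peaks whose
    GFP exceeds ``mean + sd_exclusion * SD`` of the GFP series are excluded
    (high-amplitude frames are more likely artifactual); if more than
    ``max_peaks`` survive, a uniformly spaced subsample of exactly
    ``max_peaks`` is kept.
    """
    from scipy.signal import find_peaks

    if rec.n_samples < rec.fs:
        raise ParameterError("recording shorter than 1 s")
    g = gfp(rec)
    distance = max(1, int(np.ceil(min_peak_distance_ms * rec.fs / 1000.0)))
    peaks, _ = find_peaks(g, distance=distance)
    if peaks.size == 0:
        raise EmptyResultError("no GFP peaks found")
    cutoff = g.mean() + sd_exclusion * g.std()
    peaks = peaks[g[peaks] <= cutoff]
    if peaks.size == 0:
        raise EmptyResultError("all GFP peaks excluded by the SD rule")
    if peaks.size > max_peaks:
        sel = np.linspace(0, peaks.size - 1, max_peaks).round().astype(int)
        peaks = peaks[np.unique(sel)]
    return peaks


def _principal_pattern(maps: np.ndarray) -> np.ndarray:
    """First principal direction of a stack of zero-mean maps, sign-fixed."""
    # right singular vector of the (n, C) stack
    _, _, vt = np.linalg.svd(maps, full_matrices=False)
    v = vt[0]
    # deterministic sign: largest-magnitude component positive
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v


def modified_kmeans(maps: np.ndarray, k: int = DEFAULT_K,
                    restarts: int = DEFAULT_RESTARTS,
                    max_iter: int = DEFAULT_MAX_ITER,
                    tol: float = DEFAULT_TOL, seed: int = 0
                    ) -> MicrostateModel:
    """Polarity-invariant modified K-means over GFP-peak maps.

    Each map is assigned to the template with the largest squared spatial
    correlation; each template is re-estimated as the first principal
    direction of its assigned maps.  A restart converges when the relative
    change in residual (noise) variance drops below ``tol``; the best of
    ``restarts`` runs by global explained variance (GEV) wins.
    """
    maps = _demean(np.asarray(maps, float))
    n, c = maps.shape
    if n < k:
        raise ParameterError(f"{n} maps cannot support {k} clusters")
    norms = np.linalg.norm(maps, axis=1)
    keep = norms > 0
    maps_n = np.zeros_like(maps)
    maps_n[keep] = maps[keep] / norms[keep, None]
    total_power = float(np.sum(norms ** 2))
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, dict] | None = None
    for restart in range(restarts):
        init = rng.choice(n, size=k, replace=False)
        templates = maps_n[init].copy()
        # guard degenerate zero-norm picks
        for j in range(k):
            if np.linalg.norm(templates[j]) == 0:
                templates[j] = maps_n[int(rng.choice(np.nonzero(keep)[0]))]
        prev_noise = np.inf
        assignment = np.zeros(n, dtype=int)
        n_iter = 0
        gev_trace: list[float] = []
        for n_iter in range(1, max_iter + 1):
            tn = templates / np.linalg.norm(templates, axis=1, keepdims=True)
            corr = maps_n @ tn.T  # (n, k)
            assignment = np.argmax(corr ** 2, axis=1)
            proj = corr[np.arange(n), assignment] * norms
            gev_trace.append(float(np.sum(proj ** 2)) / total_power)
            noise_var = (total_power - float(np.sum(proj ** 2))) / (n * (c - 1))
            for j in range(k):
                members = maps[assignment == j]
                if len(members) == 0:
                    # re-seed an empty cluster with the worst-fit map
                    worst = int(np.argmin(np.abs(corr[np.arange(n),
                                                      assignment])))
                    templates[j] = maps_n[worst]
                    continue
                templates[j] = _principal_pattern(members)
            if prev_noise < np.inf and prev_noise > 0:
                if abs(prev_noise - noise_var) / prev_noise < tol:
                    break
            prev_noise = noise_var
        tn = templates / np.linalg.norm(templates, axis=1, keepdims=True)
        corr = maps_n @ tn.T
        proj = np.max(np.abs(corr), axis=1) * norms
        gev = float(np.sum(proj ** 2)) / total_power
        if best is None or gev > best[0]:
            best = (gev, tn.copy(),
                    {"restarts": restarts, "iterations": n_iter,
                     "gev": gev, "noise_variance": prev_noise,
                     "gev_trace": gev_trace, "seed": seed})
    assert best is not None
    gev, templates, meta = best
    order = list(ascii_uppercase[:k])
    return MicrostateModel(templates=templates, labels_order=order,
                           fit_meta=meta)


def align_templates(model_a: MicrostateModel, model_b: MicrostateModel
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one template matching between two models.

    Returns ``(permutation, corr_matrix)`` where ``permutation[i]`` is the
    row of ``model_b`` matched to row ``i`` of ``model_a``, maximizing the
    total absolute spatial correlation (Hungarian assignment), and
    ``corr_matrix`` is the K x K matrix of absolute correlations.
    """
    if (model_a.k != model_b.k
            or model_a.n_channels != model_b.n_channels):
        raise ParameterError("models must share K and channel count")
    corr = np.abs(spatial_correlation(model_a.templates, model_b.templates))
    corr = np.atleast_2d(corr)
    _, cols = linear_sum_assignment(-corr)
    return cols, corr


def backfit(rec: EEGRecording, model: MicrostateModel,
            reject_below: float = DEFAULT_REJECT_BELOW) -> LabelSequence:
    """Winner-takes-all labeling of every frame by |spatial correlation|.

    Frames whose winning correlation falls below ``reject_below`` are left
    :data:`UNLABELED`.  Polarity is ignored.  Ties break to the lowest class
    index.
    """
    if rec.n_channels != model.n_channels:
        raise ParameterError("channel count does not match templates")
    corr = np.abs(spatial_correlation(rec.data.T, model.templates))
    corr = np.atleast_2d(corr)
    labels = np.argmax(corr, axis=1)  # argmax takes first (lowest) on ties
    winners = corr[np.arange(corr.shape[0]), labels]
    labels = np.where(winners >= reject_below, labels, UNLABELED)
    return LabelSequence(labels=labels, fs=rec.fs,
                         correlations=np.clip(winners, 0.0, 1.0),
                         source_id=rec.subject_id)


def gmd(map_u: np.ndarray, map_v: np.ndarray) -> float:
    """Global map dissimilarity between two topographies.

    Both maps are average-referenced and GFP-normalized; GMD is the smaller
    GFP of their difference and their sum, making it polarity-invariant with
    range [0, sqrt(2)].
    """
    u = _demean(np.asarray(map_u, float))
    v = _demean(np.asarray(map_v, float))
    gu = np.sqrt(np.mean(u * u))
    gv = np.sqrt(np.mean(v * v))
    if gu == 0 or gv == 0:
        raise ParameterError("GMD undefined for zero-GFP maps")
    u = u / gu
    v = v / gv
    d1 = np.sqrt(np.mean((u - v) ** 2))
    d2 = np.sqrt(np.mean((u + v) ** 2))
    return float(min(d1, d2))


def _runs(labels: np.ndarray):
    """Maximal constant runs as (start, length, value) triples."""
    if labels.size == 0:
        return
    change = np.nonzero(np.diff(labels))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    for s, e in zip(starts, ends):
        yield int(s), int(e - s), int(labels[s])


def smooth_labels(seq: LabelSequence, model: MicrostateModel,
                  rec: EEGRecording,
                  min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
                  max_passes: int = 1000) -> LabelSequence:
    """Reassign microstate runs shorter than ``min_duration_ms``.

    Each frame of a short run is relabeled to the non-current class whose
    template has the smallest GMD to that frame's topography; passes repeat
    until no labeled run is short, a pass changes nothing, or a previously
    seen labeling recurs (cycle guard).  Any short run still left (the
    frame-wise rule can oscillate when every candidate class is equidistant)
    is then absorbed into the contiguous neighboring run whose class has the
    smaller mean GMD to the run's frames, so no labeled run shorter than the
    minimum survives unless it is isolated between unlabeled gaps.
    Unlabeled frames are untouched and split runs.

    For unit-GFP maps GMD reduces to sqrt(2 - 2|corr|), so the per-frame
    GMD ordering is precomputed once from the frame-template correlations.
    """
    labels = seq.labels.copy()
    corr = np.abs(spatial_correlation(rec.data.T, model.templates))
    corr = np.atleast_2d(corr)
    gmd_matrix = np.sqrt(np.maximum(2.0 - 2.0 * corr, 0.0))  # (n, K)
    gfp_frames = gfp(rec)
    seen: set[bytes] = set()
    for _ in range(max_passes):
        key = labels.tobytes()
        if key in seen:
            break
        seen.add(key)
        changed = False
        any_short = False
        new_labels = labels.copy()
        for start, length, value in _runs(labels):
            if value == UNLABELED:
                continue
            if length * 1000.0 / seq.fs >= min_duration_ms:
                continue
            any_short = True
            for i in range(start, start + length):
                if gfp_frames[i] == 0:
                    continue
                dist = gmd_matrix[i].copy()
                dist[value] = np.inf  # must leave the current class
                new = int(np.argmin(dist))  # argmin tie -> lowest index
                if new != labels[i]:
                    new_labels[i] = new
                    changed = True
        labels = new_labels
        if not any_short or not changed:
            break
    labels = _merge_leftover_short_runs(labels, gmd_matrix, seq.fs,
                                        min_duration_ms)
    return LabelSequence(labels=labels, fs=seq.fs,
                         correlations=seq.correlations,
                         source_id=seq.source_id)


def _merge_leftover_short_runs(labels: np.ndarray, gmd_matrix: np.ndarray,
                               fs: float, min_duration_ms: float
                               ) -> np.ndarray:
    """Absorb remaining short labeled runs into a contiguous neighbor run.

    The shortest run goes first; its frames take the class of the adjacent
    labeled run (left or right, whichever class has the smaller mean GMD
    over the run's frames; ties break to the lower class index).  Each merge
    reduces the run count, so this terminates.  Runs isolated between
    unlabeled gaps have no contiguous neighbor and are left as they are.
    """
    labels = labels.copy()
    while True:
        runs = list(_runs(labels))
        short = [(length, start, value)
                 for start, length, value in runs
                 if value != UNLABELED
                 and length * 1000.0 / fs < min_duration_ms]
        if not short:
            return labels
        progressed = False
        for length, start, value in sorted(short):
            idx = next(i for i, (s, _, _) in enumerate(runs) if s == start)
            candidates = []
            for nb in (idx - 1, idx + 1):
                if 0 <= nb < len(runs) and runs[nb][2] != UNLABELED:
                    cls = runs[nb][2]
                    cost = float(np.mean(
                        gmd_matrix[start:start + length, cls]))
                    candidates.append((cost, cls))
            if not candidates:
                continue
            _, cls = min(candidates)
            labels[start:start + length] = cls
            progressed = True
            break  # recompute runs after every merge
        if not progressed:
            return labels


def microstate_stats(seq: LabelSequence, k: int | None = None):
    """Per-class duration (ms), occurrence (runs/s of labeled time), and
    coverage (fraction of labeled frames).

    A class that never occurs gets duration NaN, occurrence 0, coverage 0.
    Unlabeled frames split runs and are excluded from the denominators.
    """
    import pandas as pd

    labeled = seq.labels[seq.labels != UNLABELED]
    if k is None:
        k = int(labeled.max()) + 1 if labeled.size else 0
    labeled_seconds = labeled.size / seq.fs
    run_lengths: dict[int, list[int]] = {j: [] for j in range(k)}
    for _, length, value in _runs(seq.labels):
        if value != UNLABELED and value < k:
            run_lengths[value].append(length)
    rows = []
    for j in range(k):
        lens = run_lengths[j]
        n_runs = len(lens)
        rows.append({
            "class": ascii_uppercase[j] if j < 26 else str(j),
            "duration_ms": (np.mean(lens) * 1000.0 / seq.fs
                            if n_runs else np.nan),
            "occurrence_per_s": (n_runs / labeled_seconds
                                 if labeled_seconds > 0 else 0.0),
            "coverage": (np.sum(np.array(lens)) / labeled.size
                         if labeled.size else 0.0),
        })
    return pd.DataFrame(rows).set_index("class")
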