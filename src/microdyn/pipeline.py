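"""End-to-end analysis pipeline.

Orchestrates: preprocess -> CEEMD -> per-scale microstate segmentation
(pooled GFP-peak clustering, backfitting, smoothing) -> sequence metrics ->
group statistics -> LOSO score prediction, from a manifest of subject files
and a config of stage parameters.  Every stage draws its seed
deterministically from one master seed, the config hash is embedded in the
report, and per-subject label sequences are cached on disk keyed by that
hash so reruns with an unchanged config are free and bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import microstate as ms
from .ceemd import ceemd_recording
from .errors import MicrodynError, ParameterError
from .preprocess import average_reference
from .preprocess import preprocess as preprocess_recording
from .io import EEGRecording, load_eeg
from .stats import (SubjectScales, assemble_features, loso_predict,
                    mann_whitney_z)

GROUP_PAIRS = (("HC", "FTD"), ("FTD", "AD"), ("HC", "AD"))


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the published analysis values."""

    manifest: str = ""
    out_dir: str = "microdyn_out"
    duration_s: float | None = 180.0
    offset_s: float = 0.0
    target_fs: float = 250.0
    apply_filters: bool = True
    k_states: int = 4
    restarts: int = 50
    max_iter: int = 1000
    convergence_tol: float = 1e-6
    max_peaks: int = 2000
    min_peak_distance_ms: float = 10.0
    peak_sd_exclusion: float = 1.0
    smooth_min_duration_ms: float = 30.0
    reject_below: float = 0.5
    ceemd_noise_std_rel: float = 0.1
    ceemd_n_ensemble: int = 100
    imf_scales: tuple[int, ...] = (2, 3, 4, 5)
    m_headline: int = 8
    m_values: tuple[int, ...] = (4, 5, 6, 7, 8)
    n_surrogates: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("imf_scales", "m_values"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_manifest(path) -> pd.DataFrame:
    """Manifest CSV: subject_id, path, format, group, score."""
    df = pd.read_csv(path)
    required = {"subject_id", "path", "group", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"manifest missing columns {sorted(missing)}")
    if "format" not in df.columns:
        df["format"] = "delimited_matrix"
    return df


def _stage_seeds(master: int, n_subjects: int) -> dict:
    """Deterministic per-stage seed split from one master seed."""
    ss = np.random.SeedSequence(master)
    kmeans_seed, features_seed, *subject_seeds = [
        int(s.generate_state(1)[0] % (2 ** 31))
        for s in ss.spawn(2 + n_subjects)]
    return {"kmeans": kmeans_seed, "features": features_seed,
            "subjects": subject_seeds}


def _scale_recordings(rec: EEGRecording, cfg: PipelineConfig,
                      subject_seed: int) -> dict[str, EEGRecording]:
    """Broadband plus per-IMF views of one preprocessed recording."""
    scales = {"broadband": rec}
    if cfg.imf_scales:
        imfset = ceemd_recording(
            rec, noise_std_rel=cfg.ceemd_noise_std_rel,
            n_ensemble=cfg.ceemd_n_ensemble, seed=subject_seed,
            max_imfs=max(cfg.imf_scales))
        for j in cfg.imf_scales:
            if j <= imfset.n_imfs:
                scales[f"IMF{j}"] = imfset.imf_recording(j, rec)
            else:
                raise MicrodynError(
                    f"stage ceemd, subject {rec.subject_id}: only "
                    f"{imfset.n_imfs} IMFs extracted, IMF{j} unavailable")
    return scales


def run_on_recordings(records: list[EEGRecording], scores: pd.DataFrame,
                      cfg: PipelineConfig,
                      preprocessed: bool = False) -> dict:
    """Run the full analysis on in-memory recordings.

    ``scores`` must carry subject_id, group, score.  Set ``preprocessed``
    when the recordings are already filtered/re-referenced/segmented.
    """
    seeds = _stage_seeds(cfg.seed, len(records))
    score_map = scores.set_index("subject_id")
    out_dir = Path(cfg.out_dir)
    cache_dir = out_dir / "cache" / cfg.hash()
    cache_dir.mkdir(parents=True, exist_ok=True)

    # stage 1-2: preprocess + CEEMD, per subject
    per_subject_scales: list[dict[str, EEGRecording]] = []
    for i, rec in enumerate(records):
        try:
            if not preprocessed:
                rec = preprocess_recording(rec, target_fs=cfg.target_fs,
                                           duration_s=cfg.duration_s,
                                           offset_s=cfg.offset_s)
            else:
                rec = average_reference(rec)
            per_subject_scales.append(
                _scale_recordings(rec, cfg, seeds["subjects"][i]))
        except MicrodynError as exc:
            raise MicrodynError(
                f"stage preprocess/ceemd, subject {rec.subject_id}: {exc}"
            ) from exc

    scale_names = list(per_subject_scales[0])

    # stage 3: per-scale pooled clustering and backfitting (cached)
    label_seqs: dict[str, list[ms.LabelSequence]] = {}
    for scale in scale_names:
        cache_file = cache_dir / f"labels_{scale}.npz"
        if cache_file.exists():
            blob = np.load(cache_file)
            label_seqs[scale] = [
                ms.LabelSequence(labels=blob[f"labels_{i}"],
                                 fs=float(blob["fs"]),
                                 correlations=blob[f"corr_{i}"],
                                 source_id=records[i].subject_id)
                for i in range(len(records))]
            continue
        pooled = []
        for scales in per_subject_scales:
            rec_s = scales[scale]
            peaks = ms.extract_gfp_peaks(
                rec_s, min_peak_distance_ms=cfg.min_peak_distance_ms,
                max_peaks=cfg.max_peaks,
                sd_exclusion=cfg.peak_sd_exclusion)
            pooled.append(rec_s.data[:, peaks].T)
        model = ms.modified_kmeans(np.vstack(pooled), k=cfg.k_states,
                                   restarts=cfg.restarts,
                                   max_iter=cfg.max_iter,
                                   tol=cfg.convergence_tol,
                                   seed=seeds["kmeans"])
        seqs = []
        for scales in per_subject_scales:
            rec_s = scales[scale]
            seq = ms.backfit(rec_s, model, reject_below=cfg.reject_below)
            seq = ms.smooth_labels(seq, model, rec_s,
                                   min_duration_ms=cfg.smooth_min_duration_ms)
            seqs.append(seq)
        label_seqs[scale] = seqs
        np.savez(cache_file, fs=seqs[0].fs,
                 **{f"labels_{i}": s.labels for i, s in enumerate(seqs)},
                 **{f"corr_{i}": s.correlations for i, s in enumerate(seqs)})

    # stage 4: features
    subjects = []
    for i, rec in enumerate(records):
        sid = rec.subject_id
        subjects.append(SubjectScales(
            subject_id=sid, group=str(score_map.loc[sid, "group"]),
            score=float(score_map.loc[sid, "score"]),
            label_seqs={sc: label_seqs[sc][i] for sc in scale_names}))
    features = assemble_features(subjects, k=cfg.k_states, variant="ceemd",
                                 m_values=cfg.m_values,
                                 n_surrogates=cfg.n_surrogates,
                                 seed=seeds["features"])

    # stage 5: group statistics (MSNRI at headline m, and MSLZC, per scale)
    group_rows = []
    for scale in scale_names:
        for metric in (f"msnri_m{cfg.m_headline}", "mslzc"):
            col = f"{scale}_{metric}"
            row: dict[str, object] = {"scale": scale, "metric": metric}
            for g in ("HC", "FTD", "AD"):
                vals = features.loc[features["group"] == g, col]
                row[f"{g}_mean"] = float(vals.mean()) if len(vals) else np.nan
                row[f"{g}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            for g1, g2 in GROUP_PAIRS:
                v1 = features.loc[features["group"] == g1, col]
                v2 = features.loc[features["group"] == g2, col]
                if len(v1) and len(v2):
                    z, p = mann_whitney_z(v1, v2)
                else:
                    z, p = np.nan, np.nan
                row[f"z_{g1}_vs_{g2}"] = z
                row[f"p_{g1}_vs_{g2}"] = p
            group_rows.append(row)
    group_stats = pd.DataFrame(group_rows)

    # stage 6: LOSO predictions, both variants and both scopes
    predictions: dict[str, dict] = {}
    baseline_cols = [c for c in features.columns
                     if c in ("subject_id", "group", "score")
                     or c.startswith("broadband_")]
    for variant, table in (("baseline", features[baseline_cols]),
                           ("ceemd", features)):
        for scope in ("all", "disease"):
            sub = (table if scope == "all"
                   else table[table["group"].isin(["FTD", "AD"])])
            key = f"{variant}_{scope}"
            if len(sub) >= 3 and sub["score"].nunique() > 1:
                predictions[key] = loso_predict(sub).metrics
            else:
                predictions[key] = {"note": "not enough subjects or score "
                                            "variance in this scope"}

    report = {
        "config_hash": cfg.hash(),
        "config": asdict(cfg),
        "n_subjects": len(records),
        "scales": scale_names,
        "group_stats": group_stats.to_dict(orient="records"),
        "predictions": predictions,
    }

    out_dir.mkdir(parents=True, exist_ok=True)
    features.to_csv(out_dir / "features.csv", index=False)
    group_stats.to_csv(out_dir / "group_stats.tsv", sep="\t", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    report["features"] = features
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Load the manifest, run every stage, and write the report."""
    manifest = load_manifest(cfg.manifest)
    records = []
    for _, row in manifest.iterrows():
        try:
            records.append(load_eeg(row["path"], format=row["format"],
                                    subject_id=str(row["subject_id"]),
                                    group_label=str(row["group"])))
        except MicrodynError as exc:
            raise MicrodynError(
                f"stage load, subject {row['subject_id']}: {exc}") from exc
    scores = manifest[["subject_id", "group", "score"]].copy()
    scores["subject_id"] = scores["subject_id"].astype(str)
    return run_on_recordings(records, scores, cfg)
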