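"""End-to-end experiment orchestration.

``run_experiment`` wires the stages together: simulate a synthetic colony
(or load session WAVs), high-pass and segment each session, extract per-call
features, classify template matches, score per pup x age-bin similarity,
and fit the two mixed models — writing every intermediate table as CSV so
each stage can be audited and re-run independently.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import audio, matching, similarity
from .colony import (
    DevelopmentalConfig,
    PupRecord,
    age_bin,
    default_colony_pups,
    simulate_colony,
)
from .models import fit_match_glmm, fit_similarity_lmm, summarize_fits
from .waveform import write_wav

log = logging.getLogger("pupcall")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "pupcall_run"
    developmental: DevelopmentalConfig = field(default_factory=DevelopmentalConfig)
    spectrogram: audio.SpectrogramParams = field(
        default_factory=audio.SpectrogramParams
    )
    match_threshold_hz: float = matching.F0_MATCH_THRESHOLD_HZ
    max_onset_gap_s: float = matching.MAX_ONSET_GAP_S
    n_perm: int = 999
    seed: int = 20211025
    days: list[int] | None = None
    write_wavs: bool = False
    fit_models: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        dev = DevelopmentalConfig(**raw.pop("developmental", {}))
        spec = audio.SpectrogramParams(**raw.pop("spectrogram", {}))
        return cls(developmental=dev, spectrogram=spec, **raw)


def features_for_sessions(
    waveforms: dict[tuple[str, int], "audio.Waveform"],
    spectrogram_params: audio.SpectrogramParams | None = None,
) -> tuple[dict[tuple[str, int], list[audio.CallFeatures]], pd.DataFrame]:
    """Segment every session and measure per-call features.

    Returns the per-session CallFeatures lists plus one flat DataFrame with
    a row per call (pup_id, age_days, call_index, onset/offset, duration,
    F0 statistics, peak frequency and sequence-derived columns).
    """
    params = spectrogram_params or audio.SpectrogramParams()
    session_calls: dict[tuple[str, int], list[audio.CallFeatures]] = {}
    rows = []
    for (pup_id, age), wave in sorted(waveforms.items()):
        hp = audio.highpass(wave, params.highpass_cutoff)
        segs = audio.segment_calls(hp, parent_file=f"{pup_id}_d{age}")
        feats = [audio.extract_features(s) for s in segs]
        session_calls[(pup_id, age)] = feats
        for idx, f in enumerate(feats):
            rows.append(
                {
                    "pup_id": pup_id,
                    "age_days": age,
                    "call_index": idx,
                    "onset_s": f.onset_s,
                    "offset_s": f.offset_s,
                    "duration_s": f.duration,
                    "mean_f0": f.mean_f0,
                    "min_f0": f.min_f0,
                    "max_f0": f.max_f0,
                    "mean_peak": f.mean_peak,
                    "n_frames": len(f.f0_contour),
                }
            )
    cols = [
        "pup_id", "age_days", "call_index", "onset_s", "offset_s",
        "duration_s", "mean_f0", "min_f0", "max_f0", "mean_peak", "n_frames",
    ]
    return session_calls, pd.DataFrame(rows, columns=cols)


def matched_call_features(
    match_table: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Feature rows of matched calls, with template-position alignment.

    ``position`` is the call's rank within its matched window and
    ``inter_call_interval_s`` the onset gap to the previous call of the
    window (missing for window-initial calls) — the quantities the
    template-side Gower matrix is aligned on.
    """
    m = match_table[match_table["is_match"]].merge(
        features, on=["pup_id", "age_days", "call_index"], how="left"
    )
    if m.empty:
        return m.assign(position=[], inter_call_interval_s=[])
    m = m.sort_values(["pup_id", "age_days", "window_id", "call_index"]).reset_index(
        drop=True
    )
    grp = m.groupby(["pup_id", "age_days", "window_id"], sort=False)
    m["position"] = grp.cumcount()
    m["inter_call_interval_s"] = m["onset_s"] - grp["onset_s"].shift(1)
    return m


def similarity_by_pup(
    matched: pd.DataFrame,
    pup_meta: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per pup x age-bin Mantel r.

    Playback pups are scored against their own stimulus template; control
    pups against the template each chance-matched window realized.
    """
    out = []
    meta = pup_meta.set_index("pup_id")
    for pup_id, grp in matched.groupby("pup_id"):
        stim = meta.loc[pup_id, "stimulus_id"]
        template = None if stim == "none" else stim
        res = similarity.session_similarity(grp, template, n_perm=n_perm, seed=seed)
        if not res.empty:
            res.insert(1, "condition", meta.loc[pup_id, "condition"])
            res.insert(2, "sex", meta.loc[pup_id, "sex"])
            out.append(res)
    if not out:
        return pd.DataFrame(
            columns=["pup_id", "condition", "sex", "age_bin", "r", "p", "n_objects", "n_perm"]
        )
    return pd.concat(out, ignore_index=True)


def run_experiment(
    config: RunConfig, pups: list[PupRecord] | None = None
) -> dict:
    """Run the full pipeline and write all artifacts under ``out_dir``.

    Returns the machine-readable summary (also written as
    ``summary.json``): per-condition match fractions by age bin, mean
    Mantel r by age bin, model tables and stage timings.
    """
    if pups is None:
        pups = default_colony_pups()
    if not pups:
        raise ValueError("no pups configured")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dev = config.developmental
    if dev.seed != config.seed:
        dev = DevelopmentalConfig(**{**asdict(dev), "seed": config.seed})
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    log.info("stage simulate: %d pups, seed %d", len(pups), config.seed)
    col = simulate_colony(pups, dev, days=config.days)
    col.annotations.to_csv(out / "annotations.csv", index=False)
    if config.write_wavs:
        wav_dir = out / "sessions"
        wav_dir.mkdir(exist_ok=True)
        for (pup_id, age), wave in col.waveforms.items():
            write_wav(wav_dir / f"{pup_id}_d{age:02d}.wav", wave.normalized(0.9))
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    log.info("stage features: %d sessions", len(col.waveforms))
    session_calls, features = features_for_sessions(col.waveforms, config.spectrogram)
    features.to_csv(out / "features.csv", index=False)
    timings["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    meta = pd.DataFrame(
        [
            {
                "pup_id": p.pup_id,
                "condition": p.condition,
                "stimulus_id": p.stimulus_id,
                "sex": p.sex,
            }
            for p in pups
        ]
    )
    meta.to_csv(out / "pups.csv", index=False)
    match_table = matching.build_match_table(
        session_calls, meta, config.match_threshold_hz, config.max_onset_gap_s
    )
    match_table.to_csv(out / "matches.csv", index=False)
    timings["match"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    matched = matched_call_features(match_table, features)
    mantel_rows = similarity_by_pup(matched, meta, config.n_perm, config.seed)
    mantel_rows.to_csv(out / "mantel.csv", index=False)
    timings["similarity"] = time.perf_counter() - t0

    summary: dict = {
        "seed": config.seed,
        "n_pups": len(pups),
        "n_calls": int(len(match_table)),
        "match_fraction_by_condition_bin": {},
        "mean_mantel_r_by_condition_bin": {},
        "timings_s": timings,
    }
    mt = match_table.copy()
    mt["age_bin"] = age_bin(mt["age_days"].to_numpy())
    frac = mt.groupby(["condition", "age_bin"])["is_match"].mean()
    for (cond, b), v in frac.items():
        summary["match_fraction_by_condition_bin"][f"{cond}/bin{b}"] = float(v)
    if not mantel_rows.empty:
        mr = mantel_rows.groupby(["condition", "age_bin"])["r"].mean()
        for (cond, b), v in mr.items():
            summary["mean_mantel_r_by_condition_bin"][f"{cond}/bin{b}"] = float(v)

    if config.fit_models:
        t0 = time.perf_counter()
        try:
            glmm = fit_match_glmm(match_table)
        except ValueError as exc:
            log.warning("match GLMM not fit: %s", exc)
            glmm = None
        lmm = None
        if len(mantel_rows) >= 3 and mantel_rows["pup_id"].nunique() >= 2:
            try:
                lmm = fit_similarity_lmm(mantel_rows)
            except ValueError as exc:
                log.warning("similarity LMM not fit: %s", exc)
        tables = summarize_fits(glmm, lmm)
        if "match_model" in tables:
            tables["match_model"].to_csv(out / "table_match_model.csv", index=False)
            summary["match_model"] = tables["match_model"].to_dict("records")
        if "similarity_model" in tables:
            tables["similarity_model"].to_csv(
                out / "table_similarity_model.csv", index=False
            )
            summary["similarity_model"] = tables["similarity_model"].to_dict("records")
        timings["fit"] = time.perf_counter() - t0

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
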