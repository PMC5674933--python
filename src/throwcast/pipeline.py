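"""End-to-end orchestration: simulate -> preprocess -> events -> label ->
features -> classify -> maps, with every artifact written as CSV.

All randomness flows from the single configured seed, so a repeated run
produces byte-identical outputs. Every output file carries a header line
with the package version and the configuration hash.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ball_baseline_me
from .config import PipelineConfig
from .dataset import ParticipantData, assemble_participant
from .predictability import compute_map, min_mi, predictable_summary
from .synthetic import GroundTruth, simulate_participant
from .trialdata import TrialRecord, read_trial, write_trial

log = logging.getLogger("throwcast")


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# throwcast={__version__} config_hash={cfg.hash()}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def simulate_to_dir(cfg: PipelineConfig, out_dir, seed: int | None = None
                    ) -> list[tuple[TrialRecord, GroundTruth]]:
    """Generate one synthetic participant and write trial files plus
    ground_truth.csv and the echoed configuration."""
    out_dir = Path(out_dir)
    trial_dir = out_dir / "trials"
    trial_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.sim_config(seed)
    pairs = simulate_participant(sim_cfg)
    rows = []
    for rec, truth in pairs:
        write_trial(rec, trial_dir / f"{rec.trial_id}.csv")
        rows.append({
            "trial_id": truth.trial_id,
            "true_onset": truth.true_onset,
            "true_release": truth.true_release,
            "true_impact": truth.true_impact,
            "true_side": truth.true_side,
            "true_landing_x": truth.true_landing[0],
            "true_landing_z": truth.true_landing[1],
            "informative_markers": ";".join(
                f"{m.marker}:{m.onset_decile}:{m.amplitude_m}"
                for m in truth.informative_markers),
        })
    _write_csv(pd.DataFrame(rows), out_dir / "ground_truth.csv", cfg)
    cfg.to_yaml(out_dir / "config_used.yaml")
    log.info("simulated %d trials into %s", len(pairs), trial_dir)
    return pairs


def load_trials(trial_dir) -> list[TrialRecord]:
    paths = sorted(Path(trial_dir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trial CSVs under {trial_dir}")
    return [read_trial(p) for p in paths]


def assemble(cfg: PipelineConfig, records: list[TrialRecord]) -> ParticipantData:
    return assemble_participant(
        records,
        board=cfg.board,
        band_width=cfg.band_width_m,
        filter_order=cfg.filter_order,
        cutoff_hz=cfg.filter_cutoff_hz,
        ball_radius=cfg.ball_radius_m,
        n_resample=cfg.resample_n,
        **cfg.event_params(),
    )


def events_table(data: ParticipantData) -> pd.DataFrame:
    rows = []
    for t in data.trials:
        e = t.events
        rows.append({
            "trial_id": t.trial_id,
            "t_onset": e.t_onset if e else np.nan,
            "t_release": e.t_release if e else np.nan,
            "t_impact": e.t_impact if e else np.nan,
            "landing_x": e.landing[0] if e else np.nan,
            "landing_z": e.landing[1] if e else np.nan,
            "hand_peak_speed": e.hand_peak_speed if e else np.nan,
            "excluded": t.exclusion.excluded,
            "reason": t.exclusion.reason,
        })
    return pd.DataFrame(rows)


def labels_table(data: ParticipantData) -> pd.DataFrame:
    rows = []
    for t in data.trials:
        if t.label is None:
            continue
        rows.append({
            "trial_id": t.trial_id,
            "landing_x": t.label.landing_x,
            "side": t.label.value,
            "in_band": t.label.value == "Band",
            "band_center": t.label.band_center,
            "band_width": t.label.band_width,
        })
    return pd.DataFrame(rows)


def map_table(pmap) -> pd.DataFrame:
    df = pd.DataFrame(
        np.round(pmap.mi * 100.0, 6),
        index=list(pmap.units),
        columns=[f"decile_{d}" for d in range(1, 11)],
    )
    df.index.name = "spatial_unit"
    return df.reset_index()


def run_pipeline(cfg: PipelineConfig, out_dir, input_dir=None,
                 simulate: bool = False) -> dict:
    """Execute all stages and write every intermediate artifact.

    Either ``simulate=True`` (generate a synthetic participant under
    ``out_dir``) or ``input_dir`` (a directory of trial CSVs) must be given.
    Returns a dict with the in-memory stage products.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if simulate:
        pairs = simulate_to_dir(cfg, out_dir)
        records = [rec for rec, _ in pairs]
    elif input_dir is not None:
        records = load_trials(input_dir)
    else:
        raise ValueError("need input_dir or simulate=True")

    data = assemble(cfg, records)
    tally = data.exclusion_tally()
    log.info("exclusions: %s", tally)

    _write_csv(events_table(data), out_dir / "events.csv", cfg)
    _write_csv(labels_table(data), out_dir / "labels.csv", cfg)

    ball = ball_baseline_me(data.release_states, data.labels, cfg.lda_ridge)
    cls_rows = [{
        "predictor": "ball_release_state",
        "n_pc": 6,
        "me_pct": 100.0 * ball.me,
        "accuracy_pct": ball.accuracy_pct,
        "mi_pct": 0.0,
        "n_used": ball.n_used,
    }]

    maps, summaries = {}, {}
    for family in cfg.families:
        pmap = compute_map(data, family, vaf=cfg.stpca_vaf,
                           ridge=cfg.lda_ridge, nested_pca=cfg.nested_pca)
        maps[family] = pmap
        _write_csv(map_table(pmap), out_dir / f"map_{family}.csv", cfg)
        best, unit, dec = min_mi(pmap)
        cls_rows.append({
            "predictor": f"{family}:best",
            "n_pc": int(pmap.n_pc[pmap.units.index(unit), dec - 1]),
            "me_pct": 100.0 * pmap.me[pmap.units.index(unit), dec - 1],
            "accuracy_pct": 100.0 * (1.0 - pmap.me[pmap.units.index(unit),
                                                   dec - 1]),
            "mi_pct": 100.0 * best,
            "n_used": data.n_used,
        })
        summary = predictable_summary([pmap], cfg.accuracy_threshold)
        summaries[family] = summary
        _write_csv(
            pd.DataFrame({
                "decile": np.arange(1, 11),
                "n_predictable": summary.counts,
                "segments": [json.dumps(s, sort_keys=True)
                             for s in summary.segment_counts],
            }),
            out_dir / f"summary_{family}.csv", cfg,
        )

    _write_csv(pd.DataFrame(cls_rows), out_dir / "classification.csv", cfg)
    meta = {
        "version": __version__,
        "config_hash": cfg.hash(),
        "n_trials": len(records),
        "n_good": data.n_good,
        "n_used": data.n_used,
        "window_s": data.window_s,
        "band_center": data.band_center,
        "exclusion_tally": tally,
        "me_ball_pct": 100.0 * ball.me,
    }
    (out_dir / "run_meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True))
    return {"data": data, "ball": ball, "maps": maps,
            "summaries": summaries, "meta": meta}
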