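"""End-to-end orchestration: synth -> preprocess -> segment -> train ->
evaluate -> stream replay, with per-stage artifacts, logging and resume.

One global seed deterministically derives the per-stage seeds (synth, split,
train, stream) through numpy's SeedSequence, so each stage is individually
reproducible.  With ``resume=True`` a stage whose artifacts already exist on
disk is skipped and its outputs are read back instead.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .config import PipelineConfig, save_config
from .errors import EmgError
from .evaluation import evaluate_model, save_report
from .model import (ModelSpec, TrainConfig, load_model, save_model, train_model)
from .preprocess import causal_config, preprocess_session, read_envelope_session
from .stream import CsvCommandLog, calibrate_baseline, replay_session
from .synth import (AcquisitionProtocol, EmgRecording, read_session,
                    rest_recording, synth_session, write_session)
from .windows import (load_window_set, save_window_set, segment_session,
                      split_windows)

log = logging.getLogger("emgeca.pipeline")


def derive_seeds(global_seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(global_seed).generate_state(4, dtype=np.uint32)
    names = ("synth", "split", "train", "stream")
    return {n: int(s % np.uint32(2**31)) for n, s in zip(names, state)}


def _stage(name: str, outputs: list[Path], resume: bool):
    done = resume and all(p.exists() for p in outputs)
    log.info("stage %-10s %s", name, "skipped (artifacts present)" if done else "running")
    return done


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 resume: bool = False) -> dict:
    """Execute every stage; returns a summary dict incl. the run directory.

    Re-running with an identical config and seed reproduces identical
    metrics; a stage failure aborts with the stage name attached.
    """
    cfg.validate()
    run_dir = Path(out_dir) if out_dir else Path(cfg.out_root) / f"run-seed{cfg.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(cfg.log_level)
    save_config(cfg, run_dir / "config.yaml")
    seeds = derive_seeds(cfg.seed)
    (run_dir / "seeds.json").write_text(json.dumps(seeds, indent=2))
    summary = {"run_dir": str(run_dir), "seed": cfg.seed}

    stage = "synth"
    try:
        raw_dir = run_dir / "sessions_raw"
        rest_path = run_dir / "rest.csv"
        protocol = dataclasses.replace(cfg.protocol, subject_seed=seeds["synth"])
        if not _stage(stage, [raw_dir / "session.json", rest_path], resume):
            recs = synth_session(protocol)
            write_session(recs, raw_dir, protocol)
            rest = rest_recording(protocol, seeds["synth"] + 1)
            np.savetxt(rest_path, rest.samples, fmt="%.17g", delimiter=",",
                       header=",".join(f"ch{c+1}" for c in range(rest.n_channels)),
                       comments="")
        log.info("synth: %d gestures x %.1f s at %.0f Hz",
                 protocol.n_gestures, protocol.duration_s, protocol.fs)

        stage = "preprocess"
        env_dir = run_dir / "sessions_env"
        if not _stage(stage, [env_dir / "session.json"], resume):
            preprocess_session(raw_dir, env_dir, cfg.envelope)

        stage = "segment"
        h5_path = run_dir / "windows.h5"
        if not _stage(stage, [h5_path], resume):
            env_recs = read_envelope_session(env_dir)
            window_cfg = dataclasses.replace(cfg.window, split_seed=seeds["split"])
            ws = split_windows(segment_session(env_recs, window_cfg), window_cfg)
            save_window_set(ws, h5_path, window_cfg)
        ws = load_window_set(h5_path)
        log.info("segment: %d windows of %d samples x %d channels",
                 ws.n_windows, ws.window_len, ws.n_channels)
        summary["n_windows"] = ws.n_windows

        stage = "train"
        model_dir = run_dir / "model"
        spec = dataclasses.replace(
            cfg.model,
            input_shape=(ws.window_len, ws.n_channels, 1),
            n_classes=int(ws.labels.max()) + 1)
        if not _stage(stage, [model_dir / "model.json"], resume):
            train_cfg = dataclasses.replace(cfg.train, seed=seeds["train"])
            tm = train_model(spec, ws, train_cfg, cfg.eca)
            save_model(tm, model_dir)
        tm = load_model(model_dir)
        summary["best_epoch"] = tm.best_epoch
        summary["val_accuracy"] = float(tm.history["val_acc"].max())

        stage = "evaluate"
        eval_dir = run_dir / "eval"
        if not _stage(stage, [eval_dir / "report.json"], resume):
            report = evaluate_model(tm, ws, "test")
            save_report(report, eval_dir, history=tm.history)
        report_dict = json.loads((eval_dir / "report.json").read_text())
        summary["test_accuracy"] = report_dict["accuracy"]
        summary["test_loss"] = report_dict["loss"]
        summary["macro_f1"] = report_dict["macro_f1"]
        log.info("evaluate: test accuracy %.4f", report_dict["accuracy"])

        stage = "stream"
        trace_path = run_dir / "stream_trace.csv"
        commands_path = run_dir / "commands.csv"
        if not _stage(stage, [trace_path, commands_path], resume):
            raw_recs, _ = read_session(raw_dir)
            rest_samples = np.loadtxt(rest_path, delimiter=",", skiprows=1, ndmin=2)
            rest = EmgRecording(rest_samples, protocol.fs, -1)
            causal = causal_config(cfg.envelope)
            baseline = calibrate_baseline(rest, causal)
            sink = CsvCommandLog(commands_path)
            commands, trace = replay_session(
                raw_recs[0], tm, cfg.stream, causal, baseline, sink=sink,
                window_ms=cfg.window.w_ms)
            trace.to_csv(trace_path, index=False)
            log.info("stream: %d commands over %d steps", len(commands), len(trace))
        n_cmds = max(sum(1 for _ in open(commands_path)) - 1, 0)
        summary["stream_commands"] = n_cmds
    except EmgError as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise EmgError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
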