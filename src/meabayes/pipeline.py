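"""End-to-end orchestration: simulate -> encode -> record -> detect -> free-energy map.

One :class:`RunConfig` drives the whole closed loop, with true and
surrogate-source branches, and every table written as TSV/CSV plus a JSON
manifest (config hash, file inventory, per-stage wall clock, warnings).
All randomness flows from the config seed through per-purpose substreams,
so identical configs produce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agent, femap, generative, glm, recordings

log = logging.getLogger("meabayes")


@dataclass
class RunConfig:
    """Full configuration of a closed-loop run."""

    seed: int = 0
    n_sessions: int = 16
    epochs_per_session: int = 256
    n_agent_epochs: int | None = None  # None: all epochs
    recording: recordings.RecordingSpec = field(default_factory=lambda: recordings.RecordingSpec(
        learning_curve="agent"))
    agent: agent.AgentConfig = field(default_factory=agent.AgentConfig)
    k_interest: int = 8
    k_drift: int = 32
    f_threshold: float = 80.0
    selection_mode: str = "max_f"
    n_select: int = 512
    smoothing_window: int = 32
    clip_eps: float = 1e-3
    outdir: str = "results/run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["recording"] = recordings.RecordingSpec(**raw.get("recording", {}))
        raw["agent"] = agent.AgentConfig(**raw.get("agent", {}))
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location is not part
        of what the run computes)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Machine-readable inventory of a pipeline run."""

    config_hash: str
    files: dict[str, str]  # name -> sha256 of contents
    stage_seconds: dict[str, float]
    warnings: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_response_matrix(path: str | Path) -> recordings.ResponseMatrix:
    """Validated ingestion of an externally supplied spike-count table."""
    return recordings.read_response_matrix(path)


def _detect_branch(rec, sources, stimuli, cfg, outdir: Path, tag: str, files: dict):
    """GLM fits for both sources, F-maps, selection; returns fits and selections."""
    out = {}
    rows = []
    for source in (0, 1):
        fits = glm.fit_all_electrodes(
            rec.counts, sources, stimuli, source=source,
            k_interest=cfg.k_interest, k_drift=cfg.k_drift,
        )
        fmap = glm.f_map(fits)
        fmap_path = outdir / f"fmap_source{source + 1}_{tag}.csv"
        np.savetxt(fmap_path, fmap, delimiter=",", fmt="%.6g")
        files[fmap_path.name] = _sha(fmap_path)
        sel = glm.select_responses(
            rec.counts, fits, sources, stimuli, mode=cfg.selection_mode,
            threshold=cfg.f_threshold, source=source,
            k_interest=cfg.k_interest, k_drift=cfg.k_drift,
        )
        for e, f in enumerate(fits):
            rows.append(
                {"branch": tag, "source": source + 1, "electrode": e, "F": f.F,
                 "df1": f.df[0], "df2": f.df[1], "p": f.pvalue,
                 "amplitude": float(np.mean(f.learning_curve[-len(f.learning_curve) // 4:]))}
            )
        out[source] = (fits, sel)
    df = pd.DataFrame(rows)
    glm_path = outdir / f"glm_{tag}.tsv"
    df.to_csv(glm_path, sep="\t", index=False)
    files[glm_path.name] = _sha(glm_path)
    return out


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages with true and surrogate sources; write all artefacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    stage_seconds: dict[str, float] = {}
    caught: list[str] = []

    def stage(name):
        class _T:
            def __enter__(self):
                log.info("stage %s", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                stage_seconds[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _T()

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        with stage("simulate"):
            sources = generative.sample_sources(
                config.n_sessions, config.epochs_per_session, seed=config.seed
            )
            stimuli = generative.sample_stimuli(sources, seed=config.seed)
            exp_path = outdir / "experiment.tsv"
            generative.write_experiment(exp_path, sources, stimuli, seed=config.seed)
            files[exp_path.name] = _sha(exp_path)

        with stage("encode"):
            agent_cfg = dataclasses.replace(config.agent, seed=config.seed)
            training = agent.run_training(stimuli, config.n_agent_epochs, agent_cfg)
            # fix the blind learner's arbitrary state labelling against the
            # known generative likelihood before any source-labelled analysis
            training, _ = agent.align_to_reference(training, generative.true_likelihood().probs)
            trace_path = outdir / "agent_trace.tsv"
            agent.write_trace(trace_path, training)
            files[trace_path.name] = _sha(trace_path)

        with stage("record"):
            rec = recordings.generate_recording(
                stimuli, sources, config.recording, seed=config.seed,
                agent_posteriors=training.marginal_rates
                if config.recording.learning_curve == "agent" else None,
            )
            rec_path = outdir / "recording.tsv"
            recordings.write_response_matrix(rec_path, rec)
            files[rec_path.name] = _sha(rec_path)
            surr = recordings.surrogate_sources(sources, seed=config.seed)

        with stage("detect"):
            det_true = _detect_branch(rec, sources, stimuli, config, outdir, "true", files)
            det_surr = _detect_branch(rec, surr, stimuli, config, outdir, "surrogate", files)

        with stage("fe_map"):
            # simulated learning curve: the same GLM applied to the encoder's
            # own source-1 presence unit (its posterior expectation per epoch)
            sim_design = glm.build_design(sources, stimuli, electrode=-1, source=0,
                                          k_interest=config.k_interest, k_drift=config.k_drift)
            sim_curve = glm.fit_glm(training.marginal_rates[:, 1], sim_design).learning_curve
            for tag, det, src in (("true", det_true, sources), ("surrogate", det_surr, surr)):
                fit1, fit2 = det[0][1].fit, det[1][1].fit
                try:
                    post = femap.empirical_posterior(
                        fit1, fit2, src.states, clip_eps=config.clip_eps
                    )
                    mapping = femap.match_learning_curves(
                        fit1.learning_curve, sim_curve, n_select=config.n_select
                    )
                    o_sel = stimuli.outcomes[mapping.empirical_epochs]
                    lnA = np.stack([training.lnA_at(int(e)) for e in mapping.simulation_epochs])
                    recs = femap.empirical_free_energy(
                        o_sel, femap.EmpiricalPosterior(
                            post.marginals[mapping.empirical_epochs], post.clip_eps
                        ), lnA,
                    )
                    plane = femap.smooth_and_plane(recs, window=config.smoothing_window)
                except ValueError as err:  # degenerate surrogate curves are expected
                    caught.append(f"fe_map[{tag}]: {err}")
                    continue
                fe_df = pd.DataFrame(
                    {
                        "epoch": mapping.empirical_epochs,
                        "matched_sim_epoch": mapping.simulation_epochs,
                        "accuracy": [-r.inaccuracy for r in recs],
                        "complexity": [r.state_complexity for r in recs],
                        "F": [r.inaccuracy + r.state_complexity for r in recs],
                    }
                )
                fe_path = outdir / f"femap_{tag}.tsv"
                fe_df.to_csv(fe_path, sep="\t", index=False)
                files[fe_path.name] = _sha(fe_path)
                plane_df = pd.DataFrame(
                    {"complexity": plane.complexity, "accuracy": plane.accuracy, "F": plane.F}
                )
                plane_path = outdir / f"infoplane_{tag}.csv"
                plane_df.to_csv(plane_path, index=False)
                files[plane_path.name] = _sha(plane_path)

        caught.extend(str(w.message) for w in wrec)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        files=files,
        stage_seconds=stage_seconds,
        warnings=caught,
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
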