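"""In-memory closed-loop study: the full analysis chain without file I/O.

Runs protocol simulation, the free-energy-minimising encoder, agent-driven
synthetic recordings, specialisation detection for both sources (true and
surrogate source trains), and the free-energy mapping — returning every
intermediate object so tests and drivers can interrogate any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import agent, femap, generative, glm, recordings


@dataclass
class ClosedLoopResult:
    """Everything the closed-loop synthetic study produces for one seed."""

    sources: generative.SourceTrain
    stimuli: generative.StimulusTrain
    training: agent.TrainingResult  # state-labelling already aligned to the truth
    recording: recordings.ResponseMatrix
    fits: dict  # (branch, source) -> list[GLMFit]; branch in {"true", "surrogate"}
    selections: dict  # (branch, source) -> SelectionResult (max-F electrode)
    planted: dict  # source -> list of ground-truth specialised electrodes
    mapping: femap.EpochMapping | None
    records: list | None  # per-selected-epoch FreeEnergyRecord (true branch)
    plane: femap.InfoPlaneTrajectory | None
    surrogate_records: list | None = None
    surrogate_plane: femap.InfoPlaneTrajectory | None = None
    selected_sessions: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)


def _fe_branch(fit1, fit2, src_states, stimuli, training, sim_curve,
               n_select, window, clip_eps):
    post = femap.empirical_posterior(fit1, fit2, src_states, clip_eps=clip_eps)
    mapping = femap.match_learning_curves(fit1.learning_curve, sim_curve, n_select=n_select)
    o_sel = stimuli.outcomes[mapping.empirical_epochs]
    lnA = np.stack([training.lnA_at(int(e)) for e in mapping.simulation_epochs])
    sel_post = femap.EmpiricalPosterior(post.marginals[mapping.empirical_epochs], clip_eps)
    records = femap.empirical_free_energy(o_sel, sel_post, lnA)
    plane = femap.smooth_and_plane(records, window=window)
    return mapping, records, plane


def closed_loop(
    seed: int,
    n_sessions: int = 8,
    epochs_per_session: int = 256,
    recording_spec: recordings.RecordingSpec | None = None,
    agent_config: agent.AgentConfig | None = None,
    n_select: int = 512,
    window: int = 32,
    clip_eps: float = 1e-3,
    k_interest: int = 8,
    k_drift: int = 32,
) -> ClosedLoopResult:
    """Run the whole synthetic study for one seed and return all stages."""
    sources = generative.sample_sources(n_sessions, epochs_per_session, seed=seed)
    stimuli = generative.sample_stimuli(sources, seed=seed)
    cfg = agent_config or agent.AgentConfig(seed=seed)
    training = agent.run_training(stimuli, None, cfg)
    training, _ = agent.align_to_reference(training, generative.true_likelihood().probs)
    spec = recording_spec or recordings.RecordingSpec(learning_curve="agent")
    rec = recordings.generate_recording(
        stimuli, sources, spec, seed=seed,
        agent_posteriors=training.marginal_rates if spec.learning_curve == "agent" else None,
    )
    surr = recordings.surrogate_sources(sources, seed=seed)

    fits, selections = {}, {}
    for branch, src in (("true", sources), ("surrogate", surr)):
        for source in (0, 1):
            f = glm.fit_all_electrodes(rec.counts, src, stimuli, source=source,
                                       k_interest=k_interest, k_drift=k_drift)
            fits[branch, source] = f
            selections[branch, source] = glm.select_responses(
                rec.counts, f, src, stimuli, mode="max_f", source=source,
                k_interest=k_interest, k_drift=k_drift,
            )
    planted = {
        0: rec.ground_truth["specialised_electrodes"]["source1"],
        1: rec.ground_truth["specialised_electrodes"]["source2"],
    }

    sim_design = glm.build_design(sources, stimuli, electrode=-1, source=0,
                                  k_interest=k_interest, k_drift=k_drift)
    sim_curve = glm.fit_glm(training.marginal_rates[:, 1], sim_design).learning_curve

    notes = []
    mapping = records = plane = None
    surrogate_records = surrogate_plane = None
    selected_sessions = None
    try:
        mapping, records, plane = _fe_branch(
            selections["true", 0].fit, selections["true", 1].fit, sources.states,
            stimuli, training, sim_curve, n_select, window, clip_eps,
        )
        selected_sessions = sources.session_index[mapping.empirical_epochs]
    except ValueError as err:
        notes.append(f"true-branch free-energy mapping failed: {err}")
    try:
        _, surrogate_records, surrogate_plane = _fe_branch(
            selections["surrogate", 0].fit, selections["surrogate", 1].fit, surr.states,
            stimuli, training, sim_curve, n_select, window, clip_eps,
        )
    except ValueError as err:
        notes.append(f"surrogate-branch free-energy mapping failed: {err}")

    return ClosedLoopResult(
        sources=sources, stimuli=stimuli, training=training, recording=rec,
        fits=fits, selections=selections, planted=planted,
        mapping=mapping, records=records, plane=plane,
        surrogate_records=surrogate_records, surrogate_plane=surrogate_plane,
        selected_sessions=selected_sessions, notes=notes,
    )


def session_mean_F(result: ClosedLoopResult, session: int) -> float:
    """Mean smoothed state free energy over selected epochs of one session."""
    if result.plane is None or result.selected_sessions is None:
        raise ValueError("free-energy mapping unavailable for this run")
    # smoothing (valid mode) trims (window - 1) leading epochs
    trim = result.plane.window - 1
    sess = result.selected_sessions[trim:]
    mask = sess == session
    if not mask.any():
        raise ValueError(f"no smoothed epochs in session {session}")
    return float(result.plane.F[mask].mean())
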