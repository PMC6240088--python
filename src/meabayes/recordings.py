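"""Synthetic multi-electrode spike-count recordings.

Emulates the evoked spike counts of a cultured network on an 8x8 grid of 64
dual-use electrodes: an obligatory stimulation-evoked response at stimulated
sites, a slowly drifting baseline, Poisson count noise, and — the signal of
interest — source-selective responses whose amplitude grows with learning.
The selective component implements the encoding assumption that firing-rate
deviations from baseline are proportional to the posterior-minus-prior
expectation about a source (prior 0.5, so a fully confident posterior maps
to plus/minus the specialisation gain on the log-intensity scale).

The generator stores its own ground truth (which electrodes specialise, for
which source, with what gain and learning curve) so every downstream
estimate can be checked against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .generative import N_ELECTRODES, N_SITES, SourceTrain, StimulusTrain


@dataclass
class RecordingSpec:
    """Tunable shape of the synthetic recording.

    Gains act on the log intensity (log link guarantees non-negative
    rates).  ``baseline`` is in counts per one-second epoch.
    """

    baseline: float = 20.0
    stim_gain: float = 0.7  # log-rate boost on epochs when the own site is stimulated
    specialisation_gain: float = 0.5  # log-rate swing at full posterior confidence
    n_specialised_per_source: int = 8
    drift_amplitude: float = 0.2  # std of each random low-order cosine coefficient
    drift_components: int = 4
    noise: str = "poisson"  # "poisson" | "gaussian" | "none"
    gaussian_sd: float = 0.15  # used when noise == "gaussian" (log-intensity scale)
    learning_curve: str = "sigmoid"  # "sigmoid" (parametric) | "agent"
    sigmoid_midpoint_frac: float = 0.4
    sigmoid_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline rate must be non-negative")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise family {self.noise!r}")
        if self.learning_curve not in ("sigmoid", "agent"):
            raise ValueError(f"unknown learning_curve mode {self.learning_curve!r}")
        if not np.isfinite([self.stim_gain, self.specialisation_gain]).all():
            raise ValueError("gains must be finite")


@dataclass
class ResponseMatrix:
    """Evoked responses per electrode per epoch with generator ground truth."""

    counts: np.ndarray  # (64, n_epochs); integer counts, or real intensities
    session_index: np.ndarray  # (n_epochs,)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.session_index = np.asarray(self.session_index, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != N_ELECTRODES:
            raise ValueError(f"counts must be ({N_ELECTRODES}, n_epochs)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.session_index.shape != (self.counts.shape[1],):
            raise ValueError("session_index must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.counts.shape[1]


def sigmoid_learning_curve(n_epochs: int, midpoint_frac: float, rate: float) -> np.ndarray:
    """Parametric learning curve g(t) in [0, 1]: logistic in fractional time."""
    t = np.arange(n_epochs) / max(n_epochs - 1, 1)
    return 1.0 / (1.0 + np.exp(-rate * (t - midpoint_frac)))


def generate_recording(
    stimuli: StimulusTrain,
    sources: SourceTrain,
    spec: RecordingSpec | None = None,
    seed: int = 0,
    agent_posteriors: np.ndarray | None = None,
) -> ResponseMatrix:
    """Simulate a recording from the stimulus train.

    Per electrode e and epoch t the log intensity is

        ln rate = ln(baseline) + stim_gain * o_site(e),t
                  + sum_src gain_{e,src} * g(t) * 2 (m_src,t - 0.5) + drift_e(t)

    where ``m_src,t`` is the true source state (parametric mode) or the
    agent's marginal posterior of source presence (agent mode).  The gain
    envelope ``g(t)`` — a logistic ramp — models the slow synaptic-plasticity
    timescale of the culture in both modes; it is deliberately much slower
    than the encoder's own learning, which the epoch mapping of the
    free-energy analysis later reconciles.  ``agent_posteriors`` is an
    (n_epochs, 4) marginal-rate array as produced by
    :func:`meabayes.agent.run_training` (``marginal_rates``).
    """
    spec = spec or RecordingSpec()
    if sources.n_epochs != stimuli.n_epochs:
        raise ValueError("sources and stimuli must cover the same epochs")
    n = stimuli.n_epochs
    rng = substream(seed, "recording")

    # electrode-wise own-site stimulation indicator (0 for non-stimulated electrodes)
    own = np.zeros((N_ELECTRODES, n))
    for idx in range(N_SITES):
        own[stimuli.site_map[idx]] = stimuli.outcomes[:, idx]

    # which electrodes specialise, and for which source
    gains = np.zeros((N_ELECTRODES, 2))
    k = spec.n_specialised_per_source
    chosen = rng.choice(N_ELECTRODES, size=2 * k, replace=False) if k else np.array([], int)
    gains[chosen[:k], 0] = spec.specialisation_gain
    gains[chosen[k:], 1] = spec.specialisation_gain

    # source-presence signal per epoch
    if spec.learning_curve == "agent":
        if agent_posteriors is None:
            raise ValueError("agent mode requires agent_posteriors covering all epochs")
        ap = np.asarray(agent_posteriors)
        if ap.shape != (n, 4):
            raise ValueError("agent_posteriors must be (n_epochs, 4) marginal rates")
        m = ap[:, [1, 3]]  # presence probability of source 1 and 2
    else:
        m = sources.states.astype(float)
    g = sigmoid_learning_curve(n, spec.sigmoid_midpoint_frac, spec.sigmoid_rate)

    drift_coef = rng.normal(0.0, spec.drift_amplitude, size=(N_ELECTRODES, spec.drift_components))
    phases = rng.uniform(0, 2 * np.pi, size=(N_ELECTRODES, spec.drift_components))
    t = np.arange(n)
    drift = np.zeros((N_ELECTRODES, n))
    for c in range(spec.drift_components):
        drift += drift_coef[:, [c]] * np.cos(np.pi * (c + 1) * t[None, :] / n + phases[:, [c]])

    specialisation = gains @ (g[None, :] * 2 * (m.T - 0.5))  # (64, n)
    log_rate = np.log(max(spec.baseline, np.finfo(float).tiny)) + spec.stim_gain * own
    log_rate = log_rate + specialisation + drift

    if spec.noise == "poisson":
        counts = rng.poisson(np.exp(log_rate)).astype(np.int64)
    elif spec.noise == "gaussian":
        counts = np.maximum(log_rate + rng.normal(0.0, spec.gaussian_sd, log_rate.shape), 0.0)
    else:
        counts = log_rate  # deterministic log intensity, for calibration checks
    truth = {
        "specialised_electrodes": {
            "source1": np.flatnonzero(gains[:, 0]).tolist(),
            "source2": np.flatnonzero(gains[:, 1]).tolist(),
        },
        "gains": gains.tolist(),
        "learning_curve": g.tolist(),
        "mode": spec.learning_curve,
        "seed": seed,
    }
    return ResponseMatrix(counts=counts, session_index=sources.session_index, ground_truth=truth)


def surrogate_sources(sources: SourceTrain, seed: int = 0) -> SourceTrain:
    """Randomised control: permute each source train over epochs.

    Marginal statistics are preserved exactly; the alignment with the
    stimulus train (and with the other source) is destroyed, so any apparent
    specialisation detected against the surrogate train is a false positive.
    """
    rng = substream(seed, "surrogate")
    states = np.column_stack(
        [rng.permutation(sources.states[:, 0]), rng.permutation(sources.states[:, 1])]
    )
    return SourceTrain(
        states=states,
        session_index=sources.session_index.copy(),
        epoch_seconds=sources.epoch_seconds,
    )


def write_response_matrix(path: str | Path, rec: ResponseMatrix) -> None:
    """Electrode-rows x epoch-columns TSV plus a JSON sidecar with ground truth."""
    path = Path(path)
    df = pd.DataFrame(rec.counts, index=[f"e{e}" for e in range(N_ELECTRODES)])
    df.index.name = "electrode"
    df.to_csv(path, sep="\t")
    sidecar = {"session_index": rec.session_index.tolist(), "ground_truth": rec.ground_truth}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_response_matrix(path: str | Path) -> ResponseMatrix:
    """Read a recording written by :func:`write_response_matrix`, validating the schema."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.to_numpy()
    if counts.shape[0] != N_ELECTRODES:
        raise ValueError(f"expected {N_ELECTRODES} electrode rows, found {counts.shape[0]}")
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError("non-numeric entries in response matrix")
    bad = np.argwhere(counts < 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"negative count at electrode row {df.index[r]!r}, epoch column {c}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        session = np.array(sidecar["session_index"])
        truth = sidecar.get("ground_truth", {})
    else:
        session = np.zeros(counts.shape[1], dtype=np.int64)
        truth = {}
    return ResponseMatrix(counts=counts, session_index=session, ground_truth=truth)
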