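"""The stochastic world that generates the stimulation protocol.

Two hidden binary sources, each an i.i.d. Bernoulli(0.5) draw per one-second
epoch, are mixed onto 32 stimulated electrode sites through a fixed
likelihood: pool-1 sites (the first 16) fire with probability 3/4 when only
source 1 is present and 1/4 when only source 2 is present; pool-2 sites (the
last 16) have the mirrored probabilities.  Both sources absent means no
stimulation anywhere; both present means every site is stimulated.  Epochs
are organised into sessions (the in vitro protocol ran 100 sessions of 256
epochs); the rest periods between sessions carry no epochs and appear only
as session boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream

N_SITES = 32
N_ELECTRODES = 64
GRID_SIDE = 8
N_SESSIONS_DEFAULT = 100
EPOCHS_PER_SESSION_DEFAULT = 256
#: joint states of (s1, s2) in a fixed order used throughout the package
JOINT_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class SourceTrain:
    """Per-epoch binary states of the two hidden sources."""

    states: np.ndarray  # (n_epochs, 2) of {0, 1}
    session_index: np.ndarray  # (n_epochs,) int
    epoch_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.session_index = np.asarray(self.session_index, dtype=np.int64)
        if self.states.ndim != 2 or self.states.shape[1] != 2:
            raise ValueError("states must be (n_epochs, 2)")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("source states must be 0 or 1")
        if self.session_index.shape != (self.states.shape[0],):
            raise ValueError("session_index must have one entry per epoch")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")

    @property
    def n_epochs(self) -> int:
        return self.states.shape[0]

    def joint_index(self) -> np.ndarray:
        """Joint state index per epoch: 2*s1 + s2 ∈ {0,1,2,3}."""
        return (2 * self.states[:, 0] + self.states[:, 1]).astype(np.int64)


@dataclass
class StimulusTrain:
    """Per-epoch binary stimulation outcomes at the 32 stimulated sites."""

    outcomes: np.ndarray  # (n_epochs, 32) of {0, 1}
    site_map: np.ndarray  # (32,) distinct 0-based row-major grid positions

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=np.int8)
        self.site_map = np.asarray(self.site_map, dtype=np.int64)
        if self.outcomes.ndim != 2 or self.outcomes.shape[1] != N_SITES:
            raise ValueError(f"outcomes must be (n_epochs, {N_SITES})")
        if not np.isin(self.outcomes, (0, 1)).all():
            raise ValueError("outcomes must be 0 or 1")
        if self.site_map.shape != (N_SITES,) or len(set(self.site_map.tolist())) != N_SITES:
            raise ValueError(f"site_map must hold {N_SITES} distinct positions")
        if self.site_map.min() < 0 or self.site_map.max() >= N_ELECTRODES:
            raise ValueError("site_map positions must lie on the 8x8 grid (0..63)")

    @property
    def n_epochs(self) -> int:
        return self.outcomes.shape[0]


@dataclass(frozen=True)
class LikelihoodArray:
    """Stimulation probabilities indexed (site i, outcome j, s1 level k, s2 level l)."""

    probs: np.ndarray = field()

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (N_SITES, 2, 2, 2):
            raise ValueError(f"likelihood must have shape ({N_SITES}, 2, 2, 2)")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("probabilities must sum to 1 over outcomes")


def true_likelihood() -> LikelihoodArray:
    """The fixed generative likelihood of the stimulation protocol.

    P(o=1 | s1=k, s2=l) is ``[[0, .25], [.75, 1]]`` (rows k, columns l) for
    pool-1 sites and ``[[0, .75], [.25, 1]]`` for pool-2 sites.
    """
    pool1 = np.array([[0.0, 0.25], [0.75, 1.0]])
    pool2 = np.array([[0.0, 0.75], [0.25, 1.0]])
    p1 = np.empty((N_SITES, 2, 2, 2))
    p1[:16, 1] = pool1
    p1[16:, 1] = pool2
    p1[:, 0] = 1.0 - p1[:, 1]
    return LikelihoodArray(p1)


def sample_sources(
    n_sessions: int = N_SESSIONS_DEFAULT,
    epochs_per_session: int = EPOCHS_PER_SESSION_DEFAULT,
    seed: int = 0,
) -> SourceTrain:
    """Draw the two hidden source trains, i.i.d. Bernoulli(0.5) per epoch."""
    if n_sessions < 1 or epochs_per_session < 1:
        raise ValueError("n_sessions and epochs_per_session must be >= 1")
    rng = substream(seed, "sources")
    n = n_sessions * epochs_per_session
    states = rng.integers(0, 2, size=(n, 2))
    session = np.repeat(np.arange(n_sessions), epochs_per_session)
    return SourceTrain(states=states, session_index=session)


def assign_sites(seed: int = 0) -> np.ndarray:
    """Pick the 32 stimulated sites uniformly without replacement from the 8x8 grid."""
    rng = substream(seed, "sites")
    return np.sort(rng.choice(N_ELECTRODES, size=N_SITES, replace=False))


def sample_stimuli(
    sources: SourceTrain,
    A: LikelihoodArray | None = None,
    seed: int = 0,
    site_map: np.ndarray | None = None,
) -> StimulusTrain:
    """Sample per-site stimulation outcomes conditional on the hidden sources.

    Each site's outcome is an independent Bernoulli draw with success
    probability ``A[i, 1, s1, s2]`` for that epoch's source state.
    """
    if A is None:
        A = true_likelihood()
    if site_map is None:
        site_map = assign_sites(seed)
    rng = substream(seed, "stimuli")
    k = sources.states[:, 0]
    l = sources.states[:, 1]
    p = A.probs[:, 1][:, k, l].T  # (n_epochs, 32)
    outcomes = (rng.random(p.shape) < p).astype(np.int8)
    return StimulusTrain(outcomes=outcomes, site_map=np.asarray(site_map))


def write_experiment(
    path: str | Path, sources: SourceTrain, stimuli: StimulusTrain, seed: int | None = None
) -> None:
    """Write the protocol as TSV (epoch, session, s1, s2, o_1..o_32) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "epoch": np.arange(sources.n_epochs),
            "session": sources.session_index,
            "s1": sources.states[:, 0],
            "s2": sources.states[:, 1],
        }
    )
    for i in range(N_SITES):
        df[f"o_{i + 1}"] = stimuli.outcomes[:, i]
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "site_map": stimuli.site_map.tolist(),
        "epoch_seconds": sources.epoch_seconds,
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_experiment(path: str | Path) -> tuple[SourceTrain, StimulusTrain]:
    """Read a protocol written by :func:`write_experiment`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    sources = SourceTrain(
        states=df[["s1", "s2"]].to_numpy(),
        session_index=df["session"].to_numpy(),
        epoch_seconds=float(sidecar.get("epoch_seconds", 1.0)),
    )
    outcomes = df[[f"o_{i + 1}" for i in range(N_SITES)]].to_numpy()
    stimuli = StimulusTrain(outcomes=outcomes, site_map=np.array(sidecar["site_map"]))
    return sources, stimuli
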