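"""From detected specialisation to empirical free energy and the information plane.

The fitted specialisation traces of the GLM are read as posterior
expectations about the sources (a confident specialised response maps to a
posterior of one, a flat response to the uninformative prior 0.5).  The
empirical learning curve is matched, least-squares, to a simulated
encoder's learning curve; for 512 equally spaced empirical epochs the
matched simulation epoch supplies the encoder's likelihood beliefs E[ln A],
and the empirical free energy of each epoch is scored from the actual
stimulation pattern and the empirical posterior.  Parameter complexity is
omitted on this empirical scale (beliefs about A come from the matched
simulation, not from the recording), so F = -accuracy + state complexity
exactly.  Smoothing over 32 epochs and plotting accuracy against complexity
gives the variational information plane; a drop of three nats corresponds
to an evidence odds factor of exp(3), about 20 to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agent import FreeEnergyRecord, PosteriorState, StatePrior, free_energy
from .glm import GLMFit


def evidence_odds(delta_nats: float) -> float:
    """Odds factor corresponding to a free-energy difference in nats: exp(delta)."""
    return float(np.exp(delta_nats))


@dataclass
class EmpiricalPosterior:
    """Per-epoch source-presence probabilities read off the fitted responses."""

    marginals: np.ndarray  # (n_epochs, 2): presence probability per source
    clip_eps: float

    def __post_init__(self) -> None:
        m = np.asarray(self.marginals, dtype=float)
        if m.ndim != 2 or m.shape[1] != 2:
            raise ValueError("marginals must be (n_epochs, 2)")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("marginals must lie in [0, 1]")
        self.marginals = m

    @property
    def joint(self) -> np.ndarray:
        """(n_epochs, 4) mean-field joint: outer product of the two marginals.

        Order (s1, s2) = (0,0), (0,1), (1,0), (1,1).
        """
        m1, m2 = self.marginals[:, 0], self.marginals[:, 1]
        return np.column_stack(
            [(1 - m1) * (1 - m2), (1 - m1) * m2, m1 * (1 - m2), m1 * m2]
        )


def _rescale_marginal(
    fit: GLMFit, source_states: np.ndarray, clip_eps: float, anchor_quantile: float,
    late_fraction: float,
) -> np.ndarray:
    present, absent = fit.present_trace, fit.absent_trace
    trace = np.where(source_states == 1, present, absent)
    if np.max(np.abs(present)) == 0 and np.max(np.abs(absent)) == 0:
        return np.full(trace.shape, 0.5)  # no specialisation: flat prior throughout
    late = present[int(len(present) * (1 - late_fraction)):]
    anchor = np.quantile(late, anchor_quantile)
    if anchor <= 0:
        raise ValueError("degenerate specialisation curve: late fitted response is not positive")
    return np.clip(0.5 + 0.5 * trace / anchor, clip_eps, 1 - clip_eps)


def empirical_posterior(
    fit1: GLMFit,
    fit2: GLMFit,
    sources_states: np.ndarray,
    clip_eps: float = 1e-3,
    anchor_quantile: float = 0.95,
    late_fraction: float = 0.25,
) -> EmpiricalPosterior:
    """Rescale fitted present/absent traces to posterior expectations.

    The scaling anchor — the ``anchor_quantile`` of the late-epoch fitted
    "present" response — maps to posterior 1; the flat prior (zero fitted
    specialisation) maps to 0.5.  Probabilities are clipped to
    ``[clip_eps, 1 - clip_eps]`` so log terms stay finite.
    """
    m1 = _rescale_marginal(fit1, sources_states[:, 0], clip_eps, anchor_quantile, late_fraction)
    m2 = _rescale_marginal(fit2, sources_states[:, 1], clip_eps, anchor_quantile, late_fraction)
    return EmpiricalPosterior(marginals=np.column_stack([m1, m2]), clip_eps=clip_eps)


@dataclass
class EpochMapping:
    """Selected empirical epochs matched to simulation epochs by learning progress."""

    empirical_epochs: np.ndarray  # (n_select,) indices into the recording
    simulation_epochs: np.ndarray  # (n_select,) matched indices into the simulation
    scale: float  # least-squares regression of empirical progress onto simulated
    offset: float


def _progress(curve: np.ndarray) -> np.ndarray:
    """Learning progress: monotone non-decreasing envelope of |specialisation|."""
    return np.maximum.accumulate(np.abs(np.asarray(curve, dtype=float)))


def match_learning_curves(
    empirical: np.ndarray, simulated: np.ndarray, n_select: int = 512
) -> EpochMapping:
    """Match empirical to simulated learning, least squares on monotone progress.

    ``n_select`` equally spaced empirical epochs are each assigned the
    simulation epoch whose progress is nearest to the (affinely matched)
    empirical progress; ties break toward the earlier epoch and the mapping
    is monotone because both progress curves are.
    """
    pe, ps = _progress(empirical), _progress(simulated)
    if np.ptp(pe) == 0 or np.ptp(ps) == 0:
        raise ValueError("learning curves must be non-constant")
    sel = np.round(np.linspace(0, len(pe) - 1, n_select)).astype(int)
    # regress empirical progress onto the simulated progress range
    ps_on_emp = np.interp(np.linspace(0, 1, len(pe)), np.linspace(0, 1, len(ps)), ps)
    A = np.column_stack([pe, np.ones_like(pe)])
    (scale, offset), *_ = np.linalg.lstsq(A, ps_on_emp, rcond=None)
    target = scale * pe[sel] + offset
    lo, hi = ps[0], ps[-1]
    if target.min() < lo - 1e-12 or target.max() > hi + 1e-12:
        import warnings

        warnings.warn("matched progress outside the simulated range; clamping", stacklevel=2)
    target = np.clip(target, lo, hi)
    # nearest simulated progress; searchsorted 'left' breaks ties toward earlier
    right = np.searchsorted(ps, target, side="left")
    right = np.clip(right, 0, len(ps) - 1)
    left = np.maximum(right - 1, 0)
    pick_left = np.abs(ps[left] - target) <= np.abs(ps[right] - target)
    sim_idx = np.where(pick_left, left, right)
    sim_idx = np.maximum.accumulate(sim_idx)  # enforce monotonicity across equal plateaus
    return EpochMapping(
        empirical_epochs=sel,
        simulation_epochs=sim_idx.astype(int),
        scale=float(scale),
        offset=float(offset),
    )


def empirical_free_energy(
    outcomes: np.ndarray,
    posterior: EmpiricalPosterior | np.ndarray,
    lnA_snapshots: np.ndarray,
    prior: StatePrior | None = None,
) -> list[FreeEnergyRecord]:
    """Score the empirical free energy of each selected epoch, in nats.

    ``outcomes`` is (n_select, 32), ``lnA_snapshots`` is (n_select, 32, 2,
    2, 2): the matched simulation's E[ln A] per selected epoch.
    ``posterior`` is an :class:`EmpiricalPosterior` or a raw (n_select, 4)
    joint array.  Parameter complexity is reported as zero: on the empirical
    scale, beliefs about the likelihood come from the matched simulation and
    their complexity is omitted from the decomposition.
    """
    prior = prior or StatePrior()
    joint = posterior.joint if isinstance(posterior, EmpiricalPosterior) else np.asarray(posterior)
    records = []
    for t in range(outcomes.shape[0]):
        s = PosteriorState(joint=joint[t], v=np.log(np.maximum(joint[t], 1e-300)))
        records.append(free_energy(outcomes[t], s, lnA_snapshots[t], prior))
    return records


@dataclass
class InfoPlaneTrajectory:
    """Smoothed accuracy/complexity/free-energy trajectories, in nats."""

    accuracy: np.ndarray  # expected log likelihood (<= 0)
    complexity: np.ndarray  # KL of posterior from prior (>= 0)
    F: np.ndarray  # = -accuracy + complexity
    window: int
    delta_f_reference: float = 3.0  # nats; an odds factor of exp(3) ~ 20


def smooth_and_plane(
    records: list[FreeEnergyRecord], window: int = 32
) -> InfoPlaneTrajectory:
    """Moving-average smoothing (valid region) and the information-plane view."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(records) < window:
        raise ValueError("need at least `window` records")
    acc = np.array([-r.inaccuracy for r in records])
    comp = np.array([r.state_complexity for r in records])
    kern = np.full(window, 1.0 / window)
    acc_s = np.convolve(acc, kern, mode="valid")
    comp_s = np.convolve(comp, kern, mode="valid")
    return InfoPlaneTrajectory(
        accuracy=acc_s, complexity=comp_s, F=-acc_s + comp_s, window=window
    )
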