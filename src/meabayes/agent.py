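"""Bayes-optimal discrete-state encoder minimising variational free energy.

The agent entertains a generative model with four joint hidden states (the
product of two binary sources), a uniform categorical prior over them, and a
Dirichlet-parameterised likelihood mapping from joint state to the 32 binary
stimulation outcomes.  Within each one-second epoch the posterior over
states is found by a softmax of the summed log-likelihood messages — either
in closed form or by the neuronally plausible relaxation in which a voltage
variable integrates prediction errors.  Between epochs the Dirichlet
concentration counts accumulate outcome/state co-occurrences (an associative
Hebbian rule), and the variational free energy is scored exactly, split into
inaccuracy, state complexity and parameter complexity (all in nats).

State transitions are the identity (epochs are exchangeable trials), so no
between-epoch smoothing of beliefs occurs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp, softmax

from ._rng import substream
from .generative import JOINT_STATES, N_SITES, StimulusTrain

N_STATES = len(JOINT_STATES)  # 2 levels per source, 2 sources


@dataclass
class StatePrior:
    """Categorical prior over the four joint source states (uniform by default)."""

    D: np.ndarray = field(default_factory=lambda: np.full(N_STATES, 1.0 / N_STATES))

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (N_STATES,) or not np.isclose(self.D.sum(), 1.0):
            raise ValueError("prior must be a length-4 probability vector")

    @property
    def log(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.D)


@dataclass
class DirichletLikelihood:
    """Concentration counts over (site, outcome, s1 level, s2 level)."""

    counts: np.ndarray  # (32, 2, 2, 2), strictly positive
    prior_counts: np.ndarray  # same shape

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.prior_counts = np.asarray(self.prior_counts, dtype=float)
        if self.counts.shape != (N_SITES, 2, 2, 2):
            raise ValueError(f"counts must have shape ({N_SITES}, 2, 2, 2)")
        if self.prior_counts.shape != self.counts.shape:
            raise ValueError("prior_counts must match counts shape")
        if (self.counts <= 0).any() or (self.prior_counts <= 0).any():
            raise ValueError("Dirichlet counts must be strictly positive")

    @classmethod
    def flat(cls, prior_count: float = 1.0, jitter: float = 0.0, rng=None) -> "DirichletLikelihood":
        """Low-confidence initialisation: every count equals *prior_count*.

        A small positive uniform *jitter* may be added to the learning counts
        (never to the prior used for the KL) to break the exact symmetry of
        the four state columns, without which unsupervised learning sits on
        an unstable uniform fixed point forever.
        """
        prior = np.full((N_SITES, 2, 2, 2), float(prior_count))
        counts = prior.copy()
        if jitter > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            counts = counts + rng.uniform(0.0, jitter, size=counts.shape)
        return cls(counts=counts, prior_counts=prior)

    def mean(self) -> np.ndarray:
        """Posterior expectation of the likelihood, counts normalised over outcomes."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)


@dataclass
class PosteriorState:
    """Posterior expectation over the four joint states, with log expectations."""

    joint: np.ndarray  # (4,), simplex
    v: np.ndarray  # (4,), log expectations (softmax(v) == joint)
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.joint.shape != (N_STATES,):
            raise ValueError("joint must be length 4")
        if not np.isclose(self.joint.sum(), 1.0, atol=1e-10):
            raise ValueError("joint must sum to 1")

    @property
    def marginals(self) -> np.ndarray:
        """(2, 2) array: row per source, columns (absent, present) probabilities."""
        j = self.joint
        m1 = np.array([j[0] + j[1], j[2] + j[3]])
        m2 = np.array([j[0] + j[2], j[1] + j[3]])
        return np.vstack([m1, m2])


@dataclass
class FreeEnergyRecord:
    """One epoch's variational free energy decomposition, in nats."""

    inaccuracy: float
    state_complexity: float
    param_complexity: float

    @property
    def total(self) -> float:
        return self.inaccuracy + self.state_complexity + self.param_complexity


def expected_log_likelihood(a: DirichletLikelihood) -> np.ndarray:
    """E[ln A] under the Dirichlet posterior: psi(a) - psi(sum_j a)."""
    c = a.counts
    if (c <= 0).any():
        raise ValueError("Dirichlet counts must be strictly positive")
    return digamma(c) - digamma(c.sum(axis=1, keepdims=True))


def log_likelihood_messages(lnA: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Sum over sites of the log-likelihood of the observed outcome, per state.

    Returns a length-4 vector over joint states (2*s1 + s2).  Outcomes are
    one-hot over {0, 1} per site, so non-stimulated sites contribute their
    own (informative) log-probability of silence.
    """
    o = np.asarray(o)
    if o.shape != (N_SITES,):
        raise ValueError(f"outcome vector must have length {N_SITES}")
    if not np.isin(o, (0, 1)).all():
        raise ValueError("outcomes must be 0 or 1")
    msg = lnA[np.arange(N_SITES), o.astype(int)]  # (32, 2, 2)
    return msg.sum(axis=0).reshape(N_STATES)


def infer_states(lnA: np.ndarray, o: np.ndarray, prior: StatePrior | None = None) -> PosteriorState:
    """Closed-form posterior over the joint states: softmax(ln D + lnA . o)."""
    prior = prior or StatePrior()
    v = prior.log + log_likelihood_messages(lnA, o)
    # -inf entries (exact zeros in a known likelihood) are handled by softmax
    # via max subtraction; guard the all-(-inf) case
    if not np.isfinite(v).any():
        raise ValueError("all states have zero likelihood for this outcome")
    return PosteriorState(joint=softmax(v), v=v)


def relax_to_posterior(
    lnA: np.ndarray,
    o: np.ndarray,
    prior: StatePrior | None = None,
    step: float = 0.25,
    max_iter: int = 16,
    tol: float = 1e-8,
) -> tuple[PosteriorState, dict]:
    """Neuronal relaxation to the posterior: v integrates prediction errors.

    Iterates ``v <- v + step * eps`` with ``eps = (ln D + lnA . o) - v`` and
    ``s = softmax(v)``.  At the fixed point eps is constant across states up
    to the softmax's additive gauge, so convergence is declared when
    ``max |eps - mean(eps)| < tol``.  Returns the posterior and a trace of
    (v, eps, s) per iteration for response-simulation purposes.
    """
    if not (0 < step <= 1):
        raise ValueError("step must lie in (0, 1]")
    if tol <= 0:
        raise ValueError("tol must be positive")
    prior = prior or StatePrior()
    target = prior.log + log_likelihood_messages(lnA, o)
    v = prior.log.copy()
    vs, epss, ss = [], [], []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eps = target - v
        v = v + step * eps
        s = softmax(v)
        vs.append(v.copy())
        epss.append(eps.copy())
        ss.append(s)
        if np.max(np.abs(eps - eps.mean())) < tol:
            converged = True
            break
    post = PosteriorState(joint=softmax(v), v=v, converged=converged, n_iter=it)
    trace = {"v": np.array(vs), "epsilon": np.array(epss), "s": np.array(ss)}
    return post, trace


def update_counts(a: DirichletLikelihood, o: np.ndarray, s: PosteriorState) -> DirichletLikelihood:
    """Hebbian Dirichlet update: a += o (one-hot) outer s, one unit of mass per site."""
    o = np.asarray(o).astype(int)
    new = a.counts.copy()
    joint = s.joint.reshape(2, 2)
    new[np.arange(N_SITES), o] += joint[None, :, :]
    return DirichletLikelihood(counts=new, prior_counts=a.prior_counts)


def dirichlet_param_complexity(a: DirichletLikelihood, exact: bool = True) -> float:
    """KL divergence between posterior and prior Dirichlet beliefs, in nats.

    With ``exact=False`` returns the truncated bookkeeping form
    ``sum (a_post - a_prior) . E[ln A] - ln Beta(a_post)`` which omits the
    constant ``+ ln Beta(a_prior)``; both are exposed because reference MDP
    implementations differ in which they report.
    """
    post, pri = a.counts, a.prior_counts
    lnA = expected_log_likelihood(a)

    def ln_beta(c):
        return gammaln(c).sum(axis=1) - gammaln(c.sum(axis=1))

    cross = ((post - pri) * lnA).sum(axis=(1, 2, 3))
    lb_post = ln_beta(post).sum(axis=(1, 2))
    if not exact:
        return float((cross - lb_post).sum())
    lb_pri = ln_beta(pri).sum(axis=(1, 2))
    return float((cross - lb_post + lb_pri).sum())


def free_energy(
    o: np.ndarray,
    s: PosteriorState,
    lnA: np.ndarray,
    prior: StatePrior | None = None,
    a: DirichletLikelihood | None = None,
    exact_kl: bool = True,
) -> FreeEnergyRecord:
    """Variational free energy of one epoch, in nats.

    inaccuracy  = -s . lnA . o   (expected negative log likelihood)
    state KL    =  s . ln s - s . ln D   (ln 4 above the negentropy when D is
                   uniform; 0 . ln 0 taken as 0)
    parameter KL = exact Dirichlet KL(Q(A) || P(A)), 0 when *a* is omitted
    """
    prior = prior or StatePrior()
    msgs = log_likelihood_messages(lnA, o)
    j = s.joint
    nz = j > 0
    inacc = -float(np.dot(j[nz], msgs[nz]))
    state_kl = float(np.dot(j[nz], np.log(j[nz]) - prior.log[nz]))
    param_kl = 0.0 if a is None else dirichlet_param_complexity(a, exact=exact_kl)
    return FreeEnergyRecord(inaccuracy=inacc, state_complexity=state_kl, param_complexity=param_kl)


def negative_log_evidence(lnA: np.ndarray, o: np.ndarray, prior: StatePrior | None = None) -> float:
    """-ln sum_s D_s exp(lnA . o) by exhaustive enumeration over the 4 states."""
    prior = prior or StatePrior()
    return -float(logsumexp(prior.log + log_likelihood_messages(lnA, o)))


@dataclass
class AgentConfig:
    """Solver and learning settings for the encoder."""

    step: float = 0.25
    max_iter: int = 16
    tol: float = 1e-8
    prior_count: float = 1.0
    init_jitter: float = 0.01  # symmetry-breaking jitter on initial learning counts
    learn: bool = True
    exact_kl: bool = True
    seed: int = 0


@dataclass
class TrainingResult:
    """Epoch-by-epoch record of a training run."""

    posteriors: np.ndarray  # (n_epochs, 4)
    marginal_rates: np.ndarray  # (n_epochs, 4): absence/presence units per source
    free_energy: pd.DataFrame  # columns inaccuracy, state_complexity, param_complexity, total
    counts_history: np.ndarray  # (n_epochs + 1, 32, 2, 2, 2)
    dirichlet: DirichletLikelihood
    converged: np.ndarray  # (n_epochs,) bool

    def lnA_at(self, epoch: int) -> np.ndarray:
        """E[ln A] under the Dirichlet counts as they stood *after* *epoch*."""
        d = DirichletLikelihood(
            counts=self.counts_history[epoch + 1], prior_counts=self.dirichlet.prior_counts
        )
        return expected_log_likelihood(d)


def run_training(
    stimuli: StimulusTrain,
    n_epochs: int | None = None,
    config: AgentConfig | None = None,
    prior: StatePrior | None = None,
    init_counts: np.ndarray | None = None,
) -> TrainingResult:
    """Run the encoder over a stimulus train: infer, learn, score free energy.

    Per epoch the posterior is found by the within-epoch relaxation, the
    Dirichlet counts accumulate the outcome/posterior co-occurrence, and the
    free energy of the epoch is recorded.  ``marginal_rates`` holds the four
    "unit" firing rates: posterior expectations of absence and presence of
    each source (source-1 absent, source-1 present, source-2 absent,
    source-2 present).
    """
    config = config or AgentConfig()
    prior = prior or StatePrior()
    n_epochs = stimuli.n_epochs if n_epochs is None else int(n_epochs)
    if n_epochs > stimuli.n_epochs:
        raise ValueError("n_epochs exceeds available stimulus epochs")

    rng = substream(config.seed, "agent")
    if init_counts is not None:
        a = DirichletLikelihood(
            counts=np.asarray(init_counts, dtype=float),
            prior_counts=np.full((N_SITES, 2, 2, 2), config.prior_count),
        )
    else:
        a = DirichletLikelihood.flat(config.prior_count, jitter=config.init_jitter, rng=rng)

    posteriors = np.empty((n_epochs, N_STATES))
    rates = np.empty((n_epochs, 4))
    counts_hist = np.empty((n_epochs + 1,) + a.counts.shape)
    counts_hist[0] = a.counts
    conv = np.empty(n_epochs, dtype=bool)
    fe_rows = []
    for t in range(n_epochs):
        o = stimuli.outcomes[t]
        lnA = expected_log_likelihood(a)
        post, _ = relax_to_posterior(
            lnA, o, prior, step=config.step, max_iter=config.max_iter, tol=config.tol
        )
        if config.learn:
            a = update_counts(a, o, post)
        counts_hist[t + 1] = a.counts
        lnA_post = expected_log_likelihood(a)
        rec = free_energy(o, post, lnA_post, prior, a=a if config.learn else None,
                          exact_kl=config.exact_kl)
        posteriors[t] = post.joint
        m = post.marginals
        rates[t] = [m[0, 0], m[0, 1], m[1, 0], m[1, 1]]
        conv[t] = post.converged
        fe_rows.append(
            (rec.inaccuracy, rec.state_complexity, rec.param_complexity, rec.total)
        )
    fe = pd.DataFrame(
        fe_rows, columns=["inaccuracy", "state_complexity", "param_complexity", "total"]
    )
    return TrainingResult(
        posteriors=posteriors,
        marginal_rates=rates,
        free_energy=fe,
        counts_history=counts_hist,
        dirichlet=a,
        converged=conv,
    )


def pool_average(likelihood: np.ndarray) -> np.ndarray:
    """Average a (32, 2, 2, 2) likelihood over the two 16-site pools -> (2, 2, 2, 2).

    The generative likelihood is constant within each pool, so the
    pool-averaged matrix is the natural summary when comparing a learned
    likelihood to the generative one: site-level entries carry binomial
    sampling noise of order ``sqrt(p(1-p)/n_visits)`` that the pool mean
    suppresses sixteen-fold.
    """
    return np.stack([likelihood[:16].mean(axis=0), likelihood[16:].mean(axis=0)])


def state_relabellings() -> list[tuple[int, ...]]:
    """All bijections of the four joint states.

    With a uniform state prior and a symmetric Dirichlet prior the
    categorical model is exactly invariant under any relabelling of its four
    hidden states; a blind learner can converge to any of them.  Swapping
    the two sources and flipping either source's present/absent labels are
    special cases.
    """
    import itertools

    return list(itertools.permutations(range(N_STATES)))


def _apply_relabelling(m: np.ndarray, perm: tuple[int, ...]) -> np.ndarray:
    states = [(0, 0), (0, 1), (1, 0), (1, 1)]
    out = np.empty_like(m)
    for a, b in enumerate(perm):
        out[..., states[a][0], states[a][1]] = m[..., states[b][0], states[b][1]]
    return out


def resolve_state_relabelling(
    learned_mean: np.ndarray, reference: np.ndarray, pool_level: bool = True
) -> tuple[tuple[int, ...], float]:
    """Best-matching state relabelling and its max-abs recovery error.

    With ``pool_level`` (default) the comparison is between pool-averaged
    likelihoods, the scale on which the generative matrix is defined.
    """
    if pool_level:
        learned_mean = pool_average(learned_mean)
        reference = pool_average(reference)
    best_perm, best_err = None, np.inf
    for perm in state_relabellings():
        err = float(np.max(np.abs(_apply_relabelling(learned_mean, perm) - reference)))
        if err < best_err:
            best_perm, best_err = perm, err
    return best_perm, best_err


def relabel_training(result: TrainingResult, perm: tuple[int, ...]) -> TrainingResult:
    """Apply a state relabelling to every state-indexed quantity of a run."""
    joint = result.posteriors[:, list(perm)]
    m1 = joint[:, 2] + joint[:, 3]
    m2 = joint[:, 1] + joint[:, 3]
    rates = np.column_stack([1 - m1, m1, 1 - m2, m2])
    counts = _apply_relabelling(result.counts_history, perm)
    dirichlet = DirichletLikelihood(
        counts=_apply_relabelling(result.dirichlet.counts, perm),
        prior_counts=result.dirichlet.prior_counts,
    )
    return TrainingResult(
        posteriors=joint,
        marginal_rates=rates,
        free_energy=result.free_energy,  # label-invariant
        counts_history=counts,
        dirichlet=dirichlet,
        converged=result.converged,
    )


def align_to_reference(
    result: TrainingResult, reference: np.ndarray
) -> tuple[TrainingResult, tuple[int, ...]]:
    """Relabel a blind run's states to best match a reference likelihood.

    A blind learner's state labels are arbitrary (see
    :func:`state_relabellings`); downstream analyses that compare the
    agent's beliefs with the true sources — or hand its posteriors to the
    recording generator — first fix the gauge by matching the learned
    likelihood to the known generative one, exactly as simulated units are
    interpreted post hoc as encoding the presence of a particular source.
    """
    perm, _ = resolve_state_relabelling(result.dirichlet.mean(), reference, pool_level=True)
    return relabel_training(result, perm), perm


def write_trace(path: str | Path, result: TrainingResult) -> None:
    """Per-epoch posterior and free-energy trace as TSV."""
    df = pd.DataFrame(
        result.posteriors, columns=["s_00", "s_01", "s_10", "s_11"]
    )
    df.insert(0, "epoch", np.arange(len(df)))
    out = pd.concat([df, result.free_energy.rename(columns={"total": "F"})], axis=1)
    out.to_csv(path, sep="\t", index=False)


def save_agent(path: str | Path, result: TrainingResult, config: AgentConfig) -> None:
    """Serialise the final agent state (counts + config) to an NPZ archive."""
    path = Path(path)
    np.savez(
        path,
        counts=result.dirichlet.counts,
        prior_counts=result.dirichlet.prior_counts,
        config=json.dumps(vars(config)),
    )
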