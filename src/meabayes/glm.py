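"""Detection of emerging functional specialisation by GLM, F-maps and CVA.

Each electrode's per-epoch response is modelled by ordinary least squares
with an effects-of-interest partition — the interaction between the centred
presence indicator of one source and a low-order discrete cosine transform
(DCT) basis over epochs, which lets the selectivity emerge at an arbitrary
rate — against confounds: the electrode's own-site stimulation indicator,
the per-epoch total stimulation count, a higher-order DCT drift basis, the
other source's (centred) main effect and an intercept.  The extra
sum-of-squares partial F statistic for the interest partition quantifies
specialisation; F values placed on the 8x8 grid give a statistical
parametric map.  A canonical variates analysis generalises the univariate
fit to the best linear mixture of electrode responses.

p-values come from the central F distribution; no multiple-testing
correction is applied across electrodes (maps are descriptive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .generative import GRID_SIDE, N_ELECTRODES, N_SITES, SourceTrain, StimulusTrain


def dct_basis(n_epochs: int, n_components: int) -> np.ndarray:
    """Orthonormal DCT-II basis over the epoch index; column 0 is constant."""
    if not (1 <= n_components <= n_epochs):
        raise ValueError("need 1 <= n_components <= n_epochs")
    t = np.arange(n_epochs)
    k = np.arange(n_components)
    basis = np.cos(np.pi * np.outer(2 * t + 1, k) / (2 * n_epochs))
    basis[:, 0] *= np.sqrt(1.0 / n_epochs)
    if n_components > 1:
        basis[:, 1:] *= np.sqrt(2.0 / n_epochs)
    return basis


@dataclass
class DesignMatrix:
    """Assembled design with an interest/confound column partition."""

    X: np.ndarray  # (n_epochs, p)
    labels: list[str]
    interest: np.ndarray  # column indices of the effects of interest
    confounds: np.ndarray  # column indices of the confounds
    source: int  # which source's emergence is being tested (0 or 1)
    indicator_mean: float  # mean of the raw source-presence indicator
    rank_deficient: bool = False

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(
    sources: SourceTrain,
    stimuli: StimulusTrain,
    electrode: int,
    source: int = 0,
    k_interest: int = 8,
    k_drift: int = 32,
) -> DesignMatrix:
    """Design for one electrode and one source.

    Interest columns: each of the first ``k_interest`` DCT components
    multiplied by the centred source-presence indicator (the DC component
    carries any constant selectivity; centring makes every interest column
    orthogonal to the intercept).  Confounds: own-site stimulation indicator
    (only for electrodes that are stimulated sites), total stimulation count
    per epoch, ``k_drift`` non-constant DCT drift columns, the other
    source's centred indicator, and the intercept.
    """
    if sources.n_epochs != stimuli.n_epochs:
        raise ValueError("sources and stimuli must cover the same epochs")
    n = sources.n_epochs
    ind = sources.states[:, source].astype(float)
    other = sources.states[:, 1 - source].astype(float)
    ind_mean = float(ind.mean())
    centred = ind - ind_mean

    dct_int = dct_basis(n, k_interest)
    interest_cols = dct_int * centred[:, None]
    labels = [f"src{source + 1}_x_dct{k}" for k in range(k_interest)]

    conf_cols, conf_labels = [], []
    site_idx = np.flatnonzero(stimuli.site_map == electrode)
    if site_idx.size:
        conf_cols.append(stimuli.outcomes[:, site_idx[0]].astype(float))
        conf_labels.append("own_site_stim")
    conf_cols.append(stimuli.outcomes.sum(axis=1).astype(float))
    conf_labels.append("total_stim")
    drift = dct_basis(n, k_drift + 1)[:, 1:]  # non-constant components only
    for k in range(k_drift):
        conf_cols.append(drift[:, k])
        conf_labels.append(f"drift_dct{k + 1}")
    conf_cols.append(other - other.mean())
    conf_labels.append(f"src{2 - source}_main")
    conf_cols.append(np.ones(n))
    conf_labels.append("intercept")

    X = np.column_stack([interest_cols] + [np.asarray(c) for c in conf_cols])
    labels = labels + conf_labels
    interest = np.arange(k_interest)
    confounds = np.arange(k_interest, X.shape[1])
    rank = np.linalg.matrix_rank(X)
    return DesignMatrix(
        X=X,
        labels=labels,
        interest=interest,
        confounds=confounds,
        source=source,
        indicator_mean=ind_mean,
        rank_deficient=rank < X.shape[1],
    )


@dataclass
class GLMFit:
    """OLS fit with the partial F test for the interest partition."""

    coef: np.ndarray
    sigma2: float
    F: float
    df: tuple[int, int]
    pvalue: float
    present_trace: np.ndarray  # fitted interest component when the source is present
    absent_trace: np.ndarray  # ... and when it is absent
    design: DesignMatrix = field(repr=False)

    @property
    def learning_curve(self) -> np.ndarray:
        """Present-minus-absent fitted specialisation per epoch."""
        return self.present_trace - self.absent_trace


def fit_glm(y: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares with the extra-sum-of-squares partial F."""
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n,):
        raise ValueError("response length must match the design")
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    X = design.X
    if design.rank_deficient:
        warnings.warn("rank-deficient design; using pseudoinverse", stacklevel=2)
    beta, _, rank_full, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss_full = float(resid @ resid)
    Xc = X[:, design.confounds]
    beta_c, _, _, _ = np.linalg.lstsq(Xc, y, rcond=None)
    rss_red = float(np.sum((y - Xc @ beta_c) ** 2))

    p_int = len(design.interest)
    df2 = design.n - rank_full
    sigma2 = rss_full / df2
    extra = max(rss_red - rss_full, 0.0)
    # numerically-zero extra sum of squares (y in the confound span) -> F = 0
    if extra <= 1e-12 * float(y @ y) or sigma2 <= 0:
        F = 0.0
    else:
        F = (extra / p_int) / sigma2
    pval = float(stats.f.sf(F, p_int, df2))

    # interest columns are dct * centred indicator; the fitted interest
    # component at the two indicator levels (present: 1 - mean, absent: -mean)
    dct_int = dct_basis(design.n, p_int)
    mix = dct_int @ beta[design.interest]
    present = mix * (1.0 - design.indicator_mean)
    absent = mix * (0.0 - design.indicator_mean)
    return GLMFit(
        coef=beta,
        sigma2=sigma2,
        F=float(F),
        df=(p_int, df2),
        pvalue=pval,
        present_trace=present,
        absent_trace=absent,
        design=design,
    )


def mean_amplitude(fit: GLMFit) -> tuple[float, float]:
    """Epoch-averaged specialisation amplitude (present minus absent) and its SE.

    The learning curve is ``dct_int @ beta_int``, so its epoch mean is a
    linear contrast of the interest coefficients; the standard error follows
    from the OLS coefficient covariance.
    """
    design = fit.design
    p_int = len(design.interest)
    c = np.zeros(design.p)
    c[design.interest] = dct_basis(design.n, p_int).mean(axis=0)
    xtx_inv = np.linalg.pinv(design.X.T @ design.X)
    se = float(np.sqrt(fit.sigma2 * c @ xtx_inv @ c))
    return float(np.mean(fit.learning_curve)), se


def fit_all_electrodes(
    responses: np.ndarray,
    sources: SourceTrain,
    stimuli: StimulusTrain,
    source: int = 0,
    k_interest: int = 8,
    k_drift: int = 32,
) -> list[GLMFit]:
    """Fit the specialisation GLM for every electrode row of *responses*."""
    fits = []
    for e in range(responses.shape[0]):
        design = build_design(sources, stimuli, e, source, k_interest, k_drift)
        fits.append(fit_glm(responses[e], design))
    return fits


def f_map(fits: list[GLMFit], electrodes: np.ndarray | None = None) -> np.ndarray:
    """Place per-electrode F values on the 8x8 grid (row-major); missing -> NaN."""
    grid = np.full(N_ELECTRODES, np.nan)
    if electrodes is None:
        electrodes = np.arange(len(fits))
    for e, fit in zip(electrodes, fits):
        grid[e] = fit.F
    return grid.reshape(GRID_SIDE, GRID_SIDE)


@dataclass
class SelectionResult:
    """Summary response series selected for the free-energy mapping."""

    mode: str
    electrodes: np.ndarray  # selected electrode indices (empty allowed)
    series: np.ndarray | None  # the selected/combined response per epoch
    fit: GLMFit | None  # GLM refit of the selected series
    empty: bool = False


def select_responses(
    responses: np.ndarray,
    fits: list[GLMFit],
    sources: SourceTrain,
    stimuli: StimulusTrain,
    mode: str = "max_f",
    threshold: float = 80.0,
    source: int = 0,
    k_interest: int = 8,
    k_drift: int = 32,
) -> SelectionResult:
    """Reduce the 64-electrode recording to one specialisation series.

    ``max_f``: the single electrode with the largest F.  ``threshold_mean``:
    average the responses of all electrodes whose F exceeds *threshold*,
    then refit.  ``cva``: the principal canonical variate.
    """
    fvals = np.array([f.F for f in fits])
    if mode == "max_f":
        e = int(np.argmax(fvals))
        design = build_design(sources, stimuli, e, source, k_interest, k_drift)
        return SelectionResult("max_f", np.array([e]), responses[e], fit_glm(responses[e], design))
    if mode == "threshold_mean":
        passing = np.flatnonzero(fvals > threshold)
        if passing.size == 0:
            return SelectionResult("threshold_mean", passing, None, None, empty=True)
        series = responses[passing].mean(axis=0)
        design = build_design(sources, stimuli, int(passing[0]), source, k_interest, k_drift)
        return SelectionResult("threshold_mean", passing, series, fit_glm(series, design))
    if mode == "cva":
        res = cva(responses.T, sources, stimuli, source=source,
                  k_interest=k_interest, k_drift=k_drift)
        return SelectionResult("cva", np.arange(responses.shape[0]), res.variate, res.fit)
    raise ValueError(f"unknown selection mode {mode!r}")


@dataclass
class CVAResult:
    """Principal canonical variate of the multivariate specialisation GLM."""

    weights: np.ndarray  # (n_electrodes,)
    variate: np.ndarray  # (n_epochs,), unit norm
    canonical_corr: float
    wilks_pvalue: float  # Bartlett chi-square approximation over all variates
    fit: GLMFit  # univariate GLM refit of the variate
    ridge: float = 0.0


def cva(
    Y: np.ndarray,
    sources: SourceTrain,
    stimuli: StimulusTrain,
    source: int = 0,
    k_interest: int = 8,
    k_drift: int = 32,
    ridge: float | None = None,
) -> CVAResult:
    """Canonical variates analysis against the interest partition.

    *Y* is epochs x electrodes.  Both Y and the interest columns are
    residualised against the confounds; the principal canonical variate is
    the linear mixture of electrode responses maximally explained by the
    interest partition (generalised eigenproblem of hypothesis vs error
    sums of squares).  Ill-conditioned error covariances are handled by a
    logged ridge on the error matrix.
    """
    Y = np.asarray(Y, dtype=float)
    n, q = Y.shape
    design = build_design(sources, stimuli, electrode=-1, source=source,
                          k_interest=k_interest, k_drift=k_drift)
    Xc = design.X[:, design.confounds]
    Xi = design.X[:, design.interest]
    # residual-forming projection against confounds
    Qc, _ = np.linalg.qr(Xc)
    Yr = Y - Qc @ (Qc.T @ Y)
    Xr = Xi - Qc @ (Qc.T @ Xi)
    Qi, _ = np.linalg.qr(Xr)
    H = (Qi.T @ Yr).T @ (Qi.T @ Yr)  # hypothesis SSCP
    E = Yr.T @ Yr - H  # error SSCP
    if ridge is None:
        ridge = 0.0
        cond = np.linalg.cond(E)
        if not np.isfinite(cond) or cond > 1e10:
            ridge = 1e-6 * np.trace(E) / q
            warnings.warn(f"ill-conditioned error covariance; ridge={ridge:.3g}", stacklevel=2)
    evals, evecs = _sym_geig(H, E + ridge * np.eye(q))
    order = np.argsort(evals)[::-1]
    lam = np.maximum(evals[order], 0.0)
    w = evecs[:, order[0]]
    u = Yr @ w
    u_norm = np.linalg.norm(u)
    if u_norm > 0:
        u = u / u_norm
    cc = float(np.sqrt(lam[0] / (1.0 + lam[0])))

    # Bartlett's chi-square approximation on Wilks' lambda
    r = min(q, Xr.shape[1])
    wilks = float(np.prod(1.0 / (1.0 + lam[:r])))
    n_eff = n - np.linalg.matrix_rank(Xc)
    chi2 = -(n_eff - 1 - (q + Xr.shape[1] + 1) / 2.0) * np.log(max(wilks, 1e-300))
    pval = float(stats.chi2.sf(chi2, q * Xr.shape[1]))

    fit = fit_glm(u, design)
    # rotation-invariant sign convention: positive late-epoch specialisation
    tail = fit.learning_curve[-max(n // 4, 1):]
    if tail.mean() < 0:
        w, u = -w, -u
        fit = fit_glm(u, design)
    return CVAResult(weights=w, variate=u, canonical_corr=cc,
                     wilks_pvalue=pval, fit=fit, ridge=ridge)


def _sym_geig(H: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Generalised symmetric eigenproblem H w = lambda E w via Cholesky whitening."""
    L = np.linalg.cholesky(E)
    Linv = np.linalg.inv(L)
    M = Linv @ H @ Linv.T
    evals, V = np.linalg.eigh((M + M.T) / 2)
    return evals, Linv.T @ V
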