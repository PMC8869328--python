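"""Epoch-based entropy (EpEn): HMM segmentation + per-epoch entropy.

The measure models one channel (1-D observations) or a channel pair (2-D
observations) with a continuous left-to-right hidden Markov model whose
states carry Gaussian-mixture emission densities.  The states play the role
of piecewise-stationary *epochs* of the EEG: the Viterbi path segments the
signal into N contiguous epochs (matched across the two channels but not of
equal length), the mixture density of each state is evaluated at the
observations inside its epoch, and the epoch entropy is

    H*(S_i) = - sum_{z in S_i} P_i(z) * log2 P_i(z)          (literal form)

with EpEn the arithmetic mean of the N epoch entropies.  A high EpEn
indicates a high information content conveyed by the coupling of the two
signals.

Two estimators ship, because the literal form sums *density* values (not
probability masses), so it is length-dependent and can go negative for very
peaked densities:

``estimator="literal"`` (default)
    the formula above, exactly as printed;
``estimator="normalized"``
    the per-sample average negative log-density
    ``-(1/|S_i|) sum log2 P_i(z)``, a plug-in estimate of the differential
    entropy of the epoch's emission distribution.

Model fitting is Baum–Welch (EM) under a Bakis left-to-right topology
(self-transitions plus forward skips of at most one state), initialised
deterministically from a uniform segmentation of the sequence into
``n_states`` contiguous blocks.  Because the likelihood of a Gaussian
mixture is unbounded (a component can collapse onto a single point), the
M-step carries a small inverse-Wishart ridge on every covariance; the
training objective reported in ``loglik_trace`` is the penalized
log-likelihood this MAP-EM provably never decreases.  Observations are
standardized per channel before fitting by default (prevents scale-driven
degeneracy of the mixture covariances); full covariances are used for 2-D
observations so the cross term carries the inter-channel dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from epenet.connectivity import AdjacencyMatrix, DegenerateSignalError

__all__ = [
    "HMMSpec",
    "EpochSegmentation",
    "EpEnParams",
    "EpEnResult",
    "fit_hmm",
    "viterbi_segment",
    "epoch_entropy",
    "epen_pair",
    "epen_matrix",
]

_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class HMMSpec:
    """A fitted left-to-right Gaussian-mixture HMM.

    Shapes: ``startprob (S,)``, ``transmat (S, S)`` upper-triangular
    row-stochastic, ``weights (S, M)``, ``means (S, M, D)``,
    ``covars (S, M, D, D)``.
    """

    startprob: np.ndarray
    transmat: np.ndarray
    weights: np.ndarray
    means: np.ndarray
    covars: np.ndarray
    loglik_trace: tuple[float, ...] = ()
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        tm = np.asarray(self.transmat, dtype=float)
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.tril(tm, -1) > 1e-12):
            raise ValueError("left-to-right HMM: no backward transitions allowed")
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("mixture weights per state must sum to 1")

    @property
    def n_states(self) -> int:
        return self.transmat.shape[0]

    @property
    def n_mixtures(self) -> int:
        return self.weights.shape[1]

    @property
    def obs_dim(self) -> int:
        return self.means.shape[2]

    def state_log_density(self, obs: np.ndarray) -> np.ndarray:
        """Log mixture density of every state at every observation, (T, S)."""
        obs = _as_obs(obs, self.obs_dim)
        T = obs.shape[0]
        S, M, D = self.means.shape
        out = np.empty((T, S))
        for s in range(S):
            comp = np.empty((T, M))
            for m in range(M):
                comp[:, m] = _gauss_logpdf(obs, self.means[s, m], self.covars[s, m])
            with np.errstate(divide="ignore"):
                logw = np.log(self.weights[s])
            out[:, s] = logsumexp(comp + logw[None, :], axis=1)
        return out


@dataclass(frozen=True)
class EpochSegmentation:
    """Viterbi state path and the contiguous epochs it induces."""

    state_path: np.ndarray  # (T,) non-decreasing state indices
    epochs: tuple[tuple[int, int], ...]  # half-open [start, end) sample intervals
    epoch_states: tuple[int, ...]  # the state of each epoch

    def __post_init__(self) -> None:
        path = np.asarray(self.state_path, dtype=int)
        if np.any(np.diff(path) < 0):
            raise ValueError("left-to-right state path must be non-decreasing")
        starts = [a for a, _ in self.epochs]
        ends = [b for _, b in self.epochs]
        if starts and (starts[0] != 0 or ends[-1] != len(path) or
                       any(e != s for e, s in zip(ends[:-1], starts[1:]))):
            raise ValueError("epochs must partition the segment")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)


@dataclass(frozen=True)
class EpEnParams:
    """Tunables of the EpEn estimator (all config-exposed)."""

    n_states: int = 10
    n_mixtures: int = 3
    max_iter: int = 100
    tol: float = 1e-4  # relative log-likelihood change
    sticky: float = 5.0  # Dirichlet pseudocounts on self-transitions
    # epochs shorter than this fraction of the nominal length T/n_states
    # mark a degenerate (collapsed) state; the model is refit with one state
    # fewer until every epoch is substantial
    min_epoch_fraction: float = 0.25
    seed: int = 0
    standardize: bool = True
    estimator: str = "literal"  # or "normalized"
    covariance: str = "full"  # or "diag"
    density_floor: float = 1e-300


@dataclass(frozen=True)
class EpEnResult:
    """EpEn of one signal (pair): per-epoch entropies and their mean, in bits."""

    epoch_entropies: np.ndarray
    epen: float
    hmm: HMMSpec
    segmentation: EpochSegmentation
    diagnostics: dict = field(default_factory=dict)


def _as_obs(obs: np.ndarray, dim: int | None = None) -> np.ndarray:
    obs = np.asarray(obs, dtype=float)
    if obs.ndim == 1:
        obs = obs[:, None]
    if obs.ndim != 2:
        raise ValueError("observations must be a T x D array")
    if dim is not None and obs.shape[1] != dim:
        raise ValueError(f"observation dimension {obs.shape[1]} does not match model dim {dim}")
    return obs


def _gauss_logpdf(obs: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate normal log-density, T points at once (D small)."""
    D = mean.shape[0]
    diff = obs - mean[None, :]
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (D * np.log(2 * np.pi) + logdet + maha)


def _bakis_transmat(S: int) -> np.ndarray:
    """Left-to-right transitions: self + next state + skip of one state."""
    tm = np.zeros((S, S))
    for i in range(S):
        tm[i, i] = 0.90
        if i + 1 < S:
            tm[i, i + 1] = 0.08
        if i + 2 < S:
            tm[i, i + 2] = 0.02
        tm[i] /= tm[i].sum()
    return tm


def _uniform_segmentation_init(obs: np.ndarray, S: int, M: int):
    """Deterministic EM start: split the sequence into S contiguous blocks;
    per block, mixture means from M quantile chunks along the first
    coordinate, shared block covariance with a small ridge."""
    T, D = obs.shape
    means = np.zeros((S, M, D))
    covars = np.zeros((S, M, D, D))
    weights = np.full((S, M), 1.0 / M)
    for i, block in enumerate(np.array_split(obs, S)):
        order = np.argsort(block[:, 0], kind="stable")
        chunks = np.array_split(block[order], M)
        cov = np.atleast_2d(np.cov(block.T)) + 1e-3 * np.eye(D)
        for m, chunk in enumerate(chunks):
            means[i, m] = chunk.mean(axis=0) if len(chunk) else block.mean(axis=0)
            covars[i, m] = cov
    return means, covars, weights


# Inverse-Wishart ridge on covariances: Psi = _COV_RIDGE * I, dof nu = D + 2.
# On standardized observations this is far below the honest state variances
# but blocks the degenerate direction of the mixture likelihood (a component
# collapsing onto a point drives the penalized objective to -inf, not +inf).
_COV_RIDGE = 1e-3


def _component_logpdf(obs: np.ndarray, means: np.ndarray, covars: np.ndarray) -> np.ndarray:
    """(T, S, M) log-density of every mixture component at every sample."""
    T = obs.shape[0]
    S, M, _ = means.shape
    out = np.empty((T, S, M))
    for s in range(S):
        for m in range(M):
            out[:, s, m] = _gauss_logpdf(obs, means[s, m], covars[s, m])
    return out


def _log_prior(covars: np.ndarray, psi_scale: float, nu: float,
               transmat: np.ndarray, sticky: float) -> float:
    """Log-density of the priors (up to constants): inverse-Wishart ridge on
    every covariance plus a Dirichlet boost on self-transitions."""
    S, M, D, _ = covars.shape
    val = 0.0
    for s in range(S):
        for m in range(M):
            chol = np.linalg.cholesky(covars[s, m])
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            inv_trace = np.sum(np.linalg.inv(covars[s, m]).diagonal()) * psi_scale
            val += -0.5 * (nu + D + 1) * logdet - 0.5 * inv_trace
    if sticky > 0:
        val += sticky * float(np.sum(np.log(np.diag(transmat))))
    return val


def fit_hmm(
    obs: np.ndarray,
    n_states: int = 10,
    n_mixtures: int = 3,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
    covariance: str = "full",
    sticky: float = 5.0,
) -> HMMSpec:
    """Baum–Welch fit of a left-to-right Gaussian-mixture HMM.

    ``sticky`` adds Dirichlet pseudocounts on the self-transitions, which
    discourages degenerate sliver epochs (a state claiming one or two
    samples and collapsing its covariance onto them).

    Initialisation is the deterministic uniform segmentation described in the
    module docstring, so identical data give identical fits (``seed`` is
    accepted for interface uniformity; the fit involves no randomness).
    Convergence is declared when the relative change of the training
    objective drops below ``tol``; non-convergence within ``max_iter`` is
    flagged on the result, never silent.  ``loglik_trace`` records the
    penalized log-likelihood (data log-likelihood plus the covariance ridge
    prior), which is non-decreasing across iterations by the EM guarantee.
    """
    del seed  # deterministic fit; parameter kept for interface stability
    obs = _as_obs(obs)
    T, D = obs.shape
    if D not in (1, 2):
        raise ValueError(f"observation dimension must be 1 or 2, got {D}")
    if np.any(obs.std(axis=0) == 0):
        raise DegenerateSignalError("zero-variance observation stream; HMM fit undefined")
    if T < n_states * n_mixtures * 10:
        raise ValueError(
            f"sequence too short for identifiability: T={T} < {n_states * n_mixtures * 10}"
        )
    if covariance not in ("full", "diag"):
        raise ValueError(f"covariance must be 'full' or 'diag', got {covariance!r}")

    S, M = n_states, n_mixtures
    nu = D + 2.0
    # scale-aware ridge keeps the fit equivariant under amplitude rescaling
    psi = _COV_RIDGE * float(np.mean(obs.var(axis=0)))
    # free entry distribution: the path may begin in any state (and remains
    # non-decreasing); a forced state-0 entry would squeeze surplus states
    # into degenerate sliver epochs at the segment start
    startprob = np.full(S, 1.0 / S)
    transmat = _bakis_transmat(S)
    means, covars, weights = _uniform_segmentation_init(obs, S, M)
    allowed = transmat > 0  # structural left-to-right mask
    pi = startprob
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # --- E step (scaled forward-backward) ------------------------------
        comp = _component_logpdf(obs, means, covars)  # (T, S, M)
        with np.errstate(divide="ignore"):
            logw = np.log(weights)
        logb = logsumexp(comp + logw[None, :, :], axis=2)  # (T, S)
        shift = logb.max(axis=1)
        B = np.exp(logb - shift[:, None])  # per-row max is 1: no under/overflow

        alpha_hat = np.empty((T, S))
        c = np.empty(T)
        a = pi * B[0]
        c[0] = a.sum()
        alpha_hat[0] = a / c[0]
        for t in range(1, T):
            a = (alpha_hat[t - 1] @ transmat) * B[t]
            c[t] = a.sum()
            alpha_hat[t] = a / c[t]
        loglik = float(np.sum(np.log(c)) + np.sum(shift))

        objective = loglik + _log_prior(covars, psi, nu, transmat, sticky)
        trace.append(objective)
        if len(trace) > 1:
            delta = trace[-1] - trace[-2]
            if delta < tol * max(abs(trace[-2]), 1.0):
                converged = True
                break

        beta_hat = np.empty((T, S))
        beta_hat[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta_hat[t] = (transmat @ (B[t + 1] * beta_hat[t + 1])) / c[t + 1]

        gamma = alpha_hat * beta_hat  # (T, S), rows sum to 1
        # component responsibilities within each state
        logresp = comp + logw[None, :, :] - logb[:, :, None]
        gamma_c = gamma[:, :, None] * np.exp(logresp)  # (T, S, M)

        # expected transition counts (structural zeros stay zero)
        xi_sum = transmat * np.einsum(
            "ti,tj->ij", alpha_hat[:-1], B[1:] * beta_hat[1:] / c[1:, None]
        )
        xi_sum = np.where(allowed, xi_sum, 0.0)

        # --- M step -------------------------------------------------------
        pi = gamma[0] / gamma[0].sum()
        xi_post = xi_sum + sticky * np.eye(S)  # Dirichlet self-transition boost
        row = xi_post.sum(axis=1, keepdims=True)
        transmat = np.where(row > 0, xi_post / np.where(row > 0, row, 1.0), transmat)
        # a state never left keeps its previous outgoing distribution
        n_sm = gamma_c.sum(axis=0)  # (S, M)
        n_s = gamma.sum(axis=0)  # (S,)
        weights = np.where(n_s[:, None] > 0, n_sm / np.where(n_s[:, None] > 0, n_s[:, None], 1.0), weights)
        for s in range(S):
            for m in range(M):
                if n_sm[s, m] <= 1e-12:
                    continue  # dead component: parameters frozen, weight ~ 0
                r = gamma_c[:, s, m]
                mu = (r[:, None] * obs).sum(axis=0) / n_sm[s, m]
                diff = obs - mu
                scatter = (r[:, None] * diff).T @ diff
                cov = (scatter + psi * np.eye(D)) / (n_sm[s, m] + nu + D + 1)
                if covariance == "diag":
                    cov = np.diag(np.diag(cov))
                means[s, m] = mu
                covars[s, m] = 0.5 * (cov + cov.T)

    return HMMSpec(
        startprob=pi,
        transmat=transmat,
        weights=weights,
        means=means,
        covars=covars,
        loglik_trace=tuple(trace),
        converged=converged,
        n_iter=len(trace),
    )


def viterbi_segment(hmm: HMMSpec, obs: np.ndarray) -> EpochSegmentation:
    """Maximum a posteriori state path; contiguous runs form epochs.

    Ties are broken toward the lower state index, making the segmentation
    deterministic.
    """
    obs = _as_obs(obs, hmm.obs_dim)
    T = obs.shape[0]
    S = hmm.n_states
    logB = hmm.state_log_density(obs)
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.transmat)
        logpi = np.log(hmm.startprob)

    delta = logpi + logB[0]
    psi = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        psi[t] = np.argmax(cand, axis=0)  # argmax -> first (lowest) index on ties
        delta = cand[psi[t], np.arange(S)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]

    epochs = []
    states = []
    start = 0
    for t in range(1, T + 1):
        if t == T or path[t] != path[start]:
            epochs.append((start, t))
            states.append(int(path[start]))
            start = t
    return EpochSegmentation(state_path=path, epochs=tuple(epochs), epoch_states=tuple(states))


def epoch_entropy(
    hmm: HMMSpec,
    segmentation: EpochSegmentation,
    obs: np.ndarray,
    estimator: str = "literal",
    density_floor: float = 1e-300,
) -> np.ndarray:
    """Per-epoch entropies H*(S_i) in bits.

    ``literal``: -sum_z P_i(z) log2 P_i(z) over the epoch's observations,
    with P_i the state's mixture density floored at ``density_floor``.
    ``normalized``: per-sample average negative log2-density.
    """
    obs = _as_obs(obs, hmm.obs_dim)
    if segmentation.epochs and segmentation.epochs[-1][1] != obs.shape[0]:
        raise ValueError("segmentation does not match the observation length")
    logB = hmm.state_log_density(obs)
    out = np.empty(segmentation.n_epochs)
    for i, ((a, b), s) in enumerate(zip(segmentation.epochs, segmentation.epoch_states)):
        if b <= a:
            raise ValueError(f"empty epoch {i}")
        logp = logB[a:b, s]
        p = np.maximum(np.exp(logp), density_floor)
        log2p = np.log(p) / _LOG2
        if estimator == "literal":
            out[i] = float(-np.sum(p * log2p))
        elif estimator == "normalized":
            out[i] = float(-np.mean(log2p))
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    return out


def epen_pair(x: np.ndarray, y: np.ndarray, params: EpEnParams = EpEnParams()) -> EpEnResult:
    """EpEn of a channel pair: stack to 2-D observations, fit, segment, average.

    The construction is symmetric in (x, y) up to the deterministic EM
    initialisation, which is itself symmetric under full covariances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("epen_pair expects two equal-length 1-D channels")
    obs = np.column_stack([x, y])
    return epen_obs(obs, params)


def epen_obs(obs: np.ndarray, params: EpEnParams = EpEnParams()) -> EpEnResult:
    """EpEn of a 1-D or 2-D observation sequence (single channel or pair).

    A left-to-right chain fit to data without real epoch structure can
    collapse a surplus state onto one or two samples (a "sliver" epoch with
    a degenerate covariance); since the epoch mean weights every epoch
    equally, such slivers are treated as overfitting and the model is refit
    with one state fewer until every epoch is substantial.
    """
    obs = _as_obs(obs)
    if params.standardize:
        sd = obs.std(axis=0)
        if np.any(sd == 0):
            raise DegenerateSignalError("zero-variance channel; EpEn undefined")
        obs = (obs - obs.mean(axis=0)) / sd

    n_states = params.n_states
    while True:
        hmm = fit_hmm(
            obs,
            n_states=n_states,
            n_mixtures=params.n_mixtures,
            max_iter=params.max_iter,
            tol=params.tol,
            seed=params.seed,
            covariance=params.covariance,
            sticky=params.sticky,
        )
        seg = viterbi_segment(hmm, obs)
        min_len = max(2.0, params.min_epoch_fraction * obs.shape[0] / n_states)
        if n_states == 1 or all(b - a >= min_len for a, b in seg.epochs):
            break
        n_states -= 1
    ents = epoch_entropy(hmm, seg, obs, estimator=params.estimator,
                         density_floor=params.density_floor)
    return EpEnResult(
        epoch_entropies=ents,
        epen=float(ents.mean()),
        hmm=hmm,
        segmentation=seg,
        diagnostics={
            "converged": hmm.converged,
            "n_iter": hmm.n_iter,
            "final_loglik": hmm.loglik_trace[-1] if hmm.loglik_trace else None,
            "n_epochs": seg.n_epochs,
        },
    )


def epen_matrix(seg, params: EpEnParams = EpEnParams(), tag: str | None = None) -> AdjacencyMatrix:
    """EpEn over all unordered channel pairs of a band-filtered segment.

    Per-pair fits are independent; with a fixed seed the matrix is
    reproducible.  Raw EpEn can be negative for strongly peaked densities;
    adjacency weights are floored at 0 (degenerate pairs, logged in meta).
    """
    data = seg.data
    n = data.shape[0]
    if n < 2:
        raise ValueError("epen_matrix needs at least 2 channels")
    labels = seg.channel_labels
    values = np.zeros((n, n))
    clipped = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = epen_pair(data[i], data[j], params)
            except Exception as e:
                raise RuntimeError(
                    f"EpEn failed on pair ({labels[i]}, {labels[j]}): {e}"
                ) from e
            w = r.epen
            if w < 0:
                clipped.append((labels[i], labels[j], w))
                w = 0.0
            values[i, j] = values[j, i] = w
    meta = {"params": {"n_states": params.n_states, "n_mixtures": params.n_mixtures,
                       "estimator": params.estimator}}
    if clipped:
        meta["clipped_pairs"] = [[a, b, float(w)] for a, b, w in clipped]
    return AdjacencyMatrix(
        values=values,
        measure="EpEn",
        band=seg.band,
        channel_labels=labels,
        tag=tag if tag is not None else seg.subject_id,
        meta=meta,
    )
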