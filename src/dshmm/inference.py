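"""Exact inference on the paired-state HMM.

Implements the scaled forward-backward recursion (posterior pair occupancies
``gamma`` and expected pair-transition counts ``xi``), Viterbi decoding in log
space, and a brute-force path-enumeration oracle used in tests.

The forward-backward pass uses per-position scaling constants rather than
per-cell log arithmetic; emission densities are additionally shifted by their
per-position maximum before exponentiation, so the recursion is stable for
arbitrarily unlikely observations and arbitrarily long sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.special import logsumexp

from .model import (
    DataError,
    GenomicGrid,
    ModelValidationError,
    ObservationSet,
    PairedModel,
)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class PosteriorResult:
    """Posterior quantities from one forward-backward pass.

    ``gamma`` is the T x n_pairs posterior pair-occupancy matrix (rows sum to
    one); ``xi_sum`` the expected pair-transition counts summed over
    positions (its total equals T - 1); ``scale`` the per-position scaling
    constants of the recursion.  ``log_likelihood_backward`` recomputes the
    data log-likelihood from the backward pass as an internal consistency
    check.
    """

    log_likelihood: float
    gamma: np.ndarray
    xi_sum: np.ndarray
    scale: np.ndarray
    log_likelihood_backward: float


@dataclass
class Annotation:
    """Per-bin decoded state pair, with the two derived per-strand paths."""

    pair_path: np.ndarray
    n_states: int
    coords: GenomicGrid
    log_prob: float | None = None

    def __post_init__(self) -> None:
        self.pair_path = np.asarray(self.pair_path, dtype=int)

    @classmethod
    def from_strand_paths(
        cls,
        fwd_path: np.ndarray,
        rev_path: np.ndarray,
        n_states: int,
        coords: GenomicGrid = GenomicGrid(),
        log_prob: float | None = None,
    ) -> "Annotation":
        fwd_path = np.asarray(fwd_path, dtype=int)
        rev_path = np.asarray(rev_path, dtype=int)
        if fwd_path.shape != rev_path.shape:
            raise DataError("forward and reverse paths must have equal length")
        return cls(fwd_path * n_states + rev_path, n_states, coords, log_prob)

    @property
    def fwd_path(self) -> np.ndarray:
        return self.pair_path // self.n_states

    @property
    def rev_path(self) -> np.ndarray:
        return self.pair_path % self.n_states

    @property
    def n_bins(self) -> int:
        return self.pair_path.shape[0]


def pair_log_density(o: np.ndarray, nu: np.ndarray, gamma_cov: np.ndarray) -> float:
    """Multivariate Gaussian log-density of one observation vector.

    Because the pair covariance is block-diagonal under the dominance
    partition, this equals the sum of the two block log-densities; the value
    returned is the full-matrix density.
    """
    o = np.asarray(o, dtype=float)
    nu = np.asarray(nu, dtype=float)
    gamma_cov = np.asarray(gamma_cov, dtype=float)
    if o.shape != nu.shape or gamma_cov.shape != (o.size, o.size):
        raise DataError("observation/mean/covariance dimension mismatch")
    try:
        L = np.linalg.cholesky(gamma_cov)
    except np.linalg.LinAlgError as exc:
        raise ModelValidationError("pair covariance is not positive definite") from exc
    z = sla.solve_triangular(L, o - nu, lower=True)
    return float(
        -0.5 * (o.size * _LOG2PI + z @ z) - np.sum(np.log(np.diag(L)))
    )


def log_emission_matrix(model: PairedModel, values: np.ndarray) -> np.ndarray:
    """T x n_pairs matrix of log emission densities."""
    values = np.asarray(values, dtype=float)
    T = values.shape[0]
    S = model.n_pairs
    out = np.empty((T, S))
    for s in range(S):
        L = np.linalg.cholesky(model.pair_covs[s])
        diff = values - model.pair_means[s]
        z = sla.solve_triangular(L, diff.T, lower=True)
        out[:, s] = (
            -0.5 * (values.shape[1] * _LOG2PI + np.sum(z * z, axis=0))
            - np.sum(np.log(np.diag(L)))
        )
    return out


def _check_obs(model: PairedModel, obs: ObservationSet) -> None:
    if obs.tracks != model.layout.tracks:
        raise DataError(
            "observation tracks do not match the model's track metadata"
        )


def forward_backward(model: PairedModel, obs: ObservationSet) -> PosteriorResult:
    """Scaled forward-backward pass on the paired-state HMM."""
    _check_obs(model, obs)
    logpsi = log_emission_matrix(model, obs.values)
    T, S = logpsi.shape
    B = model.Bmat
    shift = logpsi.max(axis=1)
    psi = np.exp(logpsi - shift[:, None])

    alpha = np.empty((T, S))
    scale = np.empty(T)
    a = model.tau * psi[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ B) * psi[t]
        scale[t] = a.sum()
        if scale[t] <= 0 or not np.isfinite(scale[t]):
            raise ModelValidationError(
                f"forward recursion underflowed at position {t}"
            )
        alpha[t] = a / scale[t]
    log_likelihood = float(np.log(scale).sum() + shift.sum())

    beta = np.empty((T, S))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (B @ (psi[t + 1] * beta[t + 1])) / scale[t + 1]
    ll_backward = float(
        np.log(np.sum(model.tau * psi[0] * beta[0]))
        + np.log(scale[1:]).sum()
        + shift.sum()
    )

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi_sum = np.zeros((S, S))
    for t in range(T - 1):
        xi_sum += (
            alpha[t][:, None] * B * (psi[t + 1] * beta[t + 1])[None, :]
        ) / scale[t + 1]

    return PosteriorResult(
        log_likelihood=log_likelihood,
        gamma=gamma,
        xi_sum=xi_sum,
        scale=scale,
        log_likelihood_backward=ll_backward,
    )


def viterbi(model: PairedModel, obs: ObservationSet) -> Annotation:
    """Most probable pair path (ties broken toward the lower pair index)."""
    _check_obs(model, obs)
    logpsi = log_emission_matrix(model, obs.values)
    T, S = logpsi.shape
    with np.errstate(divide="ignore"):
        logB = np.log(model.Bmat)
        logtau = np.log(model.tau)
    delta = logtau + logpsi[0]
    back = np.empty((T, S), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logB
        back[t] = np.argmax(cand, axis=0)  # first max -> lowest pair index
        delta = cand[back[t], np.arange(S)] + logpsi[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta))
    score = float(delta[path[T - 1]])
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return Annotation(path, model.n_states, obs.coords, log_prob=score)


def brute_force(
    model: PairedModel, obs: ObservationSet, mode: str = "likelihood"
):
    """Exact enumeration over all pair paths (test oracle).

    ``mode="likelihood"`` returns the total log-likelihood; ``mode="map"``
    returns the maximum-probability :class:`Annotation`.  Refuses instances
    with more than 10^6 pair paths.
    """
    _check_obs(model, obs)
    if mode not in ("likelihood", "map"):
        raise ValueError(f"unknown mode {mode!r}")
    T = obs.n_bins
    S = model.n_pairs
    if S**T > 10**6:
        raise ValueError(
            f"brute force refused: {S}^{T} pair paths exceed the 10^6 cap"
        )
    logpsi = log_emission_matrix(model, obs.values)
    with np.errstate(divide="ignore"):
        logB = np.log(model.Bmat)
        logtau = np.log(model.tau)
    best_path, best_score = None, -np.inf
    scores = []
    for path in itertools.product(range(S), repeat=T):
        lp = logtau[path[0]] + logpsi[0, path[0]]
        for t in range(1, T):
            lp += logB[path[t - 1], path[t]] + logpsi[t, path[t]]
        scores.append(lp)
        if lp > best_score:  # strict: ties keep the lexicographically first
            best_score, best_path = lp, path
    if mode == "likelihood":
        return float(logsumexp(scores))
    return Annotation(
        np.array(best_path), model.n_states, obs.coords, log_prob=float(best_score)
    )
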