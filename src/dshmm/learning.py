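"""Parameter estimation for the dsHMM.

Training follows a generalized EM scheme on the paired-state representation:

* **Initialization** — genomic bins are split into transcriptionally active
  and inactive sets by thresholding forward-strand expression; k-means on the
  forward-oriented single-strand coordinates yields the requested number of
  transcribed-state centers (active set) and intergenic-state centers
  (inactive set).  Covariances are the empirical covariances of each cluster
  and stay fixed throughout EM; ``A`` starts uniform (hence ``pi`` uniform).

* **E-step** — scaled forward-backward on the assembled paired model.

* **M-step** — ``A`` is re-estimated from *tied* expected counts: every
  expected pair transition ``r -> s`` contributes to ``a[i, j]`` once through
  the forward chain (``r+ = i, s+ = j``) and once through the reverse chain
  (``s- = i, r- = j``, the reverse chain reads right-to-left).  ``pi`` is then
  re-derived as the stationary law of the new ``A``.  Each single-strand mean
  entry ``mu^i_p`` becomes the posterior-weighted average of the observations
  on track ``p`` over all positions and pairs in which state ``i`` is the
  *determiner* of ``p`` under the current dominance partition; partitions are
  recomputed from the new means afterwards.  Covariances are not updated.

Because the dominance partition may flip between iterations, the
log-likelihood is monitored; on any decrease the update is damped by halving
back toward the previous parameters, and the event is logged in the trace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.cluster import KMeans

from .inference import forward_backward
from .model import (
    CoreModel,
    DataError,
    ModelValidationError,
    ObservationSet,
    PairedModel,
    StrandStateEmission,
    assemble_paired_model,
)

logger = logging.getLogger("dshmm")

CONFIG_SCHEMA_VERSION = 1


@dataclass
class FitConfig:
    """Training configuration.

    ``activity_threshold`` (absolute, on expression values) overrides
    ``activity_quantile`` (a quantile of the pooled strand-specific values)
    for the initial active/inactive split.  ``transcribed_mean_threshold`` is
    the expression-mean cutoff used when (re)labelling states as transcribed.
    """

    n_transcribed: int = 15
    n_intergenic: int = 5
    activity_quantile: float = 0.6
    activity_threshold: float | None = None
    transcribed_mean_threshold: float = 0.2
    tol: float = 1e-6
    max_iter: int = 100
    seed: int = 0
    kmeans_restarts: int = 10
    covariance_floor: float = 1e-6
    jitter: float = 1e-8
    max_damping_halvings: int = 10

    def __post_init__(self) -> None:
        if self.n_transcribed < 1 or self.n_intergenic < 1:
            raise DataError("need at least one transcribed and one intergenic state")
        if not self.tol > 0:
            raise DataError("tol must be positive")
        if self.max_iter < 1:
            raise DataError("max_iter must be >= 1")

    @property
    def n_states(self) -> int:
        return self.n_transcribed + self.n_intergenic

    @classmethod
    def from_yaml(cls, path) -> "FitConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc.get("schema_version", CONFIG_SCHEMA_VERSION) != CONFIG_SCHEMA_VERSION:
            raise DataError(
                f"unsupported config schema version {doc.get('schema_version')!r}"
            )
        doc.pop("schema_version", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = {"schema_version": CONFIG_SCHEMA_VERSION}
        doc.update({k: getattr(self, k) for k in self.__dataclass_fields__})
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class FitTrace:
    """Per-iteration record of an EM run."""

    log_likelihood: list[float] = field(default_factory=list)
    delta_A: list[float] = field(default_factory=list)
    delta_mean: list[float] = field(default_factory=list)
    damping_events: list[tuple[int, int]] = field(default_factory=list)
    converged: bool = False
    reason: str = "running"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration\tlog_likelihood\tdelta_A\tdelta_mean\tdamped\n")
            damped = dict(self.damping_events)
            for i, ll in enumerate(self.log_likelihood):
                fh.write(
                    f"{i}\t{ll!r}\t{self.delta_A[i]!r}\t{self.delta_mean[i]!r}\t"
                    f"{damped.get(i, 0)}\n"
                )
            fh.write(f"# converged={self.converged} reason={self.reason}\n")


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _floored_cov(x: np.ndarray, var_floor: np.ndarray) -> np.ndarray:
    if x.shape[0] < 2:
        cov = np.zeros((x.shape[1], x.shape[1]))
    else:
        cov = np.cov(x, rowvar=False)
        cov = np.atleast_2d(cov)
    d = np.diag(cov).copy()
    np.fill_diagonal(cov, np.maximum(d, var_floor))
    return cov


def kmeans_initialize(obs: ObservationSet, cfg: FitConfig) -> CoreModel:
    """Initial model from an active/inactive split plus k-means clustering."""
    lay = obs.layout
    if not lay.forward_cols:
        raise DataError(
            "initialization requires at least one strand-specific expression pair"
        )
    X = obs.forward_view()
    fwd_expr = obs.values[:, list(lay.forward_cols)].mean(axis=1)
    if cfg.activity_threshold is not None:
        threshold = float(cfg.activity_threshold)
    else:
        pooled = obs.values[:, list(lay.forward_cols + lay.reverse_cols)].ravel()
        threshold = float(np.quantile(pooled, cfg.activity_quantile))
    active = fwd_expr > threshold
    n_active = int(active.sum())
    if n_active < cfg.n_transcribed or (obs.n_bins - n_active) < cfg.n_intergenic:
        raise DataError(
            f"active/inactive split at threshold {threshold:.4g} leaves "
            f"{n_active} active and {obs.n_bins - n_active} inactive bins; "
            "adjust activity_threshold/activity_quantile"
        )

    var_floor = cfg.covariance_floor * np.maximum(X.var(axis=0), 1e-12)
    emissions: list[StrandStateEmission] = []
    states: list[str] = []
    for name, subset, k, transcribed, seed in (
        ("T", X[active], cfg.n_transcribed, True, cfg.seed),
        ("I", X[~active], cfg.n_intergenic, False, cfg.seed + 1),
    ):
        km = KMeans(n_clusters=k, n_init=cfg.kmeans_restarts, random_state=seed)
        labels = km.fit_predict(subset)
        for c in range(k):
            members = subset[labels == c]
            cov = _floored_cov(members, var_floor)
            emissions.append(
                StrandStateEmission(km.cluster_centers_[c], cov, transcribed)
            )
            states.append(f"{name}{c + 1}")
    n = cfg.n_states
    A = np.full((n, n), 1.0 / n)
    return CoreModel(tuple(states), A, tuple(emissions))


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _m_step(
    model: CoreModel,
    paired: PairedModel,
    gamma: np.ndarray,
    xi_sum: np.ndarray,
    values: np.ndarray,
) -> CoreModel:
    n = model.n_states
    lay = paired.layout

    # tied transition counts: forward chain + reverse chain contributions
    xi4 = xi_sum.reshape(n, n, n, n)  # [r+, r-, s+, s-]
    # forward chain: a[i,j] count from pairs with r+=i, s+=j;
    # reverse chain reads right-to-left: count from pairs with s-=i, r-=j
    counts = xi4.sum(axis=(1, 3)) + xi4.sum(axis=(0, 2)).T
    row = counts.sum(axis=1, keepdims=True)
    A_new = model.A.copy()
    ok = row[:, 0] > 0
    A_new[ok] = counts[ok] / row[ok]
    if not np.all(ok):
        logger.warning(
            "states %s received zero expected transitions; rows kept",
            [model.states[i] for i in np.where(~ok)[0]],
        )

    # dominance-aware tied mean update
    K = lay.n_base
    acc = np.zeros((n, K))
    wgt = np.zeros((n, K))
    col_sums = gamma.T @ values  # (n_pairs, P)
    occ = gamma.sum(axis=0)  # (n_pairs,)
    base_index = np.asarray(lay.base_index)
    for s in range(paired.n_pairs):
        i, j = paired.pair_of(s)
        for p in range(lay.n_tracks):
            det = i if paired.dominance[s, p] else j
            c = base_index[p]
            acc[det, c] += col_sums[s, p]
            wgt[det, c] += occ[s]
    means_new = np.stack([e.mean for e in model.emissions]).copy()
    has_weight = wgt > 0
    means_new[has_weight] = acc[has_weight] / wgt[has_weight]
    if not np.all(has_weight):
        for i, c in zip(*np.where(~has_weight)):
            logger.warning(
                "mean entry (state %s, coordinate %s) had zero determiner "
                "weight; previous value kept",
                model.states[i], lay.base_names[c],
            )

    emissions = tuple(
        StrandStateEmission(means_new[i], model.emissions[i].covariance,
                            model.emissions[i].transcribed)
        for i in range(n)
    )
    return CoreModel(model.states, A_new, emissions)


def em_step(
    model: CoreModel,
    obs: ObservationSet,
    jitter: float = 1e-8,
) -> tuple[CoreModel, float]:
    """One EM iteration; returns the updated model and the log-likelihood of
    the *input* model."""
    paired = assemble_paired_model(model, obs.tracks, jitter=jitter)
    post = forward_backward(paired, obs)
    if not math.isfinite(post.log_likelihood):
        raise ModelValidationError("non-finite log-likelihood in E-step")
    new = _m_step(model, paired, post.gamma, post.xi_sum, obs.values)
    return new, post.log_likelihood


def _blend(prev: CoreModel, cur: CoreModel, w: float) -> CoreModel:
    """Convex combination ``(1 - w) * prev + w * cur`` of A and means."""
    A = (1 - w) * prev.A + w * cur.A
    emissions = tuple(
        StrandStateEmission(
            (1 - w) * ep.mean + w * ec.mean, ep.covariance, ep.transcribed
        )
        for ep, ec in zip(prev.emissions, cur.emissions)
    )
    return CoreModel(prev.states, A, emissions)


def _loglik(model: CoreModel, obs: ObservationSet, jitter: float) -> float:
    paired = assemble_paired_model(model, obs.tracks, jitter=jitter)
    return forward_backward(paired, obs).log_likelihood


def fit(
    obs: ObservationSet,
    cfg: FitConfig,
    init: CoreModel | None = None,
) -> tuple[CoreModel, FitTrace]:
    """Train a dsHMM by generalized EM from a k-means initialization.

    Stops when the relative log-likelihood change drops below ``cfg.tol`` or
    after ``cfg.max_iter`` parameter updates.  Fully deterministic given
    ``cfg.seed``.  Non-convergence is reported in the trace, not raised.
    """
    model = kmeans_initialize(obs, cfg) if init is None else init
    trace = FitTrace()
    prev_model: CoreModel | None = None
    prev_ll: float | None = None
    n_updates = 0
    iteration = 0
    while True:
        ll = _loglik(model, obs, cfg.jitter)
        if prev_ll is not None and ll < prev_ll - 1e-9 * max(1.0, abs(prev_ll)):
            accepted = False
            for k in range(1, cfg.max_damping_halvings + 1):
                cand = _blend(prev_model, model, 0.5**k)
                ll_c = _loglik(cand, obs, cfg.jitter)
                if ll_c >= prev_ll - 1e-9 * max(1.0, abs(prev_ll)):
                    model, ll = cand, ll_c
                    trace.damping_events.append((iteration, k))
                    logger.info(
                        "iteration %d: likelihood decrease damped after %d "
                        "halvings", iteration, k,
                    )
                    accepted = True
                    break
            if not accepted:
                model, ll = prev_model, prev_ll
                trace.converged = False
                trace.reason = "damping_exhausted"
                break
        trace.log_likelihood.append(ll)
        if prev_model is not None:
            trace.delta_A.append(float(np.abs(model.A - prev_model.A).max()))
            trace.delta_mean.append(
                float(
                    max(
                        np.abs(ec.mean - ep.mean).max()
                        for ec, ep in zip(model.emissions, prev_model.emissions)
                    )
                )
            )
        else:
            trace.delta_A.append(0.0)
            trace.delta_mean.append(0.0)
        if prev_ll is not None:
            rel = abs(ll - prev_ll) / max(abs(prev_ll), 1e-12)
            if rel < cfg.tol:
                trace.converged = True
                trace.reason = "tol"
                break
        if n_updates >= cfg.max_iter:
            trace.converged = False
            trace.reason = "max_iter"
            break
        paired = assemble_paired_model(model, obs.tracks, jitter=cfg.jitter)
        post = forward_backward(paired, obs)
        proposed = _m_step(model, paired, post.gamma, post.xi_sum, obs.values)
        prev_model, prev_ll = model, ll
        model = proposed
        n_updates += 1
        iteration += 1
    return model, trace


def relabel_transcribed(
    model: CoreModel, obs: ObservationSet, threshold: float = 0.2
) -> CoreModel:
    """Re-flag states as transcribed by their expression-mean coordinate(s).

    A state is transcribed when its mean over the shared ``E`` coordinates is
    >= ``threshold`` (default 0.2, the conventional low-expression cutoff).
    """
    lay = obs.layout
    e_coords = sorted({lay.base_index[p] for p in lay.forward_cols})
    if not e_coords:
        raise DataError("no strand-specific expression pair in the track set")
    emissions = tuple(
        StrandStateEmission(
            e.mean, e.covariance, bool(e.mean[e_coords].mean() >= threshold)
        )
        for e in model.emissions
    )
    return CoreModel(model.states, model.A, emissions)
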