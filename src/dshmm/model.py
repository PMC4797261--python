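"""Core dsHMM parameter objects and the paired-state HMM construction.

A double-stranded HMM (dsHMM) consists of two tied Markov chains over one
strand-generic state set ``D``, running 5'->3' on opposite DNA strands.  The
forward chain moves left-to-right with transition matrix ``A``; the reverse
chain moves right-to-left with the same ``A`` (a transition on the reverse
strand in its own reading direction has the same probability as the
corresponding forward-strand transition).  ``pi`` is required to be the unique
stationary distribution of an ergodic ``A`` and serves as the initial
distribution of both chains (at position 1 for the forward chain, at position
T for the reverse chain).

Each position emits one observation vector over a set of measurement tracks
``P = B u E+ u E-``: undirected tracks ``B`` (ChIP-style occupancy,
nucleosomes) and strand-specific track pairs (``E+``/``E-``, e.g.
forward/reverse expression) which are two copies of a shared coordinate set
``E``.  Every strand-generic state ``i`` carries a single-strand Gaussian with
mean ``mu^i`` and covariance ``Sigma^i`` over ``B u E``.

The dsHMM is equivalent to a standard HMM over state *pairs*
``s = (s+, s-)``:

* pair transition matrix ``Bmat[r, s] = A[r+, s+] * A[s-, r-] * pi[s-]/pi[r-]``
* initial pair distribution ``tau[s] = pi[s+] * pi[s-]``
* pair emission built from a *dominance partition* of the tracks: each track
  is assigned to the strand whose state determines its signal.  Strand
  specific tracks always belong to their own strand; an undirected track goes
  to the forward member iff its forward mean is >= the reverse mean (ties to
  forward), except for tracks flagged ``transcribed_dominates`` (nucleosome
  occupancy), where a transcribed state overrides an intergenic one so that
  nucleosome depletion in transcribed regions is not masked.  The pair mean
  copies each state's mean on the tracks it dominates, and the pair covariance
  tiles the two single-strand covariances block-wise with exact zeros between
  the blocks.

This sparse construction gives the paired model exactly the free-parameter
count of a standard ``|D|``-state Gaussian HMM on the single-strand space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

UNDIRECTED = "undirected"
FORWARD_SPECIFIC = "forward_specific"
REVERSE_SPECIFIC = "reverse_specific"
STRAND_CLASSES = (UNDIRECTED, FORWARD_SPECIFIC, REVERSE_SPECIFIC)

MEAN_DOMINANCE = "mean_dominance"
TRANSCRIBED_DOMINATES = "transcribed_dominates"
DOMINANCE_RULES = (MEAN_DOMINANCE, TRANSCRIBED_DOMINATES)

SCHEMA_VERSION = 1

#: tolerance below which a transition-matrix entry counts as structurally zero
ERGODICITY_EPS = 1e-12


class ModelValidationError(ValueError):
    """A model object violates one of its structural invariants."""


class DataError(ValueError):
    """An observation/track input is malformed or inconsistent."""


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackMeta:
    """Metadata for one measurement track.

    Parameters
    ----------
    name
        Unique track name.
    strand_class
        ``"undirected"`` for strand-unspecific signals, or
        ``"forward_specific"``/``"reverse_specific"`` for one member of a
        strand-specific pair.
    partner
        Name of the opposite-strand member for strand-specific tracks.
    dominance_rule
        ``"mean_dominance"`` (default) or ``"transcribed_dominates"`` (the
        nucleosome-occupancy override; only valid on undirected tracks).
    """

    name: str
    strand_class: str
    partner: str | None = None
    dominance_rule: str = MEAN_DOMINANCE

    def __post_init__(self) -> None:
        if self.strand_class not in STRAND_CLASSES:
            raise DataError(
                f"track {self.name!r}: unknown strand_class {self.strand_class!r}"
            )
        if self.dominance_rule not in DOMINANCE_RULES:
            raise DataError(
                f"track {self.name!r}: unknown dominance_rule {self.dominance_rule!r}"
            )
        if self.strand_class == UNDIRECTED:
            if self.partner is not None:
                raise DataError(f"undirected track {self.name!r} cannot have a partner")
        else:
            if self.partner is None:
                raise DataError(
                    f"strand-specific track {self.name!r} requires a partner track"
                )
            if self.dominance_rule != MEAN_DOMINANCE:
                raise DataError(
                    f"track {self.name!r}: {TRANSCRIBED_DOMINATES!r} is only "
                    "permitted on undirected tracks"
                )


@dataclass(frozen=True)
class TrackLayout:
    """Derived index structure mapping tracks ``P`` onto coordinates ``B u E``.

    ``base_index[p]`` gives, for each track column ``p``, its coordinate in the
    single-strand space: undirected tracks get their own coordinate, and the
    two members of a strand-specific pair share one ``E`` coordinate (labelled
    by the forward member's name).
    """

    tracks: tuple[TrackMeta, ...]
    base_index: tuple[int, ...]
    base_names: tuple[str, ...]
    undirected_cols: tuple[int, ...]
    forward_cols: tuple[int, ...]
    reverse_cols: tuple[int, ...]
    partner_col: dict[int, int] = field(hash=False)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    @property
    def n_base(self) -> int:
        """Dimension of the single-strand space ``|B| + |E|``."""
        return len(self.base_names)

    def column(self, name: str) -> int:
        for p, t in enumerate(self.tracks):
            if t.name == name:
                return p
        raise DataError(f"unknown track name {name!r}")


def track_layout(tracks: Sequence[TrackMeta]) -> TrackLayout:
    """Validate a track list and derive its :class:`TrackLayout`.

    Checks that names are unique and that the partner relation is a bijection
    between forward- and reverse-specific tracks.
    """
    tracks = tuple(tracks)
    names = [t.name for t in tracks]
    if len(set(names)) != len(names):
        raise DataError("track names must be unique")
    by_name = {t.name: t for t in tracks}
    for t in tracks:
        if t.strand_class == UNDIRECTED:
            continue
        partner = by_name.get(t.partner)
        if partner is None:
            raise DataError(f"track {t.name!r}: partner {t.partner!r} not present")
        want = (
            REVERSE_SPECIFIC if t.strand_class == FORWARD_SPECIFIC else FORWARD_SPECIFIC
        )
        if partner.strand_class != want:
            raise DataError(
                f"track {t.name!r}: partner {t.partner!r} must be {want}"
            )
        if partner.partner != t.name:
            raise DataError(
                f"partner relation not symmetric between {t.name!r} and {t.partner!r}"
            )

    base_index: list[int] = []
    base_names: list[str] = []
    base_of_pair: dict[str, int] = {}
    undirected_cols, forward_cols, reverse_cols = [], [], []
    partner_col: dict[int, int] = {}
    for p, t in enumerate(tracks):
        if t.strand_class == UNDIRECTED:
            undirected_cols.append(p)
            base_index.append(len(base_names))
            base_names.append(t.name)
        else:
            (forward_cols if t.strand_class == FORWARD_SPECIFIC else reverse_cols).append(p)
            # shared E coordinate, keyed by the sorted pair of names
            key = "|".join(sorted((t.name, t.partner)))
            if key not in base_of_pair:
                base_of_pair[key] = len(base_names)
                fwd_name = t.name if t.strand_class == FORWARD_SPECIFIC else t.partner
                base_names.append(fwd_name)
            base_index.append(base_of_pair[key])
    for pf in forward_cols:
        pr = names.index(tracks[pf].partner)
        partner_col[pf] = pr
        partner_col[pr] = pf
    return TrackLayout(
        tracks=tracks,
        base_index=tuple(base_index),
        base_names=tuple(base_names),
        undirected_cols=tuple(undirected_cols),
        forward_cols=tuple(forward_cols),
        reverse_cols=tuple(reverse_cols),
        partner_col=partner_col,
    )


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicGrid:
    """Fixed binning of one contig: 0-based half-open bins of equal width."""

    contig: str = "chr"
    start: int = 0
    bin_width: int = 1


@dataclass
class ObservationSet:
    """T x P matrix of binned track values plus track metadata and coordinates."""

    values: np.ndarray
    tracks: tuple[TrackMeta, ...]
    coords: GenomicGrid = field(default_factory=GenomicGrid)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.tracks = tuple(self.tracks)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D (bins x tracks) matrix")
        if self.values.shape[0] < 1:
            raise DataError("need at least one genomic bin")
        if self.values.shape[1] != len(self.tracks):
            raise DataError(
                f"{self.values.shape[1]} value columns but {len(self.tracks)} tracks"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError(
                "observations contain non-finite values; masking/imputation "
                "must be resolved upstream"
            )
        self._layout = track_layout(self.tracks)

    @property
    def layout(self) -> TrackLayout:
        return self._layout

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def forward_view(self) -> np.ndarray:
        """Project onto single-strand coordinates, forward orientation.

        Undirected columns map to their ``B`` coordinate; each pair's ``E``
        coordinate takes the forward-specific column.
        """
        lay = self._layout
        out = np.empty((self.n_bins, lay.n_base))
        for p in lay.undirected_cols + lay.forward_cols:
            out[:, lay.base_index[p]] = self.values[:, p]
        return out

    def reversed_swapped(self) -> "ObservationSet":
        """Reverse bin order and swap each strand-specific pair's values.

        The dsHMM likelihood is invariant under this transformation
        (reversibility of the model).
        """
        vals = self.values[::-1].copy()
        for pf in self._layout.forward_cols:
            pr = self._layout.partner_col[pf]
            vals[:, [pf, pr]] = vals[:, [pr, pf]]
        return ObservationSet(vals, self.tracks, self.coords)


# ---------------------------------------------------------------------------
# state emissions and the core model
# ---------------------------------------------------------------------------


@dataclass
class StrandStateEmission:
    """Single-strand Gaussian of one strand-generic state, on ``B u E``."""

    mean: np.ndarray
    covariance: np.ndarray
    transcribed: bool = False

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        k = self.mean.shape[0]
        if self.mean.ndim != 1 or self.covariance.shape != (k, k):
            raise ModelValidationError("mean/covariance dimensions inconsistent")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ModelValidationError("covariance must be symmetric")
        w = np.linalg.eigvalsh(self.covariance)
        if w.min() < -1e-8 * max(1.0, abs(w.max())):
            raise ModelValidationError("covariance must be positive semidefinite")


def derive_stationary(A: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Return the unique stationary distribution of an ergodic stochastic ``A``.

    Solves ``pi A = pi`` with ``sum(pi) = 1`` by a linear solve.  Raises
    :class:`ModelValidationError` if ``A`` is not square, not row-stochastic,
    or not ergodic (the support digraph must be strongly connected and
    aperiodic).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ModelValidationError("A must be a square matrix")
    n = A.shape[0]
    rowsums = A.sum(axis=1)
    bad = np.where(np.abs(rowsums - 1.0) > tol)[0]
    if bad.size:
        raise ModelValidationError(
            f"A is not row-stochastic: rows {bad.tolist()} sum to "
            f"{rowsums[bad].tolist()}"
        )
    if A.min() < -ERGODICITY_EPS:
        i, j = np.unravel_index(np.argmin(A), A.shape)
        raise ModelValidationError(f"A has a negative entry at ({i},{j})")

    support = (A > ERGODICITY_EPS).astype(np.int8)
    n_comp, labels = connected_components(
        csr_matrix(support), directed=True, connection="strong"
    )
    if n_comp > 1:
        classes = [np.where(labels == c)[0].tolist() for c in range(n_comp)]
        raise ModelValidationError(
            f"A is not ergodic: support digraph has {n_comp} strongly "
            f"connected classes {classes}"
        )
    g = nx.DiGraph(zip(*np.nonzero(support)))
    if not nx.is_aperiodic(g):
        raise ModelValidationError("A is not ergodic: support digraph is periodic")

    M = (A.T - np.eye(n)).copy()
    M[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(M, b)
    except np.linalg.LinAlgError:
        pi, *_ = np.linalg.lstsq(np.vstack([A.T - np.eye(n), np.ones(n)]),
                                 np.append(np.zeros(n), 1.0), rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    if not np.allclose(pi @ A, pi, atol=10 * tol):
        raise ModelValidationError("failed to derive a stationary distribution")
    if pi.min() <= 0:
        raise ModelValidationError("stationary distribution has a zero entry")
    return pi


@dataclass
class CoreModel:
    """The strand-generic dsHMM: states, tied transition matrix, emissions.

    ``pi`` is always the stationary distribution derived from ``A`` — it is
    never a free parameter and is recomputed whenever ``A`` changes.
    """

    states: tuple[str, ...]
    A: np.ndarray
    emissions: tuple[StrandStateEmission, ...]
    pi: np.ndarray = None  # derived in __post_init__ if not given

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.A = np.asarray(self.A, dtype=float)
        self.emissions = tuple(self.emissions)
        n = len(self.states)
        if self.A.shape != (n, n):
            raise ModelValidationError("A shape must match the number of states")
        if len(self.emissions) != n:
            raise ModelValidationError("need one emission per state")
        k = self.emissions[0].mean.shape[0]
        for e in self.emissions:
            if e.mean.shape[0] != k:
                raise ModelValidationError("emission dimensions differ across states")
        derived = derive_stationary(self.A)
        if self.pi is None:
            self.pi = derived
        else:
            self.pi = np.asarray(self.pi, dtype=float)
            if not np.allclose(self.pi, derived, atol=1e-6):
                raise ModelValidationError(
                    "pi is not the stationary distribution of A"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def transcribed(self) -> np.ndarray:
        return np.array([e.transcribed for e in self.emissions], dtype=bool)

    def means_matrix(self) -> np.ndarray:
        return np.stack([e.mean for e in self.emissions])


def n_free_parameters(model: CoreModel) -> int:
    """Free-parameter count of a dsHMM.

    ``A`` contributes ``n (n - 1)`` (rows are normalized; ``pi`` is derived),
    each state a length-``K`` mean and a symmetric ``K x K`` covariance.  By
    construction this equals :func:`standard_hmm_n_parameters` for a standard
    ``n``-state Gaussian HMM on the ``K``-dimensional single-strand space.
    """
    n = model.n_states
    k = model.emissions[0].mean.shape[0]
    return n * (n - 1) + n * k + n * (k * (k + 1)) // 2


def standard_hmm_n_parameters(n_states: int, n_dims: int) -> int:
    """Free parameters of a standard Gaussian HMM with derived initial law."""
    return (
        n_states * (n_states - 1)
        + n_states * n_dims
        + n_states * (n_dims * (n_dims + 1)) // 2
    )


# ---------------------------------------------------------------------------
# dominance sets and pair emissions
# ---------------------------------------------------------------------------


def compute_dominance_sets(
    mean_fwd: np.ndarray,
    mean_rev: np.ndarray,
    tracks: Sequence[TrackMeta] | TrackLayout,
    transcribed_fwd: bool,
    transcribed_rev: bool,
) -> np.ndarray:
    """Partition the track set between the two members of a state pair.

    Returns a boolean mask over tracks: ``True`` where the forward member
    dominates (track in ``P_s+``), ``False`` for ``P_s-``.  Forward-specific
    tracks are always forward-dominated and reverse-specific tracks
    reverse-dominated.  Undirected tracks under ``mean_dominance`` go to the
    forward member iff its mean is >= the reverse mean (ties to forward).
    Tracks flagged ``transcribed_dominates`` are assigned to the transcribed
    member when exactly one member is transcribed; otherwise mean dominance
    applies.
    """
    lay = tracks if isinstance(tracks, TrackLayout) else track_layout(tracks)
    mean_fwd = np.asarray(mean_fwd, dtype=float)
    mean_rev = np.asarray(mean_rev, dtype=float)
    if mean_fwd.shape != (lay.n_base,) or mean_rev.shape != (lay.n_base,):
        raise ModelValidationError(
            f"mean vectors must have length {lay.n_base} (= |B| + |E|)"
        )
    mask = np.zeros(lay.n_tracks, dtype=bool)
    for p, t in enumerate(lay.tracks):
        if t.strand_class == FORWARD_SPECIFIC:
            mask[p] = True
        elif t.strand_class == REVERSE_SPECIFIC:
            mask[p] = False
        else:
            c = lay.base_index[p]
            if (
                t.dominance_rule == TRANSCRIBED_DOMINATES
                and transcribed_fwd != transcribed_rev
            ):
                mask[p] = transcribed_fwd
            else:
                mask[p] = mean_fwd[c] >= mean_rev[c]
    return mask


def build_pair_emission(
    emission_fwd: StrandStateEmission,
    emission_rev: StrandStateEmission,
    dominance: np.ndarray,
    layout: TrackLayout,
    jitter: float = 1e-8,
    pair_label: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """Pair mean ``nu`` and block covariance ``Gamma`` over the full track set.

    ``nu`` copies the forward member's mean on forward-dominated tracks and
    the reverse member's mean elsewhere (strand-specific tracks read their
    pair's shared ``E`` coordinate).  ``Gamma`` tiles the forward covariance
    on the forward block, the reverse covariance on the reverse block and is
    exactly zero between blocks.  ``jitter`` (a fraction of the mean diagonal)
    is added to the diagonal so ``Gamma`` is strictly positive definite.
    """
    dominance = np.asarray(dominance, dtype=bool)
    if dominance.shape != (layout.n_tracks,):
        raise ModelValidationError("dominance mask length must equal track count")
    bi = np.asarray(layout.base_index)
    nu = np.where(
        dominance, emission_fwd.mean[bi], emission_rev.mean[bi]
    )
    cov_f = emission_fwd.covariance[np.ix_(bi, bi)]
    cov_r = emission_rev.covariance[np.ix_(bi, bi)]
    both_fwd = np.outer(dominance, dominance)
    both_rev = np.outer(~dominance, ~dominance)
    gamma = np.where(both_fwd, cov_f, np.where(both_rev, cov_r, 0.0))
    if jitter > 0:
        scale = np.mean(np.diag(gamma))
        gamma = gamma + jitter * max(scale, np.finfo(float).tiny) * np.eye(
            layout.n_tracks
        )
    try:
        np.linalg.cholesky(gamma)
    except np.linalg.LinAlgError as exc:
        raise ModelValidationError(
            f"pair covariance not positive definite after jitter"
            f"{' for pair ' + pair_label if pair_label else ''}"
        ) from exc
    return nu, gamma


def build_pair_transition(
    A: np.ndarray, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrix and initial law of the paired-state HMM.

    ``Bmat[(r+, r-), (s+, s-)] = A[r+, s+] * A[s-, r-] * pi[s-] / pi[r-]`` and
    ``tau[(s+, s-)] = pi[s+] * pi[s-]``.  Pairs are indexed row-major with the
    forward state outer: pair ``(i, j)`` has index ``i * n + j``.  Requires
    every ``pi`` entry strictly positive and ``pi`` stationary for ``A``.
    """
    A = np.asarray(A, dtype=float)
    pi = np.asarray(pi, dtype=float)
    n = A.shape[0]
    if pi.min() <= 0:
        raise ModelValidationError(
            "pair transition undefined: pi has a zero entry (division by zero)"
        )
    if not np.allclose(pi @ A, pi, atol=1e-8):
        raise ModelValidationError("pi must be stationary for A")
    # indices [r+, r-, s+, s-]
    b4 = np.einsum("ij,lk,l->ikjl", A, A, pi) / pi[None, :, None, None]
    bmat = b4.reshape(n * n, n * n)
    tau = np.outer(pi, pi).ravel()
    return bmat, tau


@dataclass
class PairedModel:
    """Standard HMM over state pairs, derived from a :class:`CoreModel`."""

    core: CoreModel
    layout: TrackLayout
    Bmat: np.ndarray
    tau: np.ndarray
    pair_means: np.ndarray  # (n^2, P)
    pair_covs: np.ndarray  # (n^2, P, P)
    dominance: np.ndarray  # (n^2, P) bool, True = forward-dominated

    @property
    def n_states(self) -> int:
        return self.core.n_states

    @property
    def n_pairs(self) -> int:
        return self.Bmat.shape[0]

    def pair_index(self, fwd: int, rev: int) -> int:
        return fwd * self.n_states + rev

    def pair_of(self, index: int) -> tuple[int, int]:
        return divmod(index, self.n_states)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        n = self.n_states
        return [(i, j) for i in range(n) for j in range(n)]


def assemble_paired_model(
    core: CoreModel,
    tracks: Sequence[TrackMeta] | TrackLayout,
    jitter: float = 1e-8,
) -> PairedModel:
    """Derive the full paired-state HMM from a core model and track metadata."""
    lay = tracks if isinstance(tracks, TrackLayout) else track_layout(tracks)
    if core.emissions[0].mean.shape[0] != lay.n_base:
        raise ModelValidationError(
            f"emission dimension {core.emissions[0].mean.shape[0]} does not "
            f"match the single-strand track space of size {lay.n_base}"
        )
    n, P = core.n_states, lay.n_tracks
    bmat, tau = build_pair_transition(core.A, core.pi)
    means = np.empty((n * n, P))
    covs = np.empty((n * n, P, P))
    dom = np.empty((n * n, P), dtype=bool)
    for i in range(n):
        for j in range(n):
            s = i * n + j
            ef, er = core.emissions[i], core.emissions[j]
            mask = compute_dominance_sets(
                ef.mean, er.mean, lay, ef.transcribed, er.transcribed
            )
            nu, gamma = build_pair_emission(
                ef, er, mask, lay, jitter=jitter,
                pair_label=f"({core.states[i]},{core.states[j]})",
            )
            means[s], covs[s], dom[s] = nu, gamma, mask
    return PairedModel(
        core=core, layout=lay, Bmat=bmat, tau=tau,
        pair_means=means, pair_covs=covs, dominance=dom,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def model_to_dict(core: CoreModel, tracks: Sequence[TrackMeta]) -> dict:
    tracks = tuple(tracks)
    return {
        "schema_version": SCHEMA_VERSION,
        "states": list(core.states),
        "transcribed": [bool(e.transcribed) for e in core.emissions],
        "A": core.A.tolist(),
        "pi": core.pi.tolist(),  # redundant (derived); kept as a checksum
        "means": [e.mean.tolist() for e in core.emissions],
        "covariances": [e.covariance.tolist() for e in core.emissions],
        "tracks": [
            {
                "name": t.name,
                "strand_class": t.strand_class,
                "partner": t.partner,
                "dominance_rule": t.dominance_rule,
            }
            for t in tracks
        ],
    }


def model_from_dict(doc: dict) -> tuple[CoreModel, tuple[TrackMeta, ...]]:
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise DataError(
            f"unsupported model schema version {doc.get('schema_version')!r}"
        )
    emissions = tuple(
        StrandStateEmission(np.array(m), np.array(c), bool(tr))
        for m, c, tr in zip(doc["means"], doc["covariances"], doc["transcribed"])
    )
    core = CoreModel(tuple(doc["states"]), np.array(doc["A"]), emissions)
    stored_pi = np.array(doc["pi"])
    if not np.allclose(stored_pi, core.pi, atol=1e-6):
        raise DataError("stored pi inconsistent with A (corrupted model file?)")
    tracks = tuple(
        TrackMeta(
            t["name"], t["strand_class"], t.get("partner"),
            t.get("dominance_rule", MEAN_DOMINANCE),
        )
        for t in doc["tracks"]
    )
    track_layout(tracks)
    return core, tracks


def save_model(path, core: CoreModel, tracks: Sequence[TrackMeta]) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(core, tracks), fh, indent=1)


def load_model(path) -> tuple[CoreModel, tuple[TrackMeta, ...]]:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
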