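"""Ground-truth data generation: exact dsHMM sampling and a gene-scenario
generator.

`sample_from_model` draws from the generative model itself: the forward chain
is sampled left-to-right from ``pi`` then ``A``; the reverse chain starts at
the last position from ``pi`` and extends right-to-left with the same ``A``
(its own reading direction); each position then emits from the pair Gaussian
of its state pair.

`make_overlap_scenario` builds a small genome-like layout with four gene-sized
intervals — two transcribed forward, two reverse, one convergent pair
overlapping at their 3' ends — observed through one undirected occupancy
track that is high over each gene's 5' half and low over its 3' half (read
in the gene's own direction), and one strand-specific expression pair
elevated only over genes on its strand; signals are piecewise constant over
the planted intervals with independent Gaussian noise added.  The planted truth
uses three strand-generic states per strand: intergenic, gene-start and
gene-end.  The overlap region carries transcribed states on *both* strands
simultaneously — the configuration a single-chain HMM cannot represent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    CoreModel,
    DataError,
    GenomicGrid,
    ObservationSet,
    StrandStateEmission,
    TrackMeta,
    assemble_paired_model,
    track_layout,
)

INTERGENIC, GENE_START, GENE_END = 0, 1, 2
SCENARIO_STATE_NAMES = ("intergenic", "gene_start", "gene_end")


@dataclass
class SyntheticTruth:
    """Planted per-strand state paths and feature intervals."""

    fwd_path: np.ndarray
    rev_path: np.ndarray
    features: list[tuple[int, int, str, str]]  # (start_bin, end_bin, strand, label)
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.fwd_path = np.asarray(self.fwd_path, dtype=int)
        self.rev_path = np.asarray(self.rev_path, dtype=int)
        if self.fwd_path.shape != self.rev_path.shape:
            raise DataError("planted strand paths must have equal length")
        T = self.fwd_path.shape[0]
        for s, e, *_ in self.features:
            if not (0 <= s < e <= T):
                raise DataError(f"feature [{s}, {e}) outside [0, {T})")


def _sample_chain(A: np.ndarray, pi: np.ndarray, T: int, rng) -> np.ndarray:
    n = A.shape[0]
    states = np.empty(T, dtype=int)
    cum_pi = np.cumsum(pi)
    cum_A = np.cumsum(A, axis=1)
    u = rng.random(T)
    states[0] = np.searchsorted(cum_pi, u[0])
    for t in range(1, T):
        states[t] = np.searchsorted(cum_A[states[t - 1]], u[t])
    return np.minimum(states, n - 1)


def sample_from_model(
    model: CoreModel, tracks, T: int, seed: int
) -> tuple[ObservationSet, SyntheticTruth]:
    """Draw ``T`` positions exactly from a dsHMM; reproducible given ``seed``."""
    if T < 1:
        raise DataError("T must be >= 1")
    lay = track_layout(tracks) if not hasattr(tracks, "base_index") else tracks
    paired = assemble_paired_model(model, lay)
    rng = np.random.default_rng(seed)
    fwd = _sample_chain(model.A, model.pi, T, rng)
    rev = _sample_chain(model.A, model.pi, T, rng)[::-1].copy()
    pair = fwd * model.n_states + rev
    z = rng.standard_normal((T, lay.n_tracks))
    values = np.empty((T, lay.n_tracks))
    for s in np.unique(pair):
        idx = pair == s
        L = np.linalg.cholesky(paired.pair_covs[s])
        values[idx] = paired.pair_means[s] + z[idx] @ L.T
    obs = ObservationSet(values, lay.tracks, GenomicGrid())
    truth = SyntheticTruth(fwd, rev, [], config={"T": T}, seed=seed)
    return obs, truth


# ---------------------------------------------------------------------------
# gene scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """Geometry and noise of the four-gene overlap scenario.

    Defaults: genes of 200 bins separated by 100-bin gaps, a 50-bin
    convergent overlap, and independent Gaussian noise of sigma 0.1 on
    unit-height signals.  ``mirror=True`` reverses coordinates and swaps the
    strands of the finished dataset (same seed stream, deterministic
    transform).
    """

    gene_len: int = 200
    gap: int = 100
    overlap: int = 50
    noise: float = 0.1
    mirror: bool = False

    def __post_init__(self) -> None:
        if self.gene_len < 2 or self.gap < 0:
            raise DataError("gene_len must be >= 2 and gap >= 0")
        if not 0 < self.overlap < self.gene_len:
            raise DataError("overlap must lie strictly inside a gene")

    @property
    def n_bins(self) -> int:
        return 4 * self.gene_len + 4 * self.gap - self.overlap


def scenario_tracks() -> tuple[TrackMeta, ...]:
    """Track metadata of the scenario: one occupancy track, one expression pair."""
    return (
        TrackMeta("occupancy", "undirected"),
        TrackMeta("expr_fwd", "forward_specific", partner="expr_rev"),
        TrackMeta("expr_rev", "reverse_specific", partner="expr_fwd"),
    )


def make_overlap_scenario(
    config: ScenarioConfig = ScenarioConfig(), seed: int = 0
) -> tuple[ObservationSet, SyntheticTruth]:
    """Generate the four-gene overlapping-transcription scenario."""
    L, gap, ov = config.gene_len, config.gap, config.overlap
    T = config.n_bins
    genes = []  # (start, strand)
    pos = gap
    genes.append((pos, "+"))            # forward gene 1
    pos += L + gap
    genes.append((pos, "+"))            # forward gene 2
    r1 = pos + L - ov                   # reverse gene 1 overlaps gene 2's tail
    genes.append((r1, "-"))
    r2 = r1 + L + gap
    genes.append((r2, "-"))
    if r2 + L + gap != T:
        raise DataError("scenario geometry does not fit the computed length")

    occupancy = np.zeros(T)
    expr_fwd = np.zeros(T)
    expr_rev = np.zeros(T)
    fwd_path = np.full(T, INTERGENIC, dtype=int)
    rev_path = np.full(T, INTERGENIC, dtype=int)
    features = []
    half = L // 2
    # piecewise-constant occupancy: high over the 5' half, low over the 3' half
    profile = np.where(np.arange(L) < half, 1.0, 0.25)
    for k, (s, strand) in enumerate(genes):
        e = s + L
        if strand == "+":
            occupancy[s:e] += profile
            expr_fwd[s:e] += 1.0
            fwd_path[s:s + half] = GENE_START
            fwd_path[s + half:e] = GENE_END
        else:
            occupancy[s:e] += profile[::-1]  # 5' end of a reverse gene is at e
            expr_rev[s:e] += 1.0
            rev_path[e - half:e] = GENE_START
            rev_path[s:e - half] = GENE_END
        features.append((s, e, strand, f"gene{k + 1}"))

    rng = np.random.default_rng(seed)
    values = np.column_stack([occupancy, expr_fwd, expr_rev])
    values = values + rng.normal(0.0, config.noise, size=values.shape)

    if config.mirror:
        values = values[::-1].copy()
        values[:, [1, 2]] = values[:, [2, 1]]
        fwd_path, rev_path = rev_path[::-1].copy(), fwd_path[::-1].copy()
        features = [
            (T - e, T - s, "+" if strand == "-" else "-", label)
            for (s, e, strand, label) in features
        ][::-1]

    obs = ObservationSet(values, scenario_tracks(), GenomicGrid())
    truth = SyntheticTruth(
        fwd_path, rev_path, features,
        config={
            "gene_len": L, "gap": gap, "overlap": ov,
            "noise": config.noise, "mirror": config.mirror,
        },
        seed=seed,
    )
    return obs, truth


def write_truth(truth: SyntheticTruth, path) -> None:
    """Tab-separated planted paths: bin, forward state, reverse state."""
    with open(path, "w") as fh:
        fh.write("bin\tfwd_state\trev_state\n")
        for t in range(truth.fwd_path.shape[0]):
            fh.write(f"{t}\t{truth.fwd_path[t]}\t{truth.rev_path[t]}\n")


def write_features_gff3(
    truth: SyntheticTruth, path, grid: GenomicGrid = GenomicGrid()
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (s, e, strand, label) in enumerate(truth.features):
            gs = grid.start + s * grid.bin_width
            ge = grid.start + e * grid.bin_width
            fh.write(
                f"{grid.contig}\tdshmm_sim\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t."
                f"\tID={label};Name={label}\n"
            )


# ---------------------------------------------------------------------------
# reference models used in examples and validation experiments
# ---------------------------------------------------------------------------


def three_state_demo_model() -> tuple[CoreModel, tuple[TrackMeta, ...]]:
    """A known, well-separated 3-state dsHMM used for recovery experiments.

    One intergenic state and two transcribed states on an occupancy track
    plus an expression pair; unit-scale means, diagonal covariance with
    sigma = 0.1, symmetric transitions with 0.96 self-probability (uniform
    stationary law).
    """
    tracks = scenario_tracks()
    cov = np.diag([0.01, 0.01])
    emissions = (
        StrandStateEmission(np.array([0.05, 0.0]), cov, transcribed=False),
        StrandStateEmission(np.array([0.90, 1.0]), cov, transcribed=True),
        StrandStateEmission(np.array([0.40, 0.6]), cov, transcribed=True),
    )
    A = np.array(
        [[0.96, 0.02, 0.02], [0.02, 0.96, 0.02], [0.02, 0.02, 0.96]]
    )
    return CoreModel(("I1", "T1", "T2"), A, emissions), tracks


def random_model(
    n_states: int,
    tracks,
    seed: int,
    mean_scale: float = 1.0,
    correlated: bool = True,
) -> CoreModel:
    """A random ergodic dsHMM (Dirichlet transition rows, random PSD
    covariances); useful for structural and oracle tests.

    With ``correlated=False`` the cross-covariance between undirected and
    expression coordinates is zeroed.  On that subfamily the block-tiled pair
    covariance is exactly mirror-symmetric under strand swap, so the
    reversal + strand-swap likelihood invariance holds to machine precision
    (a tied undirected track in a self-pair otherwise carries its
    expression cross-covariance on the forward copy only).
    """
    lay = track_layout(tracks) if not hasattr(tracks, "base_index") else tracks
    rng = np.random.default_rng(seed)
    A = rng.dirichlet(np.ones(n_states) * 2.0, size=n_states)
    e_coords = sorted({lay.base_index[p] for p in lay.forward_cols})
    b_coords = [c for c in range(lay.n_base) if c not in e_coords]
    emissions = []
    for i in range(n_states):
        mean = rng.uniform(0.0, mean_scale, size=lay.n_base)
        w = rng.standard_normal((lay.n_base, lay.n_base)) * 0.2
        cov = w @ w.T + 0.05 * np.eye(lay.n_base)
        if not correlated:
            cov[np.ix_(b_coords, e_coords)] = 0.0
            cov[np.ix_(e_coords, b_coords)] = 0.0
        emissions.append(
            StrandStateEmission(mean, cov, transcribed=bool(rng.integers(2)))
        )
    names = tuple(f"S{i + 1}" for i in range(n_states))
    return CoreModel(names, A, tuple(emissions))
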