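"""Post-decoding summary analyses of a strand-pair annotation.

These mirror the standard readouts of a strand-specific segmentation: the
symmetric state-pair co-occurrence matrix, the 2x2 transcription contingency
table, metagene state-frequency profiles along an average transcript (sense
and antisense), a pruned transition graph, and per-state region/overlap
counting (e.g. bidirectional-promoter detection via overlapping initiation
regions).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .inference import Annotation
from .model import CoreModel, DataError, GenomicGrid

logger = logging.getLogger("dshmm")

#: default pruning threshold for the transition graph
DEFAULT_MIN_PROB = 0.012


@dataclass
class FeatureSet:
    """Oriented genomic intervals (genes, CUTs, ...) used for metagenes."""

    table: pd.DataFrame  # columns: contig, start, end, strand, label

    def __post_init__(self) -> None:
        required = {"contig", "start", "end", "strand", "label"}
        if not required.issubset(self.table.columns):
            raise DataError(f"feature table needs columns {sorted(required)}")
        if (self.table["start"] >= self.table["end"]).any():
            raise DataError("features must satisfy start < end")
        if not self.table["strand"].isin(["+", "-"]).all():
            raise DataError("feature strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_gff3(cls, path, feature_types: set[str] | None = None) -> "FeatureSet":
        """Read features from a GFF3 file (1-based closed -> 0-based half-open)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 8:
                    raise DataError(f"{path}: malformed GFF3 line: {line!r}")
                if feature_types is not None and f[2] not in feature_types:
                    continue
                label = f[2]
                if len(f) > 8:
                    for kv in f[8].split(";"):
                        if kv.startswith(("ID=", "Name=")):
                            label = kv.split("=", 1)[1]
                            break
                rows.append(
                    {"contig": f[0], "start": int(f[3]) - 1, "end": int(f[4]),
                     "strand": f[6], "label": label}
                )
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_intervals(
        cls, intervals, grid: GenomicGrid = GenomicGrid()
    ) -> "FeatureSet":
        """Build from (start_bin, end_bin, strand, label) tuples on a grid."""
        rows = [
            {"contig": grid.contig,
             "start": grid.start + s * grid.bin_width,
             "end": grid.start + e * grid.bin_width,
             "strand": strand, "label": label}
            for s, e, strand, label in intervals
        ]
        return cls(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# co-occurrence and contingency
# ---------------------------------------------------------------------------


def pair_cooccurrence(ann: Annotation) -> np.ndarray:
    """Symmetric state-pair frequency matrix.

    Entry (x, y) is the fraction of bins annotated (x forward, y reverse)
    plus the fraction annotated (y forward, x reverse); the matrix is
    symmetric by construction and its total mass is 2 (each bin contributes
    to (x, y) and to (y, x); diagonal entries count their bins twice).
    """
    n = ann.n_states
    counts = np.zeros((n, n))
    np.add.at(counts, (ann.fwd_path, ann.rev_path), 1.0)
    counts /= ann.n_bins
    return counts + counts.T


def write_cooccurrence(matrix: np.ndarray, state_names, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# symmetric state-pair co-occurrence; entry (x,y) = fraction of "
            "bins with (x fwd, y rev) plus (y fwd, x rev); total mass 2\n"
        )
        pd.DataFrame(matrix, index=state_names, columns=state_names).to_csv(
            fh, sep="\t"
        )


def contingency_transcription(
    ann: Annotation, transcribed: np.ndarray
) -> np.ndarray:
    """2x2 fraction table {untranscribed, transcribed} fwd x rev; sums to 1."""
    transcribed = np.asarray(transcribed)
    if transcribed.shape[0] != ann.n_states:
        raise DataError(
            f"need a transcribed flag for every one of the {ann.n_states} states"
        )
    if transcribed.dtype != bool:
        raise DataError("transcribed flags must be booleans (no unlabeled states)")
    table = np.zeros((2, 2))
    f = transcribed[ann.fwd_path].astype(int)
    r = transcribed[ann.rev_path].astype(int)
    np.add.at(table, (f, r), 1.0)
    return table / ann.n_bins


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------


@dataclass
class MetageneProfiles:
    """Per-state frequency curves along a length-normalized transcript.

    ``sense``/``antisense`` have shape (flank + n_bins_scaled + flank,
    n_states); rows are metagene positions 5'->3' (flank upstream, scaled
    body, flank downstream) and sum to 1 over states wherever any feature
    contributed.
    """

    sense: np.ndarray
    antisense: np.ndarray
    flank: int
    n_bins_scaled: int
    n_features: int


def metagene_profiles(
    ann: Annotation,
    features: FeatureSet,
    n_bins_scaled: int = 100,
    flank: int | None = None,
) -> MetageneProfiles:
    """State-frequency profiles along the average feature, per strand role.

    Each feature's decoded path is read in the feature's 5'->3' orientation
    (reverse-strand features are flipped, with the strand roles swapped); the
    body is resampled to ``n_bins_scaled`` positions by nearest-bin lookup
    and fixed-length flanks are attached.  The sense curve uses the
    feature-strand path, the antisense curve the opposite strand.  Features
    shorter than 2 bins are skipped with a warning.  ``flank`` defaults to
    500 bp worth of bins.
    """
    grid = ann.coords
    if flank is None:
        flank = max(1, round(500 / grid.bin_width))
    n = ann.n_states
    width = flank + n_bins_scaled + flank
    acc = {"sense": np.zeros((width, n)), "anti": np.zeros((width, n))}
    cov = {"sense": np.zeros(width), "anti": np.zeros(width)}
    n_used = 0
    for _, row in features.table.iterrows():
        b0 = (row["start"] - grid.start) // grid.bin_width
        b1 = (row["end"] - grid.start) // grid.bin_width
        if b1 - b0 < 2:
            logger.warning("feature %s shorter than 2 bins; skipped", row["label"])
            continue
        n_used += 1
        minus = row["strand"] == "-"
        sense_path = ann.rev_path if minus else ann.fwd_path
        anti_path = ann.fwd_path if minus else ann.rev_path
        body = np.arange(b0, b1)
        up = np.arange(b0 - flank, b0)
        down = np.arange(b1, b1 + flank)
        if minus:
            body = body[::-1]
            up, down = (
                np.arange(b1 + flank - 1, b1 - 1, -1),
                np.arange(b0 - 1, b0 - flank - 1, -1),
            )
        scaled = body[
            np.minimum(
                (np.arange(n_bins_scaled) * len(body)) // n_bins_scaled,
                len(body) - 1,
            )
        ]
        positions = np.concatenate([up, scaled, down])
        valid = (positions >= 0) & (positions < ann.n_bins)
        idx = np.where(valid)[0]
        for key, path in (("sense", sense_path), ("anti", anti_path)):
            acc[key][idx, path[positions[idx]]] += 1.0
            cov[key][idx] += 1.0
    for key in acc:
        nz = cov[key] > 0
        acc[key][nz] /= cov[key][nz, None]
    return MetageneProfiles(
        sense=acc["sense"], antisense=acc["anti"],
        flank=flank, n_bins_scaled=n_bins_scaled, n_features=n_used,
    )


# ---------------------------------------------------------------------------
# transition graph
# ---------------------------------------------------------------------------


def transition_summary(
    source: Annotation | CoreModel,
    min_prob: float = DEFAULT_MIN_PROB,
) -> nx.DiGraph:
    """Directed state graph of observed (or model) transition frequencies.

    From an :class:`Annotation`, transitions are counted on both per-strand
    paths in their own reading direction (the reverse path right-to-left) and
    row-normalized; from a :class:`CoreModel`, the entries of ``A`` are used
    directly.  Self-loops are excluded and edges below ``min_prob`` (default
    0.012) are pruned.
    """
    if isinstance(source, CoreModel):
        freq = source.A.copy()
        n = source.n_states
    else:
        n = source.n_states
        counts = np.zeros((n, n))
        fwd, rev = source.fwd_path, source.rev_path
        np.add.at(counts, (fwd[:-1], fwd[1:]), 1.0)
        np.add.at(counts, (rev[1:], rev[:-1]), 1.0)  # reverse chain reads right-to-left
        row = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            freq = np.where(row > 0, counts / np.where(row > 0, row, 1.0), 0.0)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and freq[i, j] > 0 and freq[i, j] >= min_prob:
                g.add_edge(i, j, weight=float(freq[i, j]))
    return g


def write_transition_graph(g: nx.DiGraph, state_names, path) -> None:
    with open(path, "w") as fh:
        fh.write("from\tto\tfrequency\n")
        for i, j, d in sorted(g.edges(data=True)):
            fh.write(f"{state_names[i]}\t{state_names[j]}\t{d['weight']!r}\n")


# ---------------------------------------------------------------------------
# region counting
# ---------------------------------------------------------------------------


@dataclass
class RegionCount:
    n_regions: int
    n_overlapping: int
    regions: list[tuple[int, int]]


def _state_runs(path: np.ndarray, state: int) -> list[tuple[int, int]]:
    mask = np.concatenate([[False], path == state, [False]])
    starts = np.flatnonzero(~mask[:-1] & mask[1:])
    ends = np.flatnonzero(mask[:-1] & ~mask[1:])
    return list(zip(starts.tolist(), ends.tolist()))


def count_state_regions(
    ann: Annotation, state: int, strand: str = "+"
) -> RegionCount:
    """Maximal same-state runs on one strand, and how many of them share at
    least one bin with a same-state run on the opposite strand."""
    if not 0 <= state < ann.n_states:
        raise DataError(f"unknown state index {state}")
    if strand not in ("+", "-"):
        raise DataError("strand must be '+' or '-'")
    own = ann.fwd_path if strand == "+" else ann.rev_path
    other = ann.rev_path if strand == "+" else ann.fwd_path
    regions = _state_runs(own, state)
    other_mask = other == state
    n_overlap = sum(1 for s, e in regions if other_mask[s:e].any())
    return RegionCount(len(regions), n_overlap, regions)


# ---------------------------------------------------------------------------
# bundled report
# ---------------------------------------------------------------------------


def write_summary_report(
    ann: Annotation,
    state_names,
    outdir,
    transcribed: np.ndarray | None = None,
    features: FeatureSet | None = None,
    min_prob: float = DEFAULT_MIN_PROB,
) -> None:
    """Write the standard summary tables to a directory."""
    os.makedirs(outdir, exist_ok=True)
    write_cooccurrence(
        pair_cooccurrence(ann), state_names,
        os.path.join(outdir, "pair_cooccurrence.tsv"),
    )
    write_transition_graph(
        transition_summary(ann, min_prob), state_names,
        os.path.join(outdir, "transition_graph.tsv"),
    )
    if transcribed is not None:
        table = contingency_transcription(ann, np.asarray(transcribed))
        pd.DataFrame(
            table,
            index=["fwd_untranscribed", "fwd_transcribed"],
            columns=["rev_untranscribed", "rev_transcribed"],
        ).to_csv(os.path.join(outdir, "contingency.tsv"), sep="\t")
    if features is not None and len(features):
        prof = metagene_profiles(ann, features)
        for name, mat in (("sense", prof.sense), ("antisense", prof.antisense)):
            pd.DataFrame(mat, columns=state_names).to_csv(
                os.path.join(outdir, f"metagene_{name}.tsv"), sep="\t",
                index_label="position",
            )
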