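"""Reading signal tracks, quantile rescaling, and stranded annotation export.

Tracks are read from a YAML manifest that lists one entry per track (name,
file, strand class, partner, dominance rule), either as per-track bedGraph /
fixed-step wiggle files or as one tabular matrix (first column = bin start,
header = track names).  All tracks must live on a single shared grid of
contiguous, equally sized bins.  Coordinates are 0-based half-open
internally; BED exports keep that convention, GFF3 exports are 1-based
closed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .inference import Annotation
from .model import (
    DataError,
    GenomicGrid,
    MEAN_DOMINANCE,
    ObservationSet,
    TrackMeta,
    track_layout,
)


@dataclass
class RawTrack:
    """Per-bin values of one track on one contig grid."""

    meta: TrackMeta
    values: np.ndarray
    grid: GenomicGrid


# ---------------------------------------------------------------------------
# track file readers
# ---------------------------------------------------------------------------


def _read_bedgraph(path) -> tuple[np.ndarray, GenomicGrid]:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["contig", "start", "end", "value"],
        dtype={"contig": str}, float_precision="round_trip",
        skiprows=_n_header_lines(path),
    )
    if df.empty:
        raise DataError(f"{path}: no intervals")
    contigs = df["contig"].unique()
    if len(contigs) != 1:
        raise DataError(f"{path}: expected a single contig, found {list(contigs)}")
    df = df.sort_values("start", kind="stable").reset_index(drop=True)
    starts = df["start"].to_numpy(dtype=int)
    ends = df["end"].to_numpy(dtype=int)
    widths = ends - starts
    if len(np.unique(widths)) != 1:
        raise DataError(f"{path}: bins are not of uniform width")
    if np.unique(starts).size != starts.size:
        raise DataError(f"{path}: duplicate intervals")
    if np.any(starts[1:] != ends[:-1]):
        i = int(np.where(starts[1:] != ends[:-1])[0][0])
        raise DataError(
            f"{path}: intervals overlap or leave a gap after position {ends[i]}"
        )
    grid = GenomicGrid(str(contigs[0]), int(starts[0]), int(widths[0]))
    return df["value"].to_numpy(dtype=float), grid


def _n_header_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def _read_wiggle(path) -> tuple[np.ndarray, GenomicGrid]:
    values: list[float] = []
    contig = None
    origin = None
    step = None
    expect_next = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                c = fields["chrom"]
                s = int(fields["start"]) - 1  # wiggle is 1-based
                st = int(fields.get("step", 1))
                if contig is None:
                    contig, origin, step = c, s, st
                else:
                    if c != contig or st != step or s != expect_next:
                        raise DataError(
                            f"{path}: fixedStep blocks are not contiguous on one grid"
                        )
                expect_next = s
            elif line.startswith("variableStep"):
                raise DataError(f"{path}: only fixedStep wiggle is supported")
            else:
                if contig is None:
                    raise DataError(f"{path}: data before fixedStep header")
                values.append(float(line))
                expect_next += step
    if not values:
        raise DataError(f"{path}: no values")
    return np.array(values), GenomicGrid(contig, origin, step)


def _read_matrix(path) -> tuple[pd.DataFrame, GenomicGrid, str]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise DataError(f"{path}: matrix needs a start column plus track columns")
    starts = df.iloc[:, 0].to_numpy(dtype=int)
    if len(starts) > 1:
        widths = np.diff(starts)
        if len(np.unique(widths)) != 1 or widths[0] <= 0:
            raise DataError(f"{path}: bin starts are not a uniform increasing grid")
        width = int(widths[0])
    else:
        width = 1
    grid = GenomicGrid("chr", int(starts[0]), width)
    return df, grid, df.columns[0]


def read_tracks(manifest_path) -> ObservationSet:
    """Assemble an :class:`ObservationSet` from a YAML manifest.

    The manifest lists ``tracks`` (name, strand_class, optional partner and
    dominance_rule) with either a ``file`` per track (bedGraph or fixed-step
    wiggle, chosen by extension or an explicit ``format``) or one top-level
    ``matrix`` file whose header names the tracks.  An optional ``contig``
    overrides the contig name of matrix input.
    """
    with open(manifest_path) as fh:
        doc = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(manifest_path))
    entries = doc.get("tracks")
    if not entries:
        raise DataError("manifest lists no tracks")
    metas = tuple(
        TrackMeta(
            e["name"], e["strand_class"], e.get("partner"),
            e.get("dominance_rule", MEAN_DOMINANCE),
        )
        for e in entries
    )
    track_layout(metas)  # validates names/partner bijection early

    if "matrix" in doc:
        df, grid, start_col = _read_matrix(os.path.join(base, doc["matrix"]))
        missing = [m.name for m in metas if m.name not in df.columns]
        if missing:
            raise DataError(f"matrix is missing track columns {missing}")
        values = df[[m.name for m in metas]].to_numpy(dtype=float)
        if "contig" in doc:
            grid = GenomicGrid(str(doc["contig"]), grid.start, grid.bin_width)
        return ObservationSet(values, metas, grid)

    columns = []
    grid = None
    for e, meta in zip(entries, metas):
        if "file" not in e:
            raise DataError(f"track {meta.name!r}: no file and no matrix given")
        path = os.path.join(base, e["file"])
        fmt = e.get("format") or (
            "wig" if path.endswith((".wig", ".wiggle")) else "bedgraph"
        )
        if fmt == "bedgraph":
            vals, g = _read_bedgraph(path)
        elif fmt == "wig":
            vals, g = _read_wiggle(path)
        else:
            raise DataError(f"track {meta.name!r}: unknown format {fmt!r}")
        if grid is None:
            grid, n_bins = g, len(vals)
        elif g != grid or len(vals) != n_bins:
            raise DataError(
                f"track {meta.name!r}: grid {g} with {len(vals)} bins does not "
                f"match the first track's grid {grid} with {n_bins} bins"
            )
        columns.append(vals)
    return ObservationSet(np.column_stack(columns), metas, grid)


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------


def quantile_rescale(
    values: np.ndarray, q_low: float = 0.05, q_high: float = 0.95
) -> np.ndarray:
    """Affine-map values so the ``q_low`` quantile is 0 and ``q_high`` is 1.

    Quantiles use the linear-interpolation (type-7) convention.  Values
    outside [0, 1] are kept (tails are not clipped), so the map is strictly
    monotone and idempotent on its own output.
    """
    values = np.asarray(values, dtype=float)
    if not q_low < q_high:
        raise DataError("q_low must be below q_high")
    lo, hi = np.quantile(values, [q_low, q_high])
    if hi <= lo:
        raise DataError(
            f"degenerate track: the {q_low:.0%} and {q_high:.0%} quantiles "
            f"coincide at {lo:.6g}"
        )
    return (values - lo) / (hi - lo)


def rescale_observation_set(
    obs: ObservationSet, q_low: float = 0.05, q_high: float = 0.95
) -> ObservationSet:
    """Apply :func:`quantile_rescale` to every track column."""
    cols = [quantile_rescale(obs.values[:, p], q_low, q_high)
            for p in range(obs.values.shape[1])]
    return ObservationSet(np.column_stack(cols), obs.tracks, obs.coords)


# ---------------------------------------------------------------------------
# annotation export / import
# ---------------------------------------------------------------------------


def _runs(path: np.ndarray):
    """Yield (start_bin, end_bin, state) for maximal constant runs."""
    breaks = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(path)]])
    for s, e in zip(starts, ends):
        yield int(s), int(e), int(path[s])


def write_annotation(
    ann: Annotation, state_names, prefix, contig_length: int | None = None
) -> dict:
    """Write an annotation as two stranded BED files plus one combined GFF3.

    Consecutive bins with identical state are merged into intervals.  BED is
    0-based half-open with the strand in column 6; GFF3 is 1-based closed
    with the state name as feature type.  Returns the paths written.
    """
    state_names = list(state_names)
    grid = ann.coords
    end_coord = grid.start + ann.n_bins * grid.bin_width
    if contig_length is not None and end_coord > contig_length:
        raise DataError(
            f"annotation extends to {end_coord}, beyond contig length "
            f"{contig_length}"
        )
    paths = {
        "fwd_bed": f"{prefix}.fwd.bed",
        "rev_bed": f"{prefix}.rev.bed",
        "gff3": f"{prefix}.gff3",
    }
    records = []  # (start, strand_order, end, state)
    for strand, strand_path, key in (
        ("+", ann.fwd_path, "fwd_bed"),
        ("-", ann.rev_path, "rev_bed"),
    ):
        with open(paths[key], "w") as bed:
            for s, e, state in _runs(strand_path):
                gs = grid.start + s * grid.bin_width
                ge = grid.start + e * grid.bin_width
                name = state_names[state]
                bed.write(f"{grid.contig}\t{gs}\t{ge}\t{name}\t0\t{strand}\n")
                records.append((gs, strand, ge, name))
    with open(paths["gff3"], "w") as gff:
        gff.write("##gff-version 3\n")
        gff.write(f"##dshmm-bin-width {grid.bin_width}\n")
        gff.write(f"##dshmm-origin {grid.start}\n")
        gff.write(f"##dshmm-bins {ann.n_bins}\n")
        gff.write(f"##dshmm-states {','.join(state_names)}\n")
        for i, (gs, strand, ge, name) in enumerate(sorted(records)):
            gff.write(
                f"{grid.contig}\tdshmm\t{name}\t{gs + 1}\t{ge}\t.\t{strand}\t."
                f"\tID=seg{i:05d}\n"
            )
    return paths


def read_annotation(gff3_path) -> tuple[Annotation, list[str]]:
    """Reconstruct the per-bin annotation from a GFF3 written by this package."""
    bin_width = origin = n_bins = None
    state_names: list[str] | None = None
    rows = []
    contig = "chr"
    with open(gff3_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##dshmm-bin-width"):
                bin_width = int(line.split()[-1])
            elif line.startswith("##dshmm-origin"):
                origin = int(line.split()[-1])
            elif line.startswith("##dshmm-bins"):
                n_bins = int(line.split()[-1])
            elif line.startswith("##dshmm-states"):
                state_names = line.split()[-1].split(",")
            elif line.startswith("#") or not line:
                continue
            else:
                f = line.split("\t")
                contig = f[0]
                rows.append((int(f[3]) - 1, int(f[4]), f[6], f[2]))
    if None in (bin_width, origin, n_bins) or state_names is None:
        raise DataError(f"{gff3_path}: missing dshmm grid directives")
    index = {n: i for i, n in enumerate(state_names)}
    fwd = np.full(n_bins, -1, dtype=int)
    rev = np.full(n_bins, -1, dtype=int)
    for gs, ge, strand, name in rows:
        if name not in index:
            raise DataError(f"{gff3_path}: unknown state {name!r}")
        b0 = (gs - origin) // bin_width
        b1 = (ge - origin) // bin_width
        (fwd if strand == "+" else rev)[b0:b1] = index[name]
    if (fwd < 0).any() or (rev < 0).any():
        raise DataError(f"{gff3_path}: annotation does not cover every bin")
    ann = Annotation.from_strand_paths(
        fwd, rev, len(state_names), GenomicGrid(contig, origin, bin_width)
    )
    return ann, state_names


# ---------------------------------------------------------------------------
# track export (used by the simulator and for round-trips)
# ---------------------------------------------------------------------------


def write_observation_set(obs: ObservationSet, outdir, manifest="manifest.yaml") -> str:
    """Write one bedGraph per track plus a manifest; returns the manifest path."""
    os.makedirs(outdir, exist_ok=True)
    grid = obs.coords
    entries = []
    for p, meta in enumerate(obs.tracks):
        fname = f"{meta.name}.bedgraph"
        with open(os.path.join(outdir, fname), "w") as fh:
            for t in range(obs.n_bins):
                gs = grid.start + t * grid.bin_width
                fh.write(
                    f"{grid.contig}\t{gs}\t{gs + grid.bin_width}\t"
                    f"{float(obs.values[t, p])!r}\n"
                )
        entry = {"name": meta.name, "file": fname,
                 "strand_class": meta.strand_class}
        if meta.partner:
            entry["partner"] = meta.partner
        if meta.dominance_rule != MEAN_DOMINANCE:
            entry["dominance_rule"] = meta.dominance_rule
        entries.append(entry)
    mpath = os.path.join(outdir, manifest)
    with open(mpath, "w") as fh:
        yaml.safe_dump({"tracks": entries}, fh, sort_keys=False)
    return mpath
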