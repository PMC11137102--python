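"""Readers and writers for the package's plain-text interchange formats.

All genomic intervals are BED-convention: 0-based, half-open. Tables are
tab-separated; metadata lines start with '#'. Nothing binary is written.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cin import ClusterCentroids, PeakRegionSet
from .cna import BinnedCoverageProfile, ReferencePanel, SegmentedCNAProfile
from .nucleosome import NucleosomeTrack

__all__ = [
    "FORMAT_VERSION",
    "RunConfig",
    "read_bed",
    "write_bed",
    "read_binned_profile",
    "write_binned_profile",
    "read_peaks",
    "write_peaks",
    "read_centroids",
    "write_centroids",
    "read_panel",
    "write_panel",
    "write_segments",
    "read_nucleosome_track",
    "write_nucleosome_track",
    "read_fragments",
    "write_fragments",
    "read_table",
    "write_table",
    "load_run_config",
]

FORMAT_VERSION = "cfcin/0.1"


def read_bed(path, min_fields: int = 3) -> pd.DataFrame:
    """Read a BED-like TSV; rejects malformed lines with their line number.

    Columns beyond chrom/start/end are preserved as col4, col5, ...
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_fields:
                raise ValueError(f"{path}:{lineno}: expected at least "
                                 f"{min_fields} fields, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer "
                                 "coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted "
                                 f"interval [{start}, {end})")
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate")
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise ValueError(f"{path}:{lineno}: ragged row")
            rows.append([parts[0], start, end] + parts[3:])
    if not rows:
        raise ValueError(f"{path}: no intervals")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, ncols + 1)]
    return pd.DataFrame(rows, columns=cols)


def write_bed(path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION}\n")
        for _, row in df.iterrows():
            fh.write("\t".join(str(v) for v in row.tolist()) + "\n")


def write_binned_profile(path, profile: BinnedCoverageProfile) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} binned-counts sample={profile.sample_id}\n")
        for c, s, e, n in zip(profile.chrom, profile.start, profile.end,
                              profile.counts):
            fh.write(f"{c}\t{s}\t{e}\t{n}\n")


def read_binned_profile(path, sample_id: str | None = None
                        ) -> BinnedCoverageProfile:
    df = read_bed(path, min_fields=4)
    if sample_id is None:
        sample_id = Path(path).stem
    return BinnedCoverageProfile(sample_id, df.chrom.to_numpy(),
                                 df.start.to_numpy(), df.end.to_numpy(),
                                 df.col4.astype(float).astype(int).to_numpy())


def write_peaks(path, peaks: PeakRegionSet) -> None:
    df = pd.DataFrame({"chrom": peaks.chrom, "start": peaks.start,
                       "end": peaks.end, "label": peaks.label,
                       "direction": peaks.direction})
    write_bed(path, df)


def read_peaks(path) -> PeakRegionSet:
    df = read_bed(path, min_fields=5)
    return PeakRegionSet(df.chrom.to_numpy(), df.start.to_numpy(),
                         df.end.to_numpy(), df.col4.to_numpy(),
                         df.col5.to_numpy())


def write_centroids(path, centroids: ClusterCentroids) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} centroids "
                 f"burden_threshold={centroids.burden_threshold}\n")
        fh.write("peak\tcluster1\tcluster2\tcluster3\n")
        for i in range(centroids.centroids.shape[1]):
            vals = "\t".join(f"{centroids.centroids[k, i]:.6g}"
                             for k in range(3))
            fh.write(f"{i}\t{vals}\n")


def read_centroids(path) -> ClusterCentroids:
    burden = 0.05
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "burden_threshold=" in first:
            burden = float(first.split("burden_threshold=")[1].split()[0])
    df = pd.read_csv(path, sep="\t", comment="#")
    cents = df[["cluster1", "cluster2", "cluster3"]].to_numpy().T
    return ClusterCentroids(cents, burden_threshold=burden)


def write_panel(path, panel: ReferencePanel) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} reference-panel "
                 f"samples={','.join(panel.sample_ids)}\n")
        fh.write("chrom\tstart\tend\tlocation\tscale\tblacklist\n")
        for i in range(panel.n_bins):
            fh.write(f"{panel.chrom[i]}\t{panel.start[i]}\t{panel.end[i]}\t"
                     f"{panel.location[i]:.8g}\t{panel.scale[i]:.8g}\t"
                     f"{int(panel.blacklist[i])}\n")


def read_panel(path) -> ReferencePanel:
    sample_ids = []
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "samples=" in first:
            sample_ids = first.split("samples=")[1].split()[0].split(",")
    df = pd.read_csv(path, sep="\t", comment="#")
    return ReferencePanel(df.chrom.to_numpy(), df.start.to_numpy(int),
                          df.end.to_numpy(int), df.location.to_numpy(float),
                          df.scale.to_numpy(float),
                          df.blacklist.to_numpy(bool), sample_ids)


def write_segments(path, seg: SegmentedCNAProfile) -> None:
    """Segments as BED: chrom, start, end, mean_log2, n_bins."""
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} segments sample={seg.sample_id}\n")
        for s in seg.segments:
            g_start = seg.start[s.start_bin]
            g_end = seg.end[s.end_bin - 1]
            fh.write(f"{s.chrom}\t{g_start}\t{g_end}\t{s.mean:.6g}\t"
                     f"{s.n_bins}\n")


def write_nucleosome_track(path, track: NucleosomeTrack) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} nucleosome-centers\n")
        for c, centers in track.centers.items():
            for p in centers:
                fh.write(f"{c}\t{p}\t{p + 1}\n")


def read_nucleosome_track(path) -> NucleosomeTrack:
    df = read_bed(path)
    centers = {c: sub.start.to_numpy()
               for c, sub in df.groupby("chrom", sort=False)}
    return NucleosomeTrack(centers)


def write_fragments(path, fragments: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} fragment-starts\n")
        for c, pos in fragments.items():
            for p in pos:
                fh.write(f"{c}\t{p}\t{p + 1}\n")


def read_fragments(path) -> dict:
    df = read_bed(path)
    return {c: sub.start.to_numpy()
            for c, sub in df.groupby("chrom", sort=False)}


def write_table(path, df: pd.DataFrame, metadata: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} {metadata}".rstrip() + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RunConfig:
    """Paths and thresholds for a non-simulated pipeline run."""

    panel: str | None = None
    peaks: str | None = None
    centroids: str | None = None
    track: str | None = None
    burden_threshold: float = 0.05
    floor_tf: float = 0.03
    calling_threshold: float = 0.1
    split_threshold: float = 5.0
    min_segment_bins: int = 5
    seed: int = 0
    out_dir: str = "."

    def validate_paths(self) -> None:
        for name in ("panel", "peaks", "centroids", "track"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(
                    f"configured {name} file does not exist: {p}")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate_paths()
    return cfg


def to_jsonable(obj):
    """Recursively convert numpy/pandas scalars for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
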