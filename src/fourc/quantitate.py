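"""Windowed interaction tracks, normalisation and subtraction.

Per-fragment 4C counts are summarised two ways, matching standard
viewpoint-track practice:

* **absolute** — fixed genomic windows (default 10 kb); read counts per
  window, normalised across libraries to the one with the highest
  coverage, optionally expressed per million reads of the sequencing
  library;
* **relative** — adaptive windows sized so each holds a fixed combined
  read count across all samples (default 50 000), with each sample's
  window counts divided by its own total so scores are depth-corrected
  proportions summing to 1.

Differential (subtraction) tracks are computed windowwise on identically
normalised tracks; positive scores mark gained contacts, negative ones
lost contacts.  Tracks serialise to headered bedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .demux_assign import FragmentCountVector
from .fragment_map import RestrictionFragmentMap

__all__ = [
    "GenomicTrack",
    "WindowPartition",
    "fixed_window_track",
    "normalize_to_max_library",
    "per_million",
    "adaptive_partition",
    "relative_quantitate",
    "subtract_tracks",
    "write_bedgraph",
    "read_bedgraph",
]

SCHEMES = ("fixed", "adaptive")
NORMALISATIONS = ("raw", "max-library", "per-million", "relative", "difference")


@dataclass
class GenomicTrack:
    """Windowed scores for one sample with normalisation provenance."""

    sample_name: str
    starts: np.ndarray
    ends: np.ndarray
    scores: np.ndarray
    scheme: str
    normalisation: str

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (self.starts.size == self.ends.size == self.scores.size):
            raise ValueError("starts, ends and scores must be parallel")
        if np.any(self.starts >= self.ends):
            raise ValueError("windows need start < end")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("windows must be sorted and non-overlapping")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.normalisation not in NORMALISATIONS:
            raise ValueError(f"unknown normalisation {self.normalisation!r}")

    def __len__(self) -> int:
        return int(self.scores.size)

    @property
    def total(self) -> float:
        return float(self.scores.sum())

    def same_windows(self, other: "GenomicTrack") -> bool:
        return np.array_equal(self.starts, other.starts) and np.array_equal(
            self.ends, other.ends
        )


@dataclass(frozen=True)
class WindowPartition:
    """Adaptive windows as contiguous fragment-index ranges.

    ``frag_bounds[i] .. frag_bounds[i+1]`` are the fragments of window
    *i*; genomic coordinates tile the full reference so the windows are
    directly comparable with fixed-window tracks.
    """

    frag_bounds: np.ndarray  # length n_windows + 1
    starts: np.ndarray
    ends: np.ndarray

    def __len__(self) -> int:
        return int(self.starts.size)


def fixed_window_track(
    count_vector: FragmentCountVector,
    fragment_map: RestrictionFragmentMap,
    window_size: int = 10_000,
) -> GenomicTrack:
    """Raw counts in fixed windows; a fragment belongs to the window
    containing its start coordinate."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    length = fragment_map.sequence_length
    n_windows = -(-length // window_size)
    window_of_fragment = fragment_map.starts // window_size
    scores = np.bincount(
        window_of_fragment, weights=count_vector.counts, minlength=n_windows
    )
    starts = np.arange(n_windows, dtype=np.int64) * window_size
    ends = np.minimum(starts + window_size, length)
    return GenomicTrack(
        sample_name=count_vector.sample_name,
        starts=starts,
        ends=ends,
        scores=scores,
        scheme="fixed",
        normalisation="raw",
    )


def normalize_to_max_library(tracks: list[GenomicTrack]) -> list[GenomicTrack]:
    """Scale every track up to the coverage of the deepest library.

    Each track's scores are multiplied by (max total over tracks) / (own
    total), so the highest-coverage track is unchanged and all totals
    become equal.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to cross-normalise")
    first = tracks[0]
    for track in tracks[1:]:
        if not track.same_windows(first):
            raise ValueError("tracks must share identical windows")
    totals = np.array([t.total for t in tracks])
    if np.any(totals <= 0):
        raise ValueError("every track needs a positive total score")
    max_total = totals.max()
    return [
        replace(t, scores=t.scores * (max_total / total), normalisation="max-library")
        for t, total in zip(tracks, totals)
    ]


def per_million(track: GenomicTrack, library_size: float) -> GenomicTrack:
    """Express scores per million reads of the sequencing library."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return replace(
        track, scores=track.scores * (1e6 / library_size), normalisation="per-million"
    )


def adaptive_partition(
    count_vectors: list[FragmentCountVector],
    fragment_map: RestrictionFragmentMap,
    target: int = 50_000,
) -> WindowPartition:
    """Windows each holding >= ``target`` combined reads across samples.

    Greedy left-to-right scan over fragments: a window closes at the
    first fragment where the cumulative combined count reaches the
    target; the terminal window keeps the remainder (possibly short).
    """
    if target <= 0:
        raise ValueError("target must be positive")
    if not count_vectors:
        raise ValueError("need at least one sample")
    combined = np.sum([cv.counts for cv in count_vectors], axis=0)
    if combined.sum() == 0:
        raise ValueError("combined counts are all zero; cannot partition")
    bounds = [0]
    acc = 0
    for i, c in enumerate(combined):
        acc += int(c)
        if acc >= target:
            bounds.append(i + 1)
            acc = 0
    if bounds[-1] != len(combined):
        bounds.append(len(combined))
    frag_bounds = np.asarray(bounds, dtype=np.int64)
    starts = fragment_map.starts[frag_bounds[:-1]]
    ends = np.append(
        fragment_map.starts[frag_bounds[1:-1]], fragment_map.sequence_length
    )
    return WindowPartition(frag_bounds=frag_bounds, starts=starts, ends=ends)


def relative_quantitate(
    count_vector: FragmentCountVector, partition: WindowPartition
) -> GenomicTrack:
    """Depth-corrected window proportions on an adaptive partition.

    Window score = (counts in window) / (sample total); one sample's
    scores sum to 1 exactly, making libraries of different depth
    directly comparable.
    """
    total = count_vector.total_assigned
    if total == 0:
        raise ValueError(f"sample {count_vector.sample_name!r} has zero assigned reads")
    cumulative = np.concatenate([[0], np.cumsum(count_vector.counts)])
    window_counts = np.diff(cumulative[partition.frag_bounds])
    return GenomicTrack(
        sample_name=count_vector.sample_name,
        starts=partition.starts,
        ends=partition.ends,
        scores=window_counts / total,
        scheme="adaptive",
        normalisation="relative",
    )


def subtract_tracks(track_a: GenomicTrack, track_b: GenomicTrack) -> GenomicTrack:
    """Windowwise difference a - b of two identically normalised tracks."""
    if not track_a.same_windows(track_b):
        raise ValueError("difference requires identical windows")
    if track_a.normalisation != track_b.normalisation:
        raise ValueError("difference requires identically normalised tracks")
    if track_a.normalisation not in ("max-library", "relative", "per-million"):
        raise ValueError(
            f"refusing to subtract {track_a.normalisation!r} tracks; normalise first"
        )
    return GenomicTrack(
        sample_name=f"{track_a.sample_name}-minus-{track_b.sample_name}",
        starts=track_a.starts,
        ends=track_a.ends,
        scores=track_a.scores - track_b.scores,
        scheme=track_a.scheme,
        normalisation="difference",
    )


def write_bedgraph(track: GenomicTrack, chrom_name: str, path, log=None) -> None:
    """Headered bedGraph with 6-significant-digit scores."""
    with open(path, "w") as handle:
        handle.write(
            f'track type=bedGraph name="{track.sample_name}" '
            f'description="sample={track.sample_name};scheme={track.scheme};'
            f'normalisation={track.normalisation}"\n'
        )
        for start, end, score in zip(track.starts, track.ends, track.scores):
            handle.write(f"{chrom_name}\t{start}\t{end}\t{score:.6g}\n")
    if log is not None:
        print(
            f"[fourc] wrote {len(track)} windows for {track.sample_name} "
            f"({track.scheme}/{track.normalisation}, total={track.total:.6g}) to {path}",
            file=log,
        )


def read_bedgraph(path) -> GenomicTrack:
    """Read a bedGraph written by :func:`write_bedgraph`."""
    sample, scheme, normalisation = "sample", "fixed", "raw"
    starts: list[int] = []
    ends: list[int] = []
    scores: list[float] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("track"):
                desc = line.split('description="', 1)
                if len(desc) == 2:
                    for token in desc[1].split('"', 1)[0].split(";"):
                        key, _, value = token.partition("=")
                        if key == "sample":
                            sample = value
                        elif key == "scheme":
                            scheme = value
                        elif key == "normalisation":
                            normalisation = value
                continue
            if not line:
                continue
            _, start, end, score = line.split("\t")
            starts.append(int(start))
            ends.append(int(end))
            scores.append(float(score))
    return GenomicTrack(
        sample_name=sample,
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        scores=np.asarray(scores, dtype=float),
        scheme=scheme,
        normalisation=normalisation,
    )
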