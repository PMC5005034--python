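"""In-silico restriction digestion and bait (viewpoint) localisation.

A 4C-seq experiment reads out contacts between one "bait" restriction
fragment and the rest of the genome.  Everything downstream of the raw
reads is defined in fragment coordinates, so the first step of any
analysis is to reconstruct the restriction fragment map of the reference
by scanning for the recognition motif of the primary enzyme (NlaIII,
``CATG``, in the protocol this package models; DpnII, ``GATC``, is the
secondary enzyme used only inside the bait fragment).

Coordinate convention: a cut is placed at the *end* of every motif
occurrence, so each internal fragment carries the motif at its 3'
terminus (NlaIII leaves CATG on the upstream fragment).  The same
convention is applied to both enzymes; what matters downstream is that
digestion, read simulation and read assignment agree on it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RestrictionFragmentMap",
    "BaitDescriptor",
    "digest",
    "locate_bait",
    "write_fragment_bed",
    "read_fragment_bed",
]

_VALID_MOTIF = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class RestrictionFragmentMap:
    """Ordered, non-overlapping fragments tiling ``[0, sequence_length)``.

    ``starts``/``ends`` are parallel int arrays of 0-based half-open
    intervals; fragment ``i`` ends where fragment ``i + 1`` starts.
    """

    starts: np.ndarray
    ends: np.ndarray
    sequence_length: int

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.size == 0:
            raise ValueError("fragment map must contain at least one fragment")
        if starts.size != ends.size:
            raise ValueError("starts and ends differ in length")
        if np.any(starts >= ends):
            raise ValueError("every fragment needs start < end")
        if starts[0] != 0 or ends[-1] != self.sequence_length:
            raise ValueError("fragments must tile [0, sequence_length)")
        if np.any(starts[1:] != ends[:-1]):
            raise ValueError("fragments must be contiguous")

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def locate(self, position: int) -> int:
        """Index of the fragment whose half-open interval contains ``position``."""
        if not 0 <= position < self.sequence_length:
            raise ValueError(
                f"position {position} outside [0, {self.sequence_length})"
            )
        return int(np.searchsorted(self.ends, position, side="right"))

    def fragment_sequence(self, reference: str, index: int) -> str:
        return reference[int(self.starts[index]) : int(self.ends[index])]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RestrictionFragmentMap):
            return NotImplemented
        return (
            self.sequence_length == other.sequence_length
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )


@dataclass(frozen=True)
class BaitDescriptor:
    """The bait fragment and its boundary-sharing neighbours.

    The neighbours matter because reads landing there are the signature
    of failed digestion (the read runs straight through the uncut site),
    while reads landing on the bait itself indicate self-ligation; both
    are removed before quantitation.
    """

    bait_fragment_index: int
    adjacent_fragment_indices: frozenset[int] = field(default_factory=frozenset)


def digest(sequence: str, motif: str) -> RestrictionFragmentMap:
    """Cut ``sequence`` at the end of every ``motif`` occurrence.

    Overlapping occurrences are scanned left to right and each produces
    a cut.  Ambiguity codes (``N`` etc.) never match.  Concatenating the
    fragment sequences reconstructs the input exactly.
    """
    if not motif or not _VALID_MOTIF.match(motif):
        raise ValueError(f"motif must be non-empty uppercase A/C/G/T, got {motif!r}")
    if len(sequence) < len(motif):
        raise ValueError("sequence shorter than motif")
    # lookahead so overlapping occurrences each yield a cut
    cut_re = re.compile(f"(?={re.escape(motif)})")
    cuts = [m.start() + len(motif) for m in cut_re.finditer(sequence)]
    bounds = [0] + [c for c in cuts if c < len(sequence)] + [len(sequence)]
    bounds = sorted(set(bounds))
    starts = np.asarray(bounds[:-1], dtype=np.int64)
    ends = np.asarray(bounds[1:], dtype=np.int64)
    return RestrictionFragmentMap(starts=starts, ends=ends, sequence_length=len(sequence))


def locate_bait(fragment_map: RestrictionFragmentMap, bait_position: int) -> BaitDescriptor:
    """Find the fragment containing ``bait_position`` and its neighbours."""
    idx = fragment_map.locate(bait_position)
    adjacent = {i for i in (idx - 1, idx + 1) if 0 <= i < len(fragment_map)}
    return BaitDescriptor(
        bait_fragment_index=idx,
        adjacent_fragment_indices=frozenset(adjacent),
    )


def write_fragment_bed(
    fragment_map: RestrictionFragmentMap, path, chrom_name: str = "chrS"
) -> None:
    """Serialise the map as sorted BED3 (0-based half-open)."""
    with open(path, "w") as handle:
        for start, end in zip(fragment_map.starts, fragment_map.ends):
            handle.write(f"{chrom_name}\t{start}\t{end}\n")


def read_fragment_bed(path) -> RestrictionFragmentMap:
    """Read a BED3 fragment map written by :func:`write_fragment_bed`."""
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            _, start, end = line.split("\t")[:3]
            starts.append(int(start))
            ends.append(int(end))
    if not starts:
        raise ValueError(f"no fragments in {path}")
    return RestrictionFragmentMap(
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        sequence_length=ends[-1],
    )
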