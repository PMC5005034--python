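"""Demultiplexing, bait trimming, fragment assignment and viewpoint filtering.

This module turns raw inline-barcoded 4C reads into per-fragment count
vectors, reproducing the bookkeeping a 4C extraction script performs:

1. ``demultiplex`` — split reads by their inline barcode prefix and
   strip the barcode.
2. ``trim_bait`` — every informative read begins with the bait
   fragment's 3'-end segment (terminating in the primary-enzyme motif);
   remove it, keeping only the captured sequence.  Reads without the
   bait structure are discarded as non-bait.
3. ``assign_reads`` — map each captured sequence to a unique restriction
   fragment.  The internal assigner requires an exact, unique match of
   the read's first ``min_match_length`` bases against the fragment
   start sequences — an explicit form of the "uniquely mapping reads
   only" contract that aligner MAPQ thresholds realise on real data.
   ``assign_sam`` applies the literal MAPQ >= 42 filter to externally
   aligned reads instead.
4. ``filter_bait_proximal`` — zero the bait (self-ligation) and
   bait-adjacent (undigested) fragments, recording what was removed.

Every read is accounted for exactly once across the categories
(assigned / bad barcode / non-bait / unmapped / ambiguous / filtered).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fragment_map import BaitDescriptor, RestrictionFragmentMap
from .synthetic_data import BarcodeSpec, ReadRecord

__all__ = [
    "DemuxResult",
    "FragmentCountVector",
    "demultiplex",
    "trim_bait",
    "trim_bait_reads",
    "assign_reads",
    "assign_sam",
    "filter_bait_proximal",
    "write_counts_tsv",
    "read_counts_tsv",
]


@dataclass
class DemuxResult:
    """Reads split by sample, with the barcode prefix stripped."""

    per_sample: dict[str, list[ReadRecord]]
    unassigned: list[ReadRecord]

    @property
    def per_sample_counts(self) -> dict[str, int]:
        return {s: len(reads) for s, reads in self.per_sample.items()}

    @property
    def total(self) -> int:
        return sum(len(r) for r in self.per_sample.values()) + len(self.unassigned)


@dataclass
class FragmentCountVector:
    """Per-fragment read counts for one sample, with filtering tallies."""

    sample_name: str
    counts: np.ndarray
    n_filtered_undigested: int = 0
    n_filtered_self: int = 0
    n_unmapped: int = 0
    n_ambiguous: int = 0
    n_non_bait: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("fragment counts must be non-negative")

    @property
    def total_assigned(self) -> int:
        return int(self.counts.sum())


def _check_barcodes(barcode_table: list[BarcodeSpec]) -> None:
    names = [b.sample_name for b in barcode_table]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names in barcode table")
    seqs = [b.barcode for b in barcode_table]
    for i, a in enumerate(seqs):
        for b in seqs[i + 1 :]:
            if a.startswith(b) or b.startswith(a):
                raise ValueError(
                    f"barcodes {a!r} and {b!r} are prefix-nested; demultiplexing would be ambiguous"
                )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: list[ReadRecord],
    barcode_table: list[BarcodeSpec],
    max_mismatches: int = 0,
) -> DemuxResult:
    """Assign each read to the unique nearest barcode and strip it.

    A read goes to sample *s* iff its prefix matches *s*'s barcode within
    ``max_mismatches`` and strictly closer than every other barcode;
    ties and non-matches land in ``unassigned``.
    """
    _check_barcodes(barcode_table)
    per_sample: dict[str, list[ReadRecord]] = {b.sample_name: [] for b in barcode_table}
    unassigned: list[ReadRecord] = []

    if max_mismatches == 0:
        exact = {b.barcode: b.sample_name for b in barcode_table}
        lengths = sorted({len(b.barcode) for b in barcode_table})
        for read in reads:
            for length in lengths:
                sample = exact.get(read.sequence[:length])
                if sample is not None:
                    per_sample[sample].append(
                        ReadRecord(read.read_id, read.sequence[length:])
                    )
                    break
            else:
                unassigned.append(read)
        return DemuxResult(per_sample=per_sample, unassigned=unassigned)

    for read in reads:
        scored = [
            (_hamming(read.sequence[: len(b.barcode)], b.barcode), b)
            for b in barcode_table
        ]
        scored.sort(key=lambda t: t[0])
        best_d, best = scored[0]
        tie = len(scored) > 1 and scored[1][0] == best_d
        if best_d <= max_mismatches and not tie:
            per_sample[best.sample_name].append(
                ReadRecord(read.read_id, read.sequence[len(best.barcode) :])
            )
        else:
            unassigned.append(read)
    return DemuxResult(per_sample=per_sample, unassigned=unassigned)


def trim_bait(read: ReadRecord, bait_end_sequence: str, primary_motif: str = "CATG") -> ReadRecord | None:
    """Strip the bait-end segment; ``None`` flags a non-bait read.

    ``bait_end_sequence`` must terminate in the primary motif — the
    captured sequence begins immediately after the restriction site.
    """
    if not bait_end_sequence.endswith(primary_motif):
        raise ValueError("bait_end_sequence must end in the primary motif")
    if read.sequence.startswith(bait_end_sequence):
        return ReadRecord(read.read_id, read.sequence[len(bait_end_sequence) :])
    return None


def trim_bait_reads(
    reads: list[ReadRecord], bait_end_sequence: str, primary_motif: str = "CATG"
) -> tuple[list[ReadRecord], int]:
    """Trim a whole library; returns (trimmed reads, n_non_bait)."""
    if not bait_end_sequence.endswith(primary_motif):
        raise ValueError("bait_end_sequence must end in the primary motif")
    n = len(bait_end_sequence)
    trimmed: list[ReadRecord] = []
    n_non_bait = 0
    for read in reads:
        if read.sequence.startswith(bait_end_sequence):
            trimmed.append(ReadRecord(read.read_id, read.sequence[n:]))
        else:
            n_non_bait += 1
    return trimmed, n_non_bait


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _fragment_key_index(
    fragment_map: RestrictionFragmentMap,
    reference: str,
    min_match_length: int,
    both_ends: bool,
) -> dict[str, int]:
    """k-mer -> fragment index; collisions map to -1 (ambiguous).

    Keys are the genomic ``min_match_length``-mers beginning at each
    fragment start (running past the fragment's own end when it is
    shorter), mirroring aligner semantics: a read whose alignment starts
    at a fragment start belongs to that fragment.
    """
    index: dict[str, int] = {}
    length = fragment_map.sequence_length

    def add(key: str, frag: int) -> None:
        if key in index and index[key] != frag:
            index[key] = -1
        else:
            index.setdefault(key, frag)

    for i, (start, end) in enumerate(zip(fragment_map.starts, fragment_map.ends)):
        start, end = int(start), int(end)
        if start + min_match_length <= length:
            add(reference[start : start + min_match_length], i)
        if both_ends and end - min_match_length >= 0:
            tail = reference[end - min_match_length : end]
            add(tail.translate(_COMPLEMENT)[::-1], i)
    return index


def assign_reads(
    trimmed_reads: list[ReadRecord],
    fragment_map: RestrictionFragmentMap,
    reference: str,
    min_match_length: int = 20,
    sample_name: str = "sample",
    both_ends: bool = False,
) -> FragmentCountVector:
    """Unique-prefix assignment of trimmed reads to fragments.

    A read increments exactly one fragment count iff its first
    ``min_match_length`` bases equal the genomic sequence beginning at
    exactly one fragment start (with ``both_ends`` additionally at the
    reverse-complemented end of a fragment, for real libraries captured
    from either strand).  Reads shorter than ``min_match_length`` are
    unmapped; prefixes matching more than one fragment are ambiguous.
    """
    if min_match_length <= 0:
        raise ValueError("min_match_length must be positive")
    index = _fragment_key_index(fragment_map, reference, min_match_length, both_ends)
    counts = np.zeros(len(fragment_map), dtype=np.int64)
    n_unmapped = 0
    n_ambiguous = 0
    for read in trimmed_reads:
        if len(read.sequence) < min_match_length:
            n_unmapped += 1
            continue
        frag = index.get(read.sequence[:min_match_length])
        if frag is None:
            n_unmapped += 1
        elif frag == -1:
            n_ambiguous += 1
        else:
            counts[frag] += 1
    return FragmentCountVector(
        sample_name=sample_name,
        counts=counts,
        n_unmapped=n_unmapped,
        n_ambiguous=n_ambiguous,
    )


def assign_sam(
    sam_path,
    fragment_map: RestrictionFragmentMap,
    sample_name: str = "sample",
    min_mapq: int = 42,
) -> FragmentCountVector:
    """External-aligner path: count alignments per containing fragment.

    Keeps only mapped reads with ``MAPQ >= min_mapq`` (the uniqueness
    contract as realised by bowtie2 scores) and assigns each by its
    alignment start coordinate.
    """
    import pysam

    counts = np.zeros(len(fragment_map), dtype=np.int64)
    n_unmapped = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.mapping_quality < min_mapq:
                n_unmapped += 1
                continue
            pos = aln.reference_start
            if not 0 <= pos < fragment_map.sequence_length:
                n_unmapped += 1
                continue
            counts[fragment_map.locate(pos)] += 1
    return FragmentCountVector(
        sample_name=sample_name, counts=counts, n_unmapped=n_unmapped
    )


def filter_bait_proximal(
    count_vector: FragmentCountVector, bait: BaitDescriptor
) -> FragmentCountVector:
    """Remove self-ligation (bait) and undigested (bait-adjacent) counts.

    The removed reads are tallied separately; all other counts are
    untouched.  Idempotent.
    """
    n = len(count_vector.counts)
    if not 0 <= bait.bait_fragment_index < n or any(
        not 0 <= a < n for a in bait.adjacent_fragment_indices
    ):
        raise ValueError("bait descriptor inconsistent with the count vector")
    counts = count_vector.counts.copy()
    n_self = int(counts[bait.bait_fragment_index])
    counts[bait.bait_fragment_index] = 0
    n_undig = 0
    for adj in bait.adjacent_fragment_indices:
        n_undig += int(counts[adj])
        counts[adj] = 0
    return replace(
        count_vector,
        counts=counts,
        n_filtered_self=count_vector.n_filtered_self + n_self,
        n_filtered_undigested=count_vector.n_filtered_undigested + n_undig,
    )


def write_counts_tsv(count_vector: FragmentCountVector, path) -> None:
    """``fragment_index<TAB>count`` with a commented accounting header."""
    with open(path, "w") as handle:
        handle.write(
            "# sample={0}\tfiltered_undigested={1}\tfiltered_self={2}\t"
            "unmapped={3}\tambiguous={4}\tnon_bait={5}\n".format(
                count_vector.sample_name,
                count_vector.n_filtered_undigested,
                count_vector.n_filtered_self,
                count_vector.n_unmapped,
                count_vector.n_ambiguous,
                count_vector.n_non_bait,
            )
        )
        for i, c in enumerate(count_vector.counts):
            handle.write(f"{i}\t{c}\n")


def read_counts_tsv(path) -> FragmentCountVector:
    meta = {"sample": "sample"}
    counts: list[int] = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#"):
                for token in line[1:].strip().split("\t"):
                    key, _, value = token.partition("=")
                    meta[key] = value
                continue
            idx, count = line.split("\t")
            assert int(idx) == len(counts), "counts TSV must be dense and ordered"
            counts.append(int(count))
    return FragmentCountVector(
        sample_name=meta["sample"],
        counts=np.asarray(counts, dtype=np.int64),
        n_filtered_undigested=int(meta.get("filtered_undigested", 0)),
        n_filtered_self=int(meta.get("filtered_self", 0)),
        n_unmapped=int(meta.get("unmapped", 0)),
        n_ambiguous=int(meta.get("ambiguous", 0)),
        n_non_bait=int(meta.get("non_bait", 0)),
    )
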