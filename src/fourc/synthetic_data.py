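"""Synthetic 4C-seq data with known ground truth.

The generator emulates the data a double-digestion 4C protocol produces:
a genome carrying primary (NlaIII, ``CATG``) and secondary (DpnII,
``GATC``) restriction sites, a bait fragment spanning the viewpoint, and
single-end reads of the inverse-PCR structure

    [inline barcode][bait-end segment ending in CATG][captured fragment]

where the captured fragment is drawn from a per-fragment contact
distribution with power-law distance decay, optionally perturbed by
condition-specific fold changes at designated enhancer regions.  A
tunable fraction of reads is undigested (reads straight through the
uncut bait-end site into the adjacent fragment) and another fraction is
bait self-ligation; these are what the pipeline's bait-proximal filter
must remove.  Every read is recorded in a truth table so recovery can
be checked exactly.

The model deliberately omits PCR duplicates, sequencing errors and
chimeric junctions; see docs/methods.md for what that implies.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .fragment_map import BaitDescriptor, RestrictionFragmentMap, digest, locate_bait

__all__ = [
    "SimulationConfig",
    "EnhancerFold",
    "BarcodeSpec",
    "InteractionProfile",
    "SyntheticReference",
    "ReadRecord",
    "generate_reference",
    "build_profile",
    "simulate_reads",
    "simulate_qpcr_table",
]

# distance from the common-reverse-primer stand-in to the start of the
# primary motif at the bait fragment's 3' end
BAIT_TAIL_BASES = 20

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ReadRecord(NamedTuple):
    """A single-end read; quality is constant ('I', Q40) by construction."""

    read_id: str
    sequence: str


@dataclass(frozen=True)
class EnhancerFold:
    """A condition-specific contact fold change planted on a genomic interval.

    The fold multiplies the pre-normalisation contact weight of every
    fragment overlapping ``[start, end)``.  A point interval
    (``end = start + 1``) selects the single fragment containing
    ``start``, which is how an individual enhancer fragment is designated.
    Folds > 1 model gained enhancer contacts, folds < 1 model regions
    looped away from the viewpoint.
    """

    start: int
    end: int
    condition: str
    fold: float

    @classmethod
    def at_position(cls, position: int, condition: str, fold: float) -> "EnhancerFold":
        return cls(start=position, end=position + 1, condition=condition, fold=fold)

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold multipliers must be > 0")
        if self.start >= self.end:
            raise ValueError("fold interval must satisfy start < end")


@dataclass(frozen=True)
class BarcodeSpec:
    sample_name: str
    barcode: str

    def __post_init__(self) -> None:
        if not self.barcode or set(self.barcode) - set("ACGT"):
            raise ValueError(f"barcode must be non-empty A/C/G/T, got {self.barcode!r}")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic 4C study.

    Defaults mirror the modelled protocol where it pins them down
    (100 bp single-end reads; CATG/GATC motifs) and otherwise sit at
    values typical of 4C libraries (see docs/methods.md).
    """

    sequence_length: int = 100_000
    primary_motif: str = "CATG"
    secondary_motif: str = "GATC"
    bait_position: int = 50_000
    decay_exponent: float = 1.0
    enhancer_folds: Sequence[EnhancerFold] = field(default_factory=tuple)
    undigested_fraction: float = 0.1
    self_ligation_fraction: float = 0.05
    reads_per_sample: int = 100_000
    read_length: int = 100
    min_capture_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.undigested_fraction + self.self_ligation_fraction <= 1.0:
            raise ValueError("undigested + self-ligation fractions must lie in [0, 1]")
        if not (0.0 <= self.undigested_fraction and 0.0 <= self.self_ligation_fraction):
            raise ValueError("mixture fractions must be non-negative")
        if not 0 <= self.bait_position < self.sequence_length:
            raise ValueError("bait_position must lie inside the sequence")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        for entry in self.enhancer_folds:
            if entry.fold <= 0:
                raise ValueError("all enhancer folds must be > 0")


@dataclass(frozen=True)
class InteractionProfile:
    """Ground-truth per-fragment contact probabilities for one condition.

    Probabilities sum to 1; the bait and its adjacent fragments carry 0
    (their reads are, by definition, self-ligation or undigested — the
    categories the mixture fractions control separately).
    """

    condition_label: str
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", probs)
        if np.any(probs < 0):
            raise ValueError("contact probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("contact probabilities must sum to 1")


@dataclass(frozen=True)
class SyntheticReference:
    """A generated reference with its primary-digest map and bait."""

    sequence: str
    fragment_map: RestrictionFragmentMap
    bait: BaitDescriptor

    @property
    def bait_fragment_index(self) -> int:
        return self.bait.bait_fragment_index

    def bait_end_sequence(self, primary_motif: str = "CATG") -> str:
        """Bait-fragment 3'-terminal sequence every valid read starts with.

        Spans from the reverse-primer stand-in (:data:`BAIT_TAIL_BASES`
        upstream of the terminal motif) through the motif itself,
        mirroring inverse-PCR geometry.
        """
        fmap = self.fragment_map
        i = self.bait.bait_fragment_index
        end = int(fmap.ends[i])
        start = max(int(fmap.starts[i]), end - BAIT_TAIL_BASES - len(primary_motif))
        return self.sequence[start:end]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_reference(config: SimulationConfig) -> SyntheticReference:
    """Seeded uniform-random reference satisfying the motif guarantees.

    Guarantees ≥ 20 primary-motif occurrences genome-wide and ≥ 1
    secondary-motif occurrence inside the bait fragment (the protocol's
    second digestion happens there).  Identical seeds give identical
    sequences; the guarantee is sought over a bounded number of seeded
    retries, each a deterministic function of ``config.seed``.
    """
    if config.sequence_length < 10 * config.read_length:
        raise ValueError("sequence_length must be at least 10 x read_length")
    for attempt in range(50):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, attempt, 0x4C])
        )
        seq = _random_sequence(rng, config.sequence_length)
        fmap = digest(seq, config.primary_motif)
        if len(fmap) < 21:  # 20 occurrences => 21 fragments
            continue
        bait = locate_bait(fmap, config.bait_position)
        bait_seq = fmap.fragment_sequence(seq, bait.bait_fragment_index)
        if config.secondary_motif not in bait_seq:
            continue
        return SyntheticReference(sequence=seq, fragment_map=fmap, bait=bait)
    raise RuntimeError(
        "could not generate a reference meeting the motif guarantees in 50 attempts; "
        "increase sequence_length"
    )


def build_profile(
    fragment_map: RestrictionFragmentMap,
    config: SimulationConfig,
    condition_label: str,
    bait: BaitDescriptor | None = None,
) -> InteractionProfile:
    """Contact probabilities for one condition.

    Baseline weight of fragment *i* is ``(1 + |mid(i) - mid(bait)|) ** -a``
    with *a* the decay exponent; each fold entry for ``condition_label``
    multiplies the weights of the fragments its interval overlaps;
    weights at the bait, at bait-adjacent fragments, and at fragments
    shorter than ``min_capture_length`` are forced to 0; the result is
    renormalised to sum to 1.
    """
    if bait is None:
        bait = locate_bait(fragment_map, config.bait_position)
    mids = fragment_map.midpoints
    bait_mid = mids[bait.bait_fragment_index]
    weights = (1.0 + np.abs(mids - bait_mid)) ** (-config.decay_exponent)

    weights[bait.bait_fragment_index] = 0.0
    for adj in bait.adjacent_fragment_indices:
        weights[adj] = 0.0
    weights[fragment_map.lengths < config.min_capture_length] = 0.0

    for entry in config.enhancer_folds:
        if entry.condition != condition_label:
            continue
        overlap = (fragment_map.starts < entry.end) & (fragment_map.ends > entry.start)
        if not overlap.any():
            raise ValueError(
                f"enhancer fold interval [{entry.start}, {entry.end}) overlaps no fragment"
            )
        weights[overlap] *= entry.fold

    total = weights.sum()
    if total <= 0:
        raise ValueError("all contact weights are zero; nothing to simulate")
    return InteractionProfile(condition_label=condition_label, probabilities=weights / total)


def _sample_rng(config: SimulationConfig, sample_name: str, condition: str) -> np.random.Generator:
    # stable per-(seed, sample, condition) stream so libraries differ but rerun identically
    key = zlib.crc32(f"{sample_name}|{condition}".encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def simulate_reads(
    reference: SyntheticReference,
    fragment_map: RestrictionFragmentMap,
    profile: InteractionProfile,
    barcode: BarcodeSpec,
    config: SimulationConfig,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Emit one sample's reads plus their ground-truth assignment table.

    Each read is ``barcode + bait-end segment + captured sequence``,
    truncated (or 'A'-padded when the captured fragment is exhausted) to
    ``read_length``.  Category mixture: ``undigested_fraction`` of reads
    read straight through the uncut bait-end site into the genomic
    sequence of the adjacent fragment, ``self_ligation_fraction``
    recapture the bait fragment, the remainder are contacts drawn from
    ``profile``.
    The truth table has columns read_id, sample, fragment_index, category.
    """
    if len(profile.probabilities) != len(fragment_map):
        raise ValueError("profile and fragment map disagree on fragment count")
    bait_end = reference.bait_end_sequence(config.primary_motif)
    prefix = barcode.barcode + bait_end
    captured_span = config.read_length - len(prefix)
    if captured_span <= 0:
        raise ValueError("read_length shorter than barcode + bait-end segment")

    n = config.reads_per_sample
    columns = {"read_id": [], "sample": [], "fragment_index": [], "category": []}
    if n == 0:
        return [], pd.DataFrame(columns)

    bait_idx = reference.bait.bait_fragment_index
    # read-through continues downstream of the bait end; fall back to the
    # upstream neighbour only when the bait is the terminal fragment
    if bait_idx + 1 < len(fragment_map):
        undigested_idx = bait_idx + 1
        undigested_from = int(fragment_map.starts[undigested_idx])
    elif bait_idx - 1 >= 0:
        undigested_idx = bait_idx - 1
        undigested_from = int(fragment_map.starts[undigested_idx])
    else:
        undigested_idx = bait_idx
        undigested_from = int(fragment_map.starts[bait_idx])

    rng = _sample_rng(config, barcode.sample_name, profile.condition_label)
    u = rng.random(n)
    is_undig = u < config.undigested_fraction
    is_self = (~is_undig) & (
        u < config.undigested_fraction + config.self_ligation_fraction
    )
    is_contact = ~(is_undig | is_self)

    frag_idx = np.empty(n, dtype=np.int64)
    frag_idx[is_undig] = undigested_idx
    frag_idx[is_self] = bait_idx
    n_contact = int(is_contact.sum())
    if n_contact:
        frag_idx[is_contact] = rng.choice(
            len(fragment_map), size=n_contact, p=profile.probabilities
        )

    category = np.where(
        is_undig, "undigested", np.where(is_self, "self_ligation", "contact")
    )

    # captured sequence depends only on (fragment, category): precompute
    seq = reference.sequence
    starts, ends = fragment_map.starts, fragment_map.ends
    cache: dict[tuple[int, bool], str] = {}

    def read_for(f: int, undigested: bool) -> str:
        try:
            return cache[f, undigested]
        except KeyError:
            if undigested:
                # no cut at the bait end: pure genomic read-through
                captured = seq[undigested_from : undigested_from + captured_span]
            else:
                captured = seq[
                    int(starts[f]) : min(int(ends[f]), int(starts[f]) + captured_span)
                ]
            full = (prefix + captured).ljust(config.read_length, "A")
            cache[f, undigested] = full
            return full

    sample = barcode.sample_name
    read_ids = [f"{sample}:{i}" for i in range(n)]
    reads = [
        ReadRecord(rid, read_for(int(f), bool(u)))
        for rid, f, u in zip(read_ids, frag_idx, is_undig)
    ]
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "sample": sample,
            "fragment_index": frag_idx,
            "category": category,
        }
    )
    return reads, truth


def simulate_qpcr_table(
    true_quantities: dict[str, float] | Iterable[tuple[str, float]],
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Ct values from known quantities under a log-linear standard curve.

    ``Ct = intercept + slope * log10(quantity) + Normal(0, noise_sd)``.
    """
    items = list(true_quantities.items()) if isinstance(true_quantities, dict) else list(true_quantities)
    quantities = np.array([q for _, q in items], dtype=float)
    if np.any(quantities <= 0):
        raise ValueError("all quantities must be > 0")
    rng = np.random.default_rng(seed)
    ct = intercept + slope * np.log10(quantities)
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, size=ct.size)
    return pd.DataFrame(
        {"target": [t for t, _ in items], "quantity": quantities, "ct": ct}
    )
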