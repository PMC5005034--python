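"""Reference simulation studies used to validate the pipeline end to end.

The central validation is differential fold-change recovery: two
conditions are simulated on the same reference, condition B carrying
planted contact fold changes at window-sized enhancer regions (gains of
2-, 3- and 5-fold and one 0.5-fold "looped-out" region), each sample
sequenced to a fixed depth.  The full pipeline — demultiplex, trim,
assign, bait-filter, fixed windows, max-library normalisation,
subtraction — is then run and the window-score ratio B/A at each
planted region compared with the planted fold.

The planted regions span whole track windows because that is the scale
at which real enhancer and super-enhancer peaks manifest in viewpoint
tracks; a planted region much smaller than a window would be averaged
away by construction, regardless of the pipeline's correctness.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import process_library
from .quantitate import fixed_window_track, normalize_to_max_library, subtract_tracks
from .synthetic_data import (
    BarcodeSpec,
    EnhancerFold,
    SimulationConfig,
    build_profile,
    generate_reference,
    simulate_reads,
)

__all__ = ["RECOVERY_FOLDS", "RecoveryResult", "fold_recovery_replicate"]

# study conditions: 200 kb reference, central bait, 10 kb windows,
# window-aligned planted regions kept clear of the bait's own window
RECOVERY_GENOME = 200_000
RECOVERY_BAIT = 100_000
RECOVERY_WINDOW = 10_000
RECOVERY_FOLDS = (
    (30_000, 2.0),
    (140_000, 3.0),
    (150_000, 5.0),
    (40_000, 0.5),  # looped-out analogue: contacts lost in condition B
)


@dataclass(frozen=True)
class RecoveryResult:
    """Per-replicate outcome: planted fold -> (measured ratio, difference sign ok)."""

    seed: int
    ratios: dict[float, float]
    sign_correct: dict[float, bool]


def fold_recovery_replicate(
    seed: int, reads_per_sample: int = 200_000
) -> RecoveryResult:
    """Run one seeded two-condition replicate through the whole pipeline."""
    folds = tuple(
        EnhancerFold(start, start + RECOVERY_WINDOW, "B", fold)
        for start, fold in RECOVERY_FOLDS
    )
    config = SimulationConfig(
        sequence_length=RECOVERY_GENOME,
        bait_position=RECOVERY_BAIT,
        enhancer_folds=folds,
        undigested_fraction=0.1,
        self_ligation_fraction=0.05,
        reads_per_sample=reads_per_sample,
        seed=seed,
    )
    reference = generate_reference(config)
    fmap = reference.fragment_map
    barcodes = {"A": BarcodeSpec("A", "ACGTGG"), "B": BarcodeSpec("B", "TGCACC")}
    tracks = {}
    for condition, spec in barcodes.items():
        profile = build_profile(fmap, config, condition, reference.bait)
        reads, _ = simulate_reads(reference, fmap, profile, spec, config)
        result = process_library(
            reads,
            [spec],
            reference.sequence,
            fmap,
            reference.bait,
            reference.bait_end_sequence(config.primary_motif),
        )
        tracks[condition] = fixed_window_track(
            result.count_vectors[condition], fmap, RECOVERY_WINDOW
        )
    track_a, track_b = normalize_to_max_library([tracks["A"], tracks["B"]])
    difference = subtract_tracks(track_b, track_a)
    ratios: dict[float, float] = {}
    sign_correct: dict[float, bool] = {}
    for start, fold in RECOVERY_FOLDS:
        window = start // RECOVERY_WINDOW
        ratios[fold] = float(track_b.scores[window] / track_a.scores[window])
        sign_correct[fold] = bool((difference.scores[window] > 0) == (fold > 1.0))
    return RecoveryResult(seed=seed, ratios=ratios, sign_correct=sign_correct)
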