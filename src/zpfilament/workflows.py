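"""Canonical parameter-recovery workflows on synthetic study conditions.

Each function generates the synthetic inputs at the study's stated
conditions (sample sizes, signal-to-noise, geometry), runs the relevant
estimator blind, and returns its result together with the ground truth.
They exist so that the test suite, the analysis scripts and the
acceptance harness all exercise exactly the same conditions through one
code path.

Problem sizes are desk-scale by design: the segment-stack recovery uses
~200 projection segments of a 400 Å box sampled at 3.125 Å/px (the
published reconstruction pooled hundreds of thousands of 400 px
segments; the windowed-search protocol itself is what is reproduced
here, and it was run on a topology-analysis subset in the original work
too).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .helix import HelicalSymmetry
from .lattice import correlation_average_pipeline
from .repeats import RepeatEstimate, aggregate_repeats
from .search import (SearchConsensus, SearchProtocol, TemplateScorer,
                     windowed_search)
from .synthetic import (ImageStack, SheetSpec, default_filament_model,
                        make_repeat_filament_image, make_sheet_image,
                        project_segments, render_filament_volume,
                        umod_like_unit)

__all__ = [
    "make_recovery_stack",
    "run_symmetry_recovery",
    "run_repeat_recovery",
    "run_sheet_recovery",
]


def make_recovery_stack(
    seed: int,
    rise_angstrom: float = 62.5,
    twist_degrees: float = 180.0,
    n_segments: int = 200,
    image_px: int = 128,
    pixel_size_angstrom: float = 3.125,
    snr: float = 0.5,
) -> ImageStack:
    """Noisy projection stack of a branch-decorated filament.

    View angles are uniform over 360°, axial offsets uniform over one
    rise; the noise standard deviation is set from the noiseless stack to
    the requested SNR (signal sd / noise sd).
    """
    sym = HelicalSymmetry(rise_angstrom, twist_degrees)
    model = default_filament_model(sym)
    vol = render_filament_volume(
        model, pixel_size_angstrom, image_px * pixel_size_angstrom
    )
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 360.0, n_segments)
    offsets = rng.uniform(-rise_angstrom / 2, rise_angstrom / 2, n_segments)
    clean = project_segments(
        vol, pixel_size_angstrom, n_segments, angles, offsets, 0.0, 0
    )
    noise = float(clean.images.std()) / snr if snr > 0 else 0.0
    return project_segments(
        vol, pixel_size_angstrom, n_segments, angles, offsets, noise, seed
    )


def run_symmetry_recovery(
    seed: int,
    n_segments: int = 200,
    snr: float = 0.5,
    n_score_segments: int = 128,
    n_angles: int = 24,
    protocol: SearchProtocol | None = None,
) -> tuple[SearchConsensus, dict]:
    """Blind windowed twist/rise search on a synthetic stack.

    The stack is generated at the full-length uromodulin symmetry
    (62.5 Å, 180°); the search runs the published protocol (160–200°,
    60–70 Å, ±5°/±2.5 Å windows, 50% overlap, halving to ±0.5°/±0.25 Å)
    with the template scorer, blind to the truth.
    """
    truth = {"rise_angstrom": 62.5, "twist_degrees": 180.0}
    stack = make_recovery_stack(
        seed, truth["rise_angstrom"], truth["twist_degrees"],
        n_segments=n_segments, snr=snr,
    )
    if protocol is None:
        protocol = SearchProtocol()
    # score on 2x binned images: the blob size (~6 Å) makes finer sampling
    # pure cost, and binning equalizes the interpolation footprints of the
    # simulated-data and template rendering paths
    scorer = TemplateScorer(
        stack.binned(2), umod_like_unit(), n_angles=n_angles,
        n_segments=n_score_segments, seed=seed,
    )
    return windowed_search(protocol, scorer), truth


def run_repeat_recovery(
    seed: int,
    repeat_angstrom: float = 65.0,
    pixel_size_angstrom: float = 5.0,
    n_classes: int = 100,
    snr: float = 0.5,
) -> tuple[RepeatEstimate, dict]:
    """Repeat measurement over ~100 noisy synthetic filament classes."""
    probe = make_repeat_filament_image(
        repeat_angstrom, pixel_size_angstrom, noise_sigma=0.0, seed=0
    )
    noise = float(probe.std()) / snr if snr > 0 else 0.0
    rng = np.random.default_rng(seed)
    images = [
        make_repeat_filament_image(
            repeat_angstrom, pixel_size_angstrom, noise_sigma=noise,
            seed=int(rng.integers(2 ** 31)),
        )
        for _ in range(n_classes)
    ]
    est = aggregate_repeats(images, pixel_size_angstrom)
    return est, {"repeat_angstrom": repeat_angstrom,
                 "pixel_size_angstrom": pixel_size_angstrom}


def run_sheet_recovery(
    seed: int,
    size_px: int = 480,
    distortion_amplitude_px: float = 1.5,
    noise_rel: float = 1.0,
    resolution_limit_inv_angstrom: float = 1.0 / 14.0,
):
    """Correlation averaging + p2 phase residual on a noisy p2 sheet.

    The sheet covers ≥ 15 x 15 unit cells (480 px at 3 Å/px with a
    60 x 66 Å cell), carries a smooth 1.5 px rms distortion field and
    white noise with sd equal to the noiseless motif sd.
    """
    clean = make_sheet_image(SheetSpec(seed=seed), size_px)
    spec = SheetSpec(
        distortion_amplitude_px=distortion_amplitude_px,
        noise_sigma=noise_rel * float(clean.std()),
        seed=seed,
    )
    image = make_sheet_image(spec, size_px)
    average, report, lattice = correlation_average_pipeline(
        image, spec.pixel_size_angstrom,
        resolution_limit_inv_angstrom=resolution_limit_inv_angstrom,
    )
    return average, report, lattice, spec
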