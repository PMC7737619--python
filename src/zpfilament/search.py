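"""Helical twist/rise determination by exhaustive windowed search.

The protocol mirrors how helical parameters are determined in practice
when the twist is close to 180° and naive refinement fails: candidate
rises are seeded from the axial periodicity seen in the averaged power
spectrum of the segment images (``periodicity / n`` for integer ``n``),
then an exhaustive set of overlapping (twist, rise) windows tiling the
plausible ranges is refined independently. Within each window the score
is evaluated on a grid; when the optimum is interior the window is
re-centered on it and both the window and the step are halved, and when
the optimum sits on the window edge the window is shifted toward it at
constant width. A window whose optimum keeps running into the edge is
declared *edge-stuck* (not converged). The consensus is the modal
converged (twist, rise) across windows.

The score itself is a stated surrogate for full Bayesian helical
reconstruction: the mean best normalized cross-correlation between each
segment and noiseless projections of a candidate-symmetrized template
filament, maximized over axial shift and a bank of view angles. The
acceptance standard for the surrogate is parameter recovery on synthetic
stacks, not map quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .helix import HelicalSymmetry, PointSet, FilamentModel
from .synthetic import ImageStack, project_model

__all__ = [
    "SearchProtocol",
    "SearchResult",
    "SearchConsensus",
    "LayerLineEstimate",
    "average_power_spectrum",
    "estimate_layerline_periodicity",
    "TemplateScorer",
    "ShiftMirrorScorer",
    "symmetry_score",
    "windowed_search",
]


@dataclass
class SearchProtocol:
    """Configuration of the exhaustive windowed twist/rise search.

    Defaults follow the published protocol: ranges 160–200° and 60–70 Å,
    allowed windows of ±5° and ±2.5 Å, 50% overlapping windows, halving
    of window and step on interior optima, and terminal half-widths of
    ±0.5° and ±0.25 Å. The grid density within a window and the bound on
    edge shifts before a run is abandoned are implementation choices.
    """

    twist_range: tuple[float, float] = (160.0, 200.0)
    rise_range: tuple[float, float] = (60.0, 70.0)
    twist_half_width: float = 5.0
    rise_half_width: float = 2.5
    overlap: float = 0.5
    terminal_twist_half_width: float = 0.5
    terminal_rise_half_width: float = 0.25
    steps_per_window: int = 11
    max_shifts: int = 8
    max_iterations: int = 60

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if (self.terminal_twist_half_width > self.twist_half_width
                or self.terminal_rise_half_width > self.rise_half_width):
            raise ValueError("terminal half-widths must not exceed initial")
        if self.steps_per_window < 3:
            raise ValueError("need at least 3 grid steps per window")

    def window_centers(self) -> list[tuple[float, float]]:
        """Window centers tiling the ranges with the configured overlap."""
        def centers(lo, hi, hw):
            step = 2.0 * hw * (1.0 - self.overlap)
            c = lo + hw
            out = []
            while c <= hi - hw + 1e-9:
                out.append(round(c, 9))
                c += step
            if not out:
                out = [(lo + hi) / 2.0]
            return out

        tw = centers(*self.twist_range, self.twist_half_width)
        ri = centers(*self.rise_range, self.rise_half_width)
        return [(t, r) for t in tw for r in ri]


@dataclass
class SearchResult:
    """Outcome of one window refinement, with its full trajectory."""

    twist_degrees: float
    rise_angstrom: float
    score: float
    converged: bool
    edge_stuck: bool
    trajectory: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.edge_stuck and self.converged:
            raise ValueError("edge_stuck result cannot be converged")


@dataclass
class SearchConsensus:
    """Modal converged (twist, rise) across all windows."""

    twist_degrees: float
    rise_angstrom: float
    score: float
    n_supporting_windows: int
    n_converged: int
    n_edge_stuck: int
    handedness_ambiguous: bool
    results: list[SearchResult] = field(default_factory=list)

    @property
    def twist_magnitude_degrees(self) -> float:
        from .helix import normalize_twist
        return abs(normalize_twist(self.twist_degrees))


@dataclass
class LayerLineEstimate:
    """Axial periodicity read off the meridional power profile."""

    periodicity_angstrom: float
    peak_strength: float
    resolution_angstrom_per_sample: float

    def __post_init__(self) -> None:
        if self.periodicity_angstrom <= 0:
            raise ValueError("periodicity must be > 0")


# ---------------------------------------------------------------------------
# Power spectrum and layer lines
# ---------------------------------------------------------------------------

def average_power_spectrum(stack: ImageStack) -> np.ndarray:
    """Mean squared Fourier amplitude over the stack (DC centered).

    Segments are assumed rotationally pre-aligned with the filament axis
    vertical; each image has its mean removed before transforming.
    """
    imgs = stack.images
    spec = np.zeros(imgs.shape[1:])
    for img in imgs:
        f = np.fft.fftshift(np.fft.fft2(img - img.mean()))
        spec += np.abs(f) ** 2
    return spec / len(stack)


def estimate_layerline_periodicity(
    spectrum: np.ndarray,
    pixel_size_angstrom: float,
    min_snr: float = 5.0,
    band_width_px: Optional[int] = None,
) -> LayerLineEstimate:
    """Periodicity of the strongest off-origin meridional layer line.

    The power in each axial-frequency row is summed over a narrow band of
    columns around the meridian (layer-line intensity is concentrated
    there, so a narrow band keeps the white-noise background from
    swamping it); the strongest peak away from the origin gives the axial
    repeat as the reciprocal of its (parabolically refined) frequency.
    Raises when no peak rises ``min_snr`` times above the median profile
    level (no layer line).
    """
    h, w = spectrum.shape
    row0 = h // 2  # DC row after fftshift
    if band_width_px is None:
        band_width_px = max(5, h // 16)
    c0 = w // 2
    half_band = band_width_px // 2
    cols = slice(max(c0 - half_band, 0), min(c0 + half_band + 1, w))
    profile = spectrum[:, cols].sum(axis=1)
    # fold the two meridional halves; index = axial frequency in bins
    n = min(row0, h - row0 - 1)
    folded = profile[row0 + 1 : row0 + 1 + n] + profile[row0 - 1 :: -1][:n]
    if n < 3:
        raise ValueError("spectrum too small for layer-line analysis")
    # exclude the lowest frequency bin (residual background around DC)
    search = folded.copy()
    search[0] = 0.0
    floor = np.median(folded)
    peak_idx = int(np.argmax(search))
    strength = search[peak_idx] / floor if floor > 0 else np.inf
    if not np.isfinite(strength) or strength < min_snr:
        raise ValueError(
            "no off-origin layer line above the noise floor "
            f"(best peak {strength:.2f}x median, need {min_snr}x)"
        )
    # parabolic sub-bin refinement
    k = float(peak_idx)
    if 0 < peak_idx < n - 1:
        y0, y1, y2 = folded[peak_idx - 1], folded[peak_idx], folded[peak_idx + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            k += 0.5 * (y0 - y2) / denom
    freq_per_bin = 1.0 / (h * pixel_size_angstrom)
    periodicity = 1.0 / ((k + 1) * freq_per_bin)
    return LayerLineEstimate(
        periodicity_angstrom=periodicity,
        peak_strength=float(strength),
        resolution_angstrom_per_sample=h * pixel_size_angstrom,
    )


# ---------------------------------------------------------------------------
# Symmetry scorers
# ---------------------------------------------------------------------------

def _normalize(img: np.ndarray) -> np.ndarray:
    z = img - img.mean()
    nrm = np.linalg.norm(z)
    return z / nrm if nrm > 0 else z


class TemplateScorer:
    """Mean best cross-correlation against candidate-symmetrized templates.

    For a candidate (twist, rise), noiseless projections of the template
    filament are rendered at ``n_angles`` view angles; each segment is
    correlated with every reference over all axial shifts (segments are
    assumed laterally centered and rotationally aligned), and the best
    value per segment is averaged. The result lies in [-1, 1] and is
    invariant to global intensity scaling of the stack.

    A subset of segments may be used for speed; scores are memoized per
    candidate.
    """

    def __init__(
        self,
        stack: ImageStack,
        template_unit: PointSet,
        n_angles: int = 12,
        n_segments: Optional[int] = None,
        n_subunits: int = 11,
        blob_sigma_angstrom: float = 6.0,
        seed: int = 0,
    ) -> None:
        imgs = stack.images
        if len(imgs) == 0:
            raise ValueError("empty stack")
        if n_segments is not None and n_segments < len(imgs):
            rng = np.random.default_rng(seed)
            sel = rng.choice(len(imgs), size=n_segments, replace=False)
            imgs = imgs[np.sort(sel)]
        self.pixel_size = stack.pixel_size_angstrom
        self.shape = imgs.shape[1:]
        self.unit = template_unit
        self.n_angles = n_angles
        self.n_subunits = n_subunits
        self.blob_sigma = blob_sigma_angstrom
        # precompute segment FFTs along the axial (row) axis
        segs = np.stack([_normalize(i) for i in imgs])
        self._seg_fft_conj = np.conj(np.fft.rfft(segs, axis=1))  # (N, Hf, W)
        self._cache: dict[tuple[float, float], float] = {}

    def _references(self, sym: HelicalSymmetry) -> np.ndarray:
        model = FilamentModel(
            asymmetric_unit=self.unit, symmetry=sym, n_subunits=self.n_subunits
        )
        angles = np.arange(self.n_angles) * (360.0 / self.n_angles)
        refs = [
            _normalize(
                project_model(
                    model, a, self.shape, self.pixel_size, self.blob_sigma
                )
            )
            for a in angles
        ]
        return np.stack(refs)

    def __call__(self, twist_degrees: float, rise_angstrom: float) -> float:
        key = (round(twist_degrees, 6), round(rise_angstrom, 6))
        if key in self._cache:
            return self._cache[key]
        sym = HelicalSymmetry(rise_angstrom=rise_angstrom,
                              twist_degrees=twist_degrees)
        refs = self._references(sym)
        ref_fft = np.fft.rfft(refs, axis=1)  # (A, Hf, W)
        # correlation over axial shifts: sum product spectra across columns
        prod = np.einsum("nfw,afw->naf", self._seg_fft_conj, ref_fft)
        corr = np.fft.irfft(prod, n=self.shape[0], axis=2)  # (N, A, H)
        best = corr.reshape(corr.shape[0], -1).max(axis=1)
        score = float(best.mean())
        self._cache[key] = score
        return score


class ShiftMirrorScorer:
    """Template-free score valid near a twist of 180°.

    A projection of a two-subunits-per-turn filament maps onto itself
    under (mirror about the axis line, shift by one rise); the score is
    the mean correlation between each segment shifted axially by the
    candidate rise and its mirror image. Only the rise is scored — the
    twist must already be known to be close to 180° for the relation to
    hold, which is the documented validity domain.
    """

    VALID_TWIST_TOLERANCE = 5.0

    def __init__(self, stack: ImageStack) -> None:
        if len(stack.images) == 0:
            raise ValueError("empty stack")
        self.pixel_size = stack.pixel_size_angstrom
        h = stack.images.shape[1]
        segs = np.stack([_normalize(i) for i in stack.images])
        self._seg_fft = np.fft.fft(segs, axis=1)
        self._mirror_fft_conj = np.conj(np.fft.fft(segs[:, :, ::-1], axis=1))
        self._h = h
        self._cache: dict[tuple[float, float], float] = {}

    def __call__(self, twist_degrees: float, rise_angstrom: float) -> float:
        from .helix import normalize_twist
        if abs(abs(normalize_twist(twist_degrees)) - 180.0) > self.VALID_TWIST_TOLERANCE:
            raise ValueError(
                "shift-mirror score is only valid near |twist| = 180°"
            )
        key = (round(twist_degrees, 6), round(rise_angstrom, 6))
        if key in self._cache:
            return self._cache[key]
        shift_px = rise_angstrom / self.pixel_size
        # correlation of each segment shifted by the rise with its mirror,
        # evaluated at the (fractional) shift via the Fourier shift theorem
        phase = np.exp(
            2j * np.pi * np.fft.fftfreq(self._h) * shift_px
        )[None, :, None]
        prod = (self._seg_fft * phase * self._mirror_fft_conj).sum(axis=(1, 2))
        score = float(np.real(prod).mean()) / self._h
        self._cache[key] = score
        return score


def symmetry_score(
    stack: ImageStack,
    candidate: HelicalSymmetry,
    template: Optional[PointSet] = None,
    mode: str = "template",
    **scorer_kwargs,
) -> float:
    """Score one candidate symmetry against a segment stack.

    ``mode='template'`` requires a template asymmetric unit;
    ``mode='shiftmirror'`` is template-free but only valid near 180°.
    """
    if mode == "template":
        if template is None:
            raise ValueError("template mode requires a template point set")
        scorer = TemplateScorer(stack, template, **scorer_kwargs)
    elif mode == "shiftmirror":
        scorer = ShiftMirrorScorer(stack)
    else:
        raise ValueError(f"unknown scorer mode {mode!r}")
    return scorer(candidate.twist_degrees, candidate.rise_angstrom)


# ---------------------------------------------------------------------------
# Windowed search
# ---------------------------------------------------------------------------

def _grid(center: float, half_width: float, n: int) -> np.ndarray:
    return np.linspace(center - half_width, center + half_width, n)


def _refine_window(
    scorer: Callable[[float, float], float],
    twist_center: float,
    rise_center: float,
    protocol: SearchProtocol,
    allow_shifts: bool = True,
) -> SearchResult:
    tc, rc = twist_center, rise_center
    thw = protocol.twist_half_width
    rhw = protocol.rise_half_width
    n = protocol.steps_per_window
    shifts = 0
    trajectory: list[dict] = []
    for _ in range(protocol.max_iterations):
        tg = _grid(tc, thw, n)
        rg = _grid(rc, rhw, n)
        scores = np.array([[scorer(t, r) for r in rg] for t in tg])
        # deterministic tie-break: highest score, then nearest to the
        # window center in twist, then in rise
        best = scores.max()
        cand = np.argwhere(scores >= best - 1e-12)
        order = sorted(
            (abs(tg[i] - tc), abs(rg[j] - rc), i, j) for i, j in cand
        )
        bi, bj = order[0][2], order[0][3]
        bt, br, bs = tg[bi], rg[bj], scores[bi, bj]
        on_edge_t = bi in (0, n - 1)
        on_edge_r = bj in (0, n - 1)
        trajectory.append({
            "twist_center": tc, "rise_center": rc,
            "twist_half_width": thw, "rise_half_width": rhw,
            "optimum_twist": float(bt), "optimum_rise": float(br),
            "score": float(bs), "on_edge": bool(on_edge_t or on_edge_r),
        })
        if on_edge_t or on_edge_r:
            if not allow_shifts or shifts >= protocol.max_shifts:
                return SearchResult(
                    twist_degrees=float(bt), rise_angstrom=float(br),
                    score=float(bs), converged=False, edge_stuck=True,
                    trajectory=trajectory,
                )
            # shift the window toward the edge at constant width
            if on_edge_t:
                tc += thw if bi == n - 1 else -thw
            if on_edge_r:
                rc += rhw if bj == n - 1 else -rhw
            shifts += 1
            continue
        at_terminal = (
            thw <= protocol.terminal_twist_half_width + 1e-12
            and rhw <= protocol.terminal_rise_half_width + 1e-12
        )
        if at_terminal:
            return SearchResult(
                twist_degrees=float(bt), rise_angstrom=float(br),
                score=float(bs), converged=True, edge_stuck=False,
                trajectory=trajectory,
            )
        tc, rc = float(bt), float(br)
        thw = max(thw / 2.0, protocol.terminal_twist_half_width)
        rhw = max(rhw / 2.0, protocol.terminal_rise_half_width)
    return SearchResult(
        twist_degrees=float(bt), rise_angstrom=float(br), score=float(bs),
        converged=False, edge_stuck=False, trajectory=trajectory,
    )


def windowed_search(
    protocol: SearchProtocol,
    scorer: Callable[[float, float], float],
    allow_shifts: bool = True,
) -> SearchConsensus:
    """Run every tiling window to convergence and form the consensus.

    ``scorer`` is any callable mapping (twist °, rise Å) to a real score
    (higher is better); use :class:`TemplateScorer` for image stacks.
    The consensus is the modal converged result: converged windows are
    clustered within twice the terminal grid step and the largest cluster
    is summarized by its median. A consensus twist within the terminal
    tolerance of ±180° is flagged handedness-ambiguous, since +180° and
    −180° describe the same operator.
    """
    results = [
        _refine_window(scorer, tc, rc, protocol, allow_shifts=allow_shifts)
        for tc, rc in protocol.window_centers()
    ]
    converged = [r for r in results if r.converged]
    n_edge = sum(r.edge_stuck for r in results)
    if not converged:
        raise RuntimeError(
            "no search window converged "
            f"({n_edge}/{len(results)} edge-stuck)"
        )
    step_t = 2 * protocol.terminal_twist_half_width / (protocol.steps_per_window - 1)
    step_r = 2 * protocol.terminal_rise_half_width / (protocol.steps_per_window - 1)
    clusters: list[list[SearchResult]] = []
    for r in sorted(converged, key=lambda x: -x.score):
        for cl in clusters:
            if (abs(cl[0].twist_degrees - r.twist_degrees) <= 2 * step_t
                    and abs(cl[0].rise_angstrom - r.rise_angstrom) <= 2 * step_r):
                cl.append(r)
                break
        else:
            clusters.append([r])
    modal = max(clusters, key=len)
    twist = float(np.median([r.twist_degrees for r in modal]))
    rise = float(np.median([r.rise_angstrom for r in modal]))
    score = float(np.median([r.score for r in modal]))
    from .helix import normalize_twist
    ambiguous = (
        abs(abs(normalize_twist(twist)) - 180.0)
        <= protocol.terminal_twist_half_width
    )
    return SearchConsensus(
        twist_degrees=twist,
        rise_angstrom=rise,
        score=score,
        n_supporting_windows=len(modal),
        n_converged=len(converged),
        n_edge_stuck=n_edge,
        handedness_ambiguous=ambiguous,
        results=results,
    )
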