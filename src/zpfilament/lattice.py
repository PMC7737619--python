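"""Correlation averaging of quasi-crystalline filament sheets.

Laterally associated filaments form semi-regular 2D crystals whose images
are too noisy and too distorted for direct Fourier analysis. The classic
correlation-averaging route is implemented here: a (Fourier-filtered)
reference patch locates repeating units as peaks of a normalized
cross-correlation map; a 2D lattice is least-squares fitted to the peaks,
with per-node residuals retained as the lattice distortion field; unit
cells are re-sampled at the distortion-corrected node positions and
averaged; and the presence of a two-fold axis (plane group p2) is judged
from the deviation of the Fourier phases of the average from the 0°/180°
values a centrosymmetric cell enforces, after refining the phase origin.

Averages are kept in the *fractional cell frame* (an N x N grid over one
unit cell), which makes them periodic by construction so that their DFT
samples exactly the crystallographic reflections (h, k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import match_template, peak_local_max

__all__ = [
    "Lattice2D",
    "UnitCellAverage",
    "PhaseResidualReport",
    "correlate_reference",
    "fit_lattice",
    "average_unit_cells",
    "merge_averages",
    "phase_residual",
    "symmetrize_p2",
    "correlation_average_pipeline",
]


@dataclass
class Lattice2D:
    """A fitted 2D lattice with its distortion field.

    ``basis`` holds the lattice vectors a, b as columns, in pixels, (x, y)
    components; ``node_indices`` are the integer (n_a, n_b) indices of the
    detected nodes, ``displacements`` their residuals from the ideal
    positions ``origin + basis @ index`` (the distortion field).
    """

    origin: np.ndarray  # (2,) px, (x, y)
    basis: np.ndarray  # (2, 2) px, columns a and b
    node_indices: np.ndarray  # (M, 2) int
    node_positions: np.ndarray  # (M, 2) px, observed (x, y)
    displacements: np.ndarray  # (M, 2) px

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.basis)) <= 0:
            raise ValueError("degenerate lattice basis")

    @property
    def n_nodes(self) -> int:
        return len(self.node_indices)


@dataclass
class UnitCellAverage:
    """Distortion-corrected average of one unit cell.

    ``cell`` is sampled on an ``n x n`` grid of fractional lattice
    coordinates (periodic); ``basis_px`` and ``pixel_size_angstrom``
    carry the physical cell geometry for resolution calculations.
    """

    cell: np.ndarray
    basis_px: np.ndarray
    pixel_size_angstrom: float
    n_cells: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class PhaseResidualReport:
    """Outcome of the plane-group phase test on a unit-cell average."""

    residual_degrees: float  # amplitude-weighted (headline statistic)
    residual_unweighted_degrees: float
    plane_group: str
    resolution_limit_inv_angstrom: float
    origin_frac: tuple[float, float]
    n_reflections: int
    reflections: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.residual_degrees <= 90.0 + 1e-9):
            raise ValueError("phase residual must lie in [0, 90] degrees")


# ---------------------------------------------------------------------------
# Peak finding and lattice fitting
# ---------------------------------------------------------------------------

def _subpixel_refine(corr: np.ndarray, peaks_rc: np.ndarray) -> np.ndarray:
    """Parabolic sub-pixel refinement of correlation peaks (row, col)."""
    out = peaks_rc.astype(float).copy()
    h, w = corr.shape
    for i, (r, c) in enumerate(peaks_rc):
        if 0 < r < h - 1:
            y0, y1, y2 = corr[r - 1, c], corr[r, c], corr[r + 1, c]
            d = y0 - 2 * y1 + y2
            if d != 0:
                out[i, 0] += np.clip(0.5 * (y0 - y2) / d, -0.5, 0.5)
        if 0 < c < w - 1:
            y0, y1, y2 = corr[r, c - 1], corr[r, c], corr[r, c + 1]
            d = y0 - 2 * y1 + y2
            if d != 0:
                out[i, 1] += np.clip(0.5 * (y0 - y2) / d, -0.5, 0.5)
    return out


def correlate_reference(
    image: np.ndarray,
    reference_patch: np.ndarray,
    min_distance_px: int = 8,
    threshold: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation map and its significant peaks.

    Returns ``(corr_map, peaks)`` where ``peaks`` are sub-pixel (x, y)
    positions. When no threshold is given, peaks must exceed both half
    the global maximum and a null-distribution floor of
    ``8 / sqrt(patch pixels)`` (the null NCC standard deviation is about
    ``1 / sqrt(patch pixels)``, so pure-noise maxima stay below the
    floor); non-maximum suppression uses ``min_distance_px``.
    """
    corr = match_template(image, reference_patch, pad_input=True)
    if threshold is None:
        floor = 8.0 / np.sqrt(reference_patch.size)
        threshold = float(max(floor, 0.5 * corr.max()))
    peaks_rc = peak_local_max(
        corr, min_distance=min_distance_px, threshold_abs=threshold,
        exclude_border=min_distance_px,
    )
    if len(peaks_rc) == 0:
        return corr, np.empty((0, 2))
    refined = _subpixel_refine(corr, peaks_rc)
    return corr, refined[:, ::-1].copy()  # (row, col) -> (x, y)


def _short_vectors(peaks: np.ndarray, k_neighbors: int = 6) -> np.ndarray:
    """Canonicalized nearest-neighbor difference vectors between peaks."""
    from scipy.spatial import cKDTree

    tree = cKDTree(peaks)
    k = min(k_neighbors + 1, len(peaks))
    _, idx = tree.query(peaks, k=k)
    diffs = []
    for i, row in enumerate(idx):
        for j in row[1:]:
            d = peaks[j] - peaks[i]
            if d[1] < 0 or (d[1] == 0 and d[0] < 0):
                d = -d
            diffs.append(d)
    return np.array(diffs)


def _reduce_basis(basis: np.ndarray) -> np.ndarray:
    """Lagrange-reduce a 2D basis (shortest pair, fixed cell area)."""
    if abs(np.linalg.det(basis)) < 1e-9:
        raise np.linalg.LinAlgError("degenerate basis")
    a, b = basis[:, 0].copy(), basis[:, 1].copy()
    for _ in range(16):
        if np.linalg.norm(a) > np.linalg.norm(b):
            a, b = b, a
        m = round(float(a @ b) / float(a @ a))
        if m == 0:
            break
        b = b - m * a
    return np.stack([a, b], axis=1)


def fit_lattice(
    peaks: np.ndarray,
    max_displacement_px: float = 10.0,
    heights: Optional[np.ndarray] = None,
) -> Lattice2D:
    """Least-squares lattice through correlation peaks, with distortions.

    The shortest cluster of nearest-neighbor difference vectors and the
    shortest non-parallel one seed the basis, which is Lagrange-reduced;
    peaks are integer-indexed against it and basis plus origin are
    refined by linear least squares with iterative rejection of outliers
    (spurious correlation maxima that do not index onto the lattice).
    Per-node residuals of the surviving peaks become the distortion
    field. Requires at least six non-collinear peaks.

    When correlation ``heights`` are supplied, a pseudo-centered
    sublattice is detected and resolved: in a p2 crystal the two-fold
    partner of the motif produces secondary correlation maxima halfway
    between genuine nodes, which would halve the fitted cell. Genuine and
    pseudo nodes then separate into the even and odd (i + j) index-parity
    classes of the half-cell basis; if their mean heights differ clearly,
    the weaker class is dropped and the full cell is refitted.
    """
    peaks = np.asarray(peaks, dtype=float)
    if heights is not None:
        heights = np.asarray(heights, dtype=float)
    if len(peaks) < 6:
        raise ValueError(f"need >= 6 peaks to fit a lattice, got {len(peaks)}")
    diffs = _short_vectors(peaks)
    lengths = np.linalg.norm(diffs, axis=1)
    if np.all(lengths < 1e-9):
        raise ValueError("degenerate peak set")

    def cluster_mean(cands):
        ref = cands[0]
        cos = cands @ ref / (
            np.linalg.norm(ref) * np.linalg.norm(cands, axis=1)
        )
        return cands[cos > 0.9].mean(axis=0)

    lmin = lengths[lengths > 1e-9].min()
    a = cluster_mean(diffs[(lengths > 1e-9) & (lengths < 1.15 * lmin)])
    la = np.linalg.norm(a)
    cross = np.abs(diffs[:, 0] * a[1] - diffs[:, 1] * a[0]) / (lengths + 1e-12)
    nonpar = diffs[(cross > 0.35 * la) & (lengths > 1e-9)]
    if len(nonpar) == 0:
        raise ValueError("peaks are collinear; no 2D lattice")
    lmin_b = np.linalg.norm(nonpar, axis=1).min()
    b = cluster_mean(nonpar[np.linalg.norm(nonpar, axis=1) < 1.15 * lmin_b])

    def refine(basis, origin, keep):
        for _ in range(4):
            idx = np.rint(
                np.linalg.solve(basis, (peaks[keep] - origin).T).T
            ).astype(int)
            design = np.column_stack([idx, np.ones(keep.sum())])
            sol, *_ = np.linalg.lstsq(design, peaks[keep], rcond=None)
            basis = _reduce_basis(sol[:2].T)
            origin = sol[2]
            # reject peaks that do not sit on the fitted lattice
            idx_all = np.rint(
                np.linalg.solve(basis, (peaks - origin).T).T
            ).astype(int)
            disp_all = peaks - (origin + idx_all @ basis.T)
            norms = np.linalg.norm(disp_all, axis=1)
            # cap from the lower quartile: robust even when up to half the
            # peaks are secondary-site outliers (for Rayleigh-distributed
            # genuine displacements, 4 x p25 ≈ 3 sigma keeps ~99%)
            cap = min(max(1.0, 4.0 * np.percentile(norms[keep], 25)),
                      max_displacement_px)
            new_keep = norms <= cap
            if new_keep.sum() < 6:
                break
            keep = new_keep
        return basis, origin, keep

    basis = _reduce_basis(np.stack([a, b], axis=1))
    origin = peaks[np.argmin(np.linalg.norm(peaks - peaks.mean(0), axis=1))].copy()
    keep = np.ones(len(peaks), dtype=bool)
    basis, origin, keep = refine(basis, origin, keep)

    def fit_quality(basis, origin):
        d = peaks - origin
        idx = np.rint(np.linalg.solve(basis, d.T).T)
        resid = np.linalg.norm(d - idx @ basis.T, axis=1)
        return int((resid <= 1.0).sum())

    med = float(np.median(np.linalg.norm(
        peaks[keep] - (origin + np.rint(np.linalg.solve(
            basis, (peaks[keep] - origin).T).T) @ basis.T), axis=1)))
    if med > 1.5:
        # the short-vector seed found a pseudo-lattice (e.g. secondary
        # correlation sites of an almost-centrosymmetric motif); try small
        # integer recombinations of the basis and keep the one that
        # indexes the most peaks tightly
        u, v = basis[:, 0], basis[:, 1]
        combos = [
            m * u + n * v
            for m in range(-2, 3) for n in range(-2, 3)
            if (m, n) != (0, 0)
        ]
        combos.sort(key=lambda w: np.linalg.norm(w))
        best = (fit_quality(basis, origin), basis, origin, keep)
        for i in range(6):
            for j in range(i + 1, 8):
                w1, w2 = combos[i], combos[j]
                if abs(w1[0] * w2[1] - w1[1] * w2[0]) < 1e-6:
                    continue
                cand = _reduce_basis(np.stack([w1, w2], axis=1))
                try:
                    # start from the core of peaks this candidate already
                    # indexes loosely (gate scaled to the cell so the core
                    # spans both basis directions), then let refinement
                    # re-admit and reject
                    d = peaks - origin
                    idx0 = np.rint(np.linalg.solve(cand, d.T).T)
                    gate = max(2.0, 0.35 * float(
                        np.linalg.norm(cand, axis=0).min()
                    ))
                    resid0 = np.linalg.norm(d - idx0 @ cand.T, axis=1)
                    core = resid0 <= gate
                    if core.sum() < 6 or np.linalg.matrix_rank(
                        idx0[core] - idx0[core][0]
                    ) < 2:
                        continue
                    cb, co, ck = refine(cand, origin.copy(), core)
                    q = fit_quality(cb, co)
                except np.linalg.LinAlgError:
                    continue
                if q > best[0]:
                    best = (q, cb, co, ck)
        _, basis, origin, keep = best

    if heights is not None and keep.sum() >= 12:
        idx = np.rint(
            np.linalg.solve(basis, (peaks[keep] - origin).T).T
        ).astype(int)
        parity = (idx.sum(axis=1)) % 2
        n0, n1 = (parity == 0).sum(), (parity == 1).sum()
        if min(n0, n1) >= 0.2 * keep.sum():
            h = heights[keep]
            m0, m1 = h[parity == 0].mean(), h[parity == 1].mean()
            strong = 0 if m0 >= m1 else 1
            if min(m0, m1) < 0.9 * max(m0, m1):
                # pseudo-centered: keep the strong parity, double the cell
                u, v = basis[:, 0], basis[:, 1]
                basis2 = _reduce_basis(np.stack([u - v, u + v], axis=1))
                kept_idx = np.flatnonzero(keep)[parity == strong]
                keep2 = np.zeros(len(peaks), dtype=bool)
                keep2[kept_idx] = True
                origin2 = peaks[kept_idx[
                    np.argmin(np.linalg.norm(
                        peaks[kept_idx] - peaks[kept_idx].mean(0), axis=1))
                ]].copy()
                basis, origin, keep = refine(basis2, origin2, keep2)

    idx = np.rint(
        np.linalg.solve(basis, (peaks[keep] - origin).T).T
    ).astype(int)
    disp = peaks[keep] - (origin + idx @ basis.T)
    if keep.sum() < 6:
        raise ValueError("too few peaks after outlier rejection")
    return Lattice2D(
        origin=origin, basis=basis, node_indices=idx,
        node_positions=peaks[keep], displacements=disp,
    )


# ---------------------------------------------------------------------------
# Unit-cell averaging
# ---------------------------------------------------------------------------

def average_unit_cells(
    image: np.ndarray,
    lattice: Lattice2D,
    n_samples: int = 64,
    pixel_size_angstrom: float = 1.0,
) -> UnitCellAverage:
    """Average the unit cell over all distortion-corrected nodes.

    For each detected node the cell around its *observed* (displaced)
    position is re-sampled on an ``n_samples``-square grid of fractional
    lattice coordinates using bicubic interpolation, then all cells are
    averaged. Sampling at observed rather than ideal positions is what
    corrects the smooth lattice distortion. Nodes whose cell footprint
    leaves the image are skipped. For white noise the averaged cell's
    noise falls as 1/sqrt(N).
    """
    h, w = image.shape
    u = (np.arange(n_samples) + 0.5) / n_samples - 0.5
    uu, vv = np.meshgrid(u, u, indexing="ij")
    frac = np.stack([uu.ravel(), vv.ravel()])  # (2, S^2)
    offsets = lattice.basis @ frac  # (2, S^2) px, (x, y)
    acc = np.zeros((n_samples, n_samples))
    count = 0
    margin = np.abs(offsets).max(axis=1)
    for pos in lattice.node_positions:
        if (pos[0] - margin[0] < 1 or pos[0] + margin[0] > w - 2
                or pos[1] - margin[1] < 1 or pos[1] + margin[1] > h - 2):
            continue
        xs = pos[0] + offsets[0]
        ys = pos[1] + offsets[1]
        cell = ndimage.map_coordinates(
            image, [ys, xs], order=3, mode="nearest"
        ).reshape(n_samples, n_samples)
        acc += cell
        count += 1
    if count == 0:
        raise ValueError("no unit cell fits inside the image")
    return UnitCellAverage(
        cell=acc / count,
        basis_px=lattice.basis,
        pixel_size_angstrom=pixel_size_angstrom,
        n_cells=count,
    )


def merge_averages(
    averages: Sequence[UnitCellAverage],
    rotation_step_degrees: float = 2.0,
) -> UnitCellAverage:
    """Merge several sheet averages after rotational/translational alignment.

    Each average is aligned to the first by an exhaustive search over
    rotations (in steps of ``rotation_step_degrees``) combined with
    periodic translational alignment by phase correlation, then all are
    averaged. A partner whose best correlation is negative is still
    merged but flagged with a warning.
    """
    from skimage.transform import rotate as sk_rotate

    if len(averages) == 0:
        raise ValueError("nothing to merge")
    if len(averages) == 1:
        return averages[0]
    ref = averages[0]
    refc = ref.cell - ref.cell.mean()
    ref_fft = np.fft.fft2(refc)
    out = ref.cell.copy()
    n_cells = ref.n_cells
    warnings = list(ref.warnings)
    angles = np.arange(0.0, 360.0, rotation_step_degrees)
    for av in averages[1:]:
        best = (-np.inf, None)
        for ang in angles:
            rot = sk_rotate(av.cell, ang, mode="wrap", order=1)
            rotc = rot - rot.mean()
            corr = np.real(np.fft.ifft2(ref_fft * np.conj(np.fft.fft2(rotc))))
            peak = float(corr.max())
            denom = np.linalg.norm(refc) * np.linalg.norm(rotc)
            score = peak / denom if denom > 0 else 0.0
            if score > best[0]:
                shift = np.unravel_index(np.argmax(corr), corr.shape)
                best = (score, (ang, shift))
        score, (ang, shift) = best
        rot = sk_rotate(av.cell, ang, mode="wrap", order=3)
        aligned = np.roll(rot, shift, axis=(0, 1))
        if score < 0:
            warnings.append(
                f"merge partner anti-correlated (r = {score:.3f})"
            )
        out = out + aligned
        n_cells += av.n_cells
    return UnitCellAverage(
        cell=out / len(averages),
        basis_px=ref.basis_px,
        pixel_size_angstrom=ref.pixel_size_angstrom,
        n_cells=n_cells,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Phase residual and p2 symmetrization
# ---------------------------------------------------------------------------

def _reflections_within(
    average: UnitCellAverage, resolution_limit_inv_angstrom: float
):
    """Friedel-unique reflections (h, k) within the resolution limit."""
    n = average.cell.shape[0]
    f = np.fft.fft2(average.cell)
    recip = np.linalg.inv(average.basis_px).T  # columns a*, b* in px^-1
    hs, ks, amps, phases = [], [], [], []
    hmax = n // 2 - 1
    for h in range(-hmax, hmax + 1):
        for k in range(0, hmax + 1):
            if k == 0 and h <= 0:
                continue  # Friedel half, origin excluded
            g = recip @ np.array([h, k])
            s = np.linalg.norm(g) / average.pixel_size_angstrom
            if s > resolution_limit_inv_angstrom:
                continue
            coeff = f[h % n, k % n]
            hs.append(h)
            ks.append(k)
            amps.append(np.abs(coeff))
            phases.append(np.angle(coeff))
    return (np.array(hs), np.array(ks), np.array(amps), np.array(phases))


def _centro_residuals(phases: np.ndarray) -> np.ndarray:
    """Per-reflection distance (rad) of a phase to the nearest of 0 / 180°."""
    return np.abs((phases + np.pi / 2) % np.pi - np.pi / 2)


def _residual_at_origin(hs, ks, phases, du, dv):
    shifted = phases - 2 * np.pi * (np.outer(du, hs) + np.outer(dv, ks))
    return _centro_residuals(shifted)


def phase_residual(
    average: UnitCellAverage,
    plane_group: str = "p2",
    resolution_limit_inv_angstrom: float = 1.0 / 14.0,
    amplitude_weighted: bool = True,
) -> PhaseResidualReport:
    """Phase deviation from centrosymmetry after origin refinement.

    For plane group p2, every reflection of a correctly-origined cell has
    phase 0° or 180°. The phase origin is refined by exhaustive search on
    a sub-pixel grid over half the unit cell (coarse-to-fine); the
    residual is the amplitude-weighted mean over reflections within the
    resolution limit of the circular distance to the nearest theoretical
    value. A residual near 0° indicates two-fold symmetry; uniformly
    random phases give 45° in expectation. The unweighted statistic is
    reported alongside.
    """
    if plane_group != "p2":
        raise ValueError("only plane group p2 is supported")
    hs, ks, amps, phases = _reflections_within(
        average, resolution_limit_inv_angstrom
    )
    if len(hs) == 0:
        raise ValueError("no reflections within the resolution limit")
    w = amps if amplitude_weighted else np.ones_like(amps)

    def weighted_mean(res):
        return np.degrees((res * w).sum(axis=1) / w.sum())

    # coarse-to-fine origin search over half the cell (phase residual is
    # periodic with period 1/2 in each fractional coordinate)
    grid = np.linspace(0.0, 0.5, 81, endpoint=False)
    du, dv = np.meshgrid(grid, grid, indexing="ij")
    du, dv = du.ravel(), dv.ravel()
    res = weighted_mean(_residual_at_origin(hs, ks, phases, du, dv))
    best = int(np.argmin(res))
    u0, v0 = du[best], dv[best]
    fine = np.linspace(-0.5 / 80, 0.5 / 80, 41)
    du, dv = np.meshgrid(u0 + fine, v0 + fine, indexing="ij")
    du, dv = du.ravel(), dv.ravel()
    res = weighted_mean(_residual_at_origin(hs, ks, phases, du, dv))
    best = int(np.argmin(res))
    u0, v0 = float(du[best]), float(dv[best])

    per_ref = _residual_at_origin(hs, ks, phases, [u0], [v0])[0]
    weighted = float(np.degrees((per_ref * amps).sum() / amps.sum()))
    unweighted = float(np.degrees(per_ref.mean()))
    # the search parameter u0 shifts phases by -2*pi*h*u0; the physical
    # two-fold point p satisfies phi + 2*pi*h*p centric, i.e. p = -u0
    # (two-fold points repeat every half cell, so reduce modulo 0.5)
    p_u, p_v = (-u0) % 0.5, (-v0) % 0.5
    shifted_phases = phases + 2 * np.pi * (p_u * hs + p_v * ks)
    return PhaseResidualReport(
        residual_degrees=weighted if amplitude_weighted else unweighted,
        residual_unweighted_degrees=unweighted,
        plane_group=plane_group,
        resolution_limit_inv_angstrom=resolution_limit_inv_angstrom,
        origin_frac=(p_u, p_v),
        n_reflections=len(hs),
        reflections=[
            {
                "h": int(h), "k": int(k), "amplitude": float(a),
                "phase_degrees": float(np.degrees(
                    (p + np.pi) % (2 * np.pi) - np.pi)),
                "residual_degrees": float(np.degrees(r)),
            }
            for h, k, a, p, r in zip(hs, ks, amps, shifted_phases, per_ref)
        ],
    )


def symmetrize_p2(
    average: UnitCellAverage, origin_frac: tuple[float, float]
) -> UnitCellAverage:
    """Impose the two-fold axis at the refined origin on the average.

    The cell is shifted (periodically, via the Fourier shift theorem) so
    the two-fold point sits at the grid origin, averaged with its 180°
    rotation, and shifted back. The result is exactly invariant under the
    two-fold rotation about the refined origin.
    """
    n = average.cell.shape[0]
    f = np.fft.fft2(average.cell)
    fi = np.fft.fftfreq(n) * n
    hh, kk = np.meshgrid(fi, fi, indexing="ij")
    shift = np.exp(2j * np.pi * (hh * origin_frac[0] + kk * origin_frac[1]))
    f0 = f * shift  # origin moved to (0, 0)
    f_sym = 0.5 * (f0 + np.conj(f0))  # average with the 180° rotation
    cell = np.real(np.fft.ifft2(f_sym / shift))
    return UnitCellAverage(
        cell=cell,
        basis_px=average.basis_px,
        pixel_size_angstrom=average.pixel_size_angstrom,
        n_cells=average.n_cells,
        warnings=list(average.warnings),
    )


def correlation_average_pipeline(
    image: np.ndarray,
    pixel_size_angstrom: float,
    reference_center_xy: Optional[tuple[float, float]] = None,
    reference_size_px: int = 48,
    lowpass_sigma_px: float = 1.5,
    n_samples: int = 64,
    resolution_limit_inv_angstrom: float = 1.0 / 14.0,
    plane_group: str = "p2",
    p2_residual_threshold_degrees: float = 25.0,
) -> tuple[UnitCellAverage, PhaseResidualReport, Lattice2D]:
    """Full correlation-averaging pass over one sheet image.

    A low-pass-filtered patch (default: at the image center) serves as the
    cross-correlation reference; peaks are lattice-fitted, unit cells are
    averaged at distortion-corrected positions, and the p2 phase residual
    is evaluated to the resolution limit. The p2-symmetrized average is
    substituted only when the residual passes the acceptance threshold
    (default 25°).
    """
    h, w = image.shape
    if reference_center_xy is None:
        reference_center_xy = (w / 2.0, h / 2.0)
    cx, cy = (int(round(c)) for c in reference_center_xy)
    half = reference_size_px // 2
    patch = image[cy - half : cy + half, cx - half : cx + half]
    if patch.size == 0:
        raise ValueError("reference patch outside image")
    patch = ndimage.gaussian_filter(patch, lowpass_sigma_px)
    corr, peaks = correlate_reference(
        ndimage.gaussian_filter(image, lowpass_sigma_px / 2), patch,
        min_distance_px=max(4, reference_size_px // 6),
    )
    heights = np.array([
        corr[int(round(p[1])), int(round(p[0]))] for p in peaks
    ]) if len(peaks) else None
    lattice = fit_lattice(peaks, heights=heights)
    average = average_unit_cells(
        image, lattice, n_samples=n_samples,
        pixel_size_angstrom=pixel_size_angstrom,
    )
    report = phase_residual(
        average, plane_group=plane_group,
        resolution_limit_inv_angstrom=resolution_limit_inv_angstrom,
    )
    if report.residual_degrees <= p2_residual_threshold_degrees:
        average = symmetrize_p2(average, report.origin_frac)
    return average, report, lattice
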