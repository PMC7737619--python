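"""Shared I/O and the end-to-end pipeline driver.

Image stacks and volumes travel as MRC2014 (mode 2, float32) maps written
through gemmi, with the physical pixel size carried in the unit cell and
per-image ground-truth metadata in a JSON sidecar; plain 2D images may
also be written as TIFF/PNG. Structures are PDB/mmCIF via gemmi.

Conventions used everywhere: images are indexed (row, col) with row 0 at
top and the filament axis vertical; all lengths are in Å, converted from
pixels only at I/O boundaries; every stochastic stage receives an
explicit seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .synthetic import ImageStack

__all__ = [
    "write_mrc",
    "read_mrc",
    "write_stack",
    "read_stack",
    "write_image",
    "read_image",
    "RunConfig",
    "run_pipeline",
]


def write_mrc(path, data: np.ndarray, voxel_size_angstrom: float) -> None:
    """Write a 2D/3D array (or stack) as an MRC2014 mode-2 map."""
    import gemmi

    arr = np.ascontiguousarray(np.asarray(data, dtype=np.float32))
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError("expected a 2D or 3D array")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr.shape[2], arr.shape[1], arr.shape[0])
    np.asarray(m.grid, dtype=np.float32).reshape(arr.shape[::-1])[:] = (
        arr.transpose(2, 1, 0)
    )
    m.grid.unit_cell = gemmi.UnitCell(
        arr.shape[2] * voxel_size_angstrom,
        arr.shape[1] * voxel_size_angstrom,
        arr.shape[0] * voxel_size_angstrom,
        90.0, 90.0, 90.0,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC/CCP4 map; returns (array (sections, rows, cols), Å/voxel)."""
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    arr = np.asarray(m.grid, dtype=np.float32).transpose(2, 1, 0).copy()
    nx = m.grid.nu
    voxel = m.grid.unit_cell.a / nx
    return arr, float(voxel)


def write_stack(path, stack: ImageStack) -> None:
    """Write an image stack as MRC plus a JSON metadata sidecar."""
    path = Path(path)
    write_mrc(path, stack.images, stack.pixel_size_angstrom)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "pixel_size_angstrom": stack.pixel_size_angstrom,
        "metadata": stack.metadata,
    }, indent=1))


def read_stack(path) -> ImageStack:
    path = Path(path)
    data, voxel = read_mrc(path)
    meta: list[dict] = []
    pixel = voxel
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        meta = side.get("metadata", [])
        pixel = side.get("pixel_size_angstrom", voxel)
    return ImageStack(images=data, pixel_size_angstrom=pixel, metadata=meta)


def write_image(path, image: np.ndarray,
                pixel_size_angstrom: Optional[float] = None) -> None:
    """Write a single 2D image as TIFF/PNG (8-bit rescaled) or MRC."""
    path = Path(path)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".map"):
        write_mrc(path, image, pixel_size_angstrom or 1.0)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    elif suffix == ".png":
        import imageio.v3 as iio

        lo, hi = float(image.min()), float(image.max())
        scaled = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
        iio.imwrite(path, (scaled * 255).astype(np.uint8))
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    if pixel_size_angstrom is not None and suffix not in (".mrc", ".map"):
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"pixel_size_angstrom": pixel_size_angstrom})
        )


def read_image(path) -> np.ndarray:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".map"):
        arr, _ = read_mrc(path)
        return arr[0] if arr.shape[0] == 1 else arr
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    if suffix == ".png":
        import imageio.v3 as iio

        return np.asarray(iio.imread(path), dtype=float)
    raise ValueError(f"unsupported image format {suffix!r}")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration (JSON round-trippable).

    Each stage block mirrors that module's defaults; stages may be turned
    off. The sizes below are deliberately modest so a full pass stays
    interactive — scale up per stage for production runs.
    """

    seed: int = 0
    run_search: bool = True
    run_sheet: bool = True
    run_xlms: bool = True
    run_repeats: bool = True
    search: dict = field(default_factory=lambda: {
        "rise_angstrom": 62.5, "twist_degrees": 180.0,
        "n_segments": 48, "snr": 0.5, "image_px": 64,
        "pixel_size_angstrom": 6.25,
        "twist_range": [170.0, 190.0], "rise_range": [60.0, 65.0],
        "n_score_segments": 16, "n_angles": 8,
    })
    sheet: dict = field(default_factory=lambda: {
        "size_px": 360, "distortion_amplitude_px": 1.0,
        "noise_sigma_rel": 1.0,
    })
    repeats: dict = field(default_factory=lambda: {
        "repeat_angstrom": 65.0, "pixel_size_angstrom": 5.0,
        "n_classes": 20, "snr": 0.5,
    })

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return a JSON-serializable report.

    Deterministic: the same config (including seed) produces an identical
    report. Stage seeds are derived from the master seed so stages stay
    independent.
    """
    from . import __version__
    from .helix import HelicalSymmetry, enumerate_compatible_rises
    from .repeats import aggregate_repeats
    from .search import (SearchProtocol, TemplateScorer,
                         average_power_spectrum,
                         estimate_layerline_periodicity, windowed_search)
    from .synthetic import (SheetSpec, default_filament_model,
                            make_repeat_filament_image, project_segments,
                            render_filament_volume, umod_like_unit)
    from .lattice import correlation_average_pipeline
    from .xlms import assign_peaklist, spacing_analysis
    from . import datasets

    rng = np.random.default_rng(config.seed)
    stage_seed = {name: int(rng.integers(2 ** 31))
                  for name in ("search", "sheet", "repeats")}
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    if config.run_search:
        p = config.search
        sym = HelicalSymmetry(p["rise_angstrom"], p["twist_degrees"])
        model = default_filament_model(sym)
        box = p["image_px"] * p["pixel_size_angstrom"]
        vol = render_filament_volume(model, p["pixel_size_angstrom"], box)
        sr = np.random.default_rng(stage_seed["search"])
        angles = sr.uniform(0, 360, p["n_segments"])
        offsets = sr.uniform(-sym.rise_angstrom, sym.rise_angstrom,
                             p["n_segments"])
        clean = project_segments(vol, p["pixel_size_angstrom"],
                                 p["n_segments"], angles, offsets, 0.0, 0)
        signal_sd = float(clean.images.std())
        stack = project_segments(
            vol, p["pixel_size_angstrom"], p["n_segments"], angles, offsets,
            signal_sd / p["snr"], stage_seed["search"],
        )
        spec = average_power_spectrum(stack)
        layer = estimate_layerline_periodicity(spec, stack.pixel_size_angstrom)
        rises = enumerate_compatible_rises(layer.periodicity_angstrom, 10)
        protocol = SearchProtocol(
            twist_range=tuple(p["twist_range"]),
            rise_range=tuple(p["rise_range"]),
        )
        scorer = TemplateScorer(
            stack, umod_like_unit(), n_angles=p["n_angles"],
            n_segments=p["n_score_segments"], seed=stage_seed["search"],
        )
        consensus = windowed_search(protocol, scorer)
        report["stages"]["search"] = {
            "layerline_periodicity_angstrom": layer.periodicity_angstrom,
            "compatible_rises_angstrom": rises,
            "consensus_twist_degrees": consensus.twist_degrees,
            "consensus_twist_magnitude_degrees":
                consensus.twist_magnitude_degrees,
            "consensus_rise_angstrom": consensus.rise_angstrom,
            "n_converged": consensus.n_converged,
            "n_edge_stuck": consensus.n_edge_stuck,
            "handedness_ambiguous": consensus.handedness_ambiguous,
        }

    if config.run_sheet:
        from .synthetic import make_sheet_image

        p = config.sheet
        clean = make_sheet_image(
            SheetSpec(seed=stage_seed["sheet"]), p["size_px"]
        )
        spec = SheetSpec(
            distortion_amplitude_px=p["distortion_amplitude_px"],
            noise_sigma=p["noise_sigma_rel"] * float(clean.std()),
            seed=stage_seed["sheet"],
        )
        img = make_sheet_image(spec, p["size_px"])
        _, residual_report, lattice = correlation_average_pipeline(
            img, spec.pixel_size_angstrom
        )
        report["stages"]["sheet"] = {
            "n_lattice_nodes": lattice.n_nodes,
            "phase_residual_degrees": residual_report.residual_degrees,
            "phase_residual_unweighted_degrees":
                residual_report.residual_unweighted_degrees,
            "n_reflections": residual_report.n_reflections,
        }

    if config.run_xlms:
        peaks = datasets.crosslinked_peaklist()
        assignments = assign_peaklist(peaks, datasets.DIGEST_COMPONENTS)
        spacing = spacing_analysis(
            datasets.f1_peaklist(),
            reference_window=(datasets.ZI12_HALF_ZPN_DA, 20000.0),
        )
        report["stages"]["xlms"] = {
            "assignments": [
                {
                    "peak_da": a.peak_da,
                    "unique": a.unique,
                    "compositions": [c.as_dict() for c, _ in a.feasible],
                }
                for a in assignments
            ],
            "spacings_explained": sum(t.explained for t in spacing),
            "spacings_total": len(spacing),
        }

    if config.run_repeats:
        p = config.repeats
        probe = make_repeat_filament_image(
            p["repeat_angstrom"], p["pixel_size_angstrom"],
            noise_sigma=0.0, seed=0,
        )
        signal_sd = float(probe.std())
        images = [
            make_repeat_filament_image(
                p["repeat_angstrom"], p["pixel_size_angstrom"],
                noise_sigma=signal_sd / p["snr"],
                seed=stage_seed["repeats"] + i,
            )
            for i in range(p["n_classes"])
        ]
        est = aggregate_repeats(images, p["pixel_size_angstrom"])
        report["stages"]["repeats"] = {
            "mean_spacing_angstrom": est.spacing_angstrom,
            "sd_angstrom": est.spacing_sd_angstrom,
            "n_measurements": est.n_measurements,
            "n_excluded": est.n_excluded,
        }
    return report
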