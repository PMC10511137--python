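"""NIR hyperspectral cube handling.

Reads ENVI-dialect header/cube pairs (BSQ/BIL/BIP), calibrates raw
counts to absolute reflectance against dark (0%) and 99%-reflectance
references, segments seed-occupied pixels on the matt-black tray,
extracts per-seed mean spectra, and renders pseudo-color score maps.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import DegenerateDataError, FormatError, InputError
from .preprocess import SpectraMatrix

logger = logging.getLogger(__name__)

# ENVI data-type code -> numpy dtype
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class HyperCube:
    """Cube in memory order ``(line, sample, band)``."""

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"  # "raw" counts or calibrated "reflectance"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise InputError("cube must be (lines, samples, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise InputError(
                f"{self.data.shape[2]} bands but {self.wavelengths.size} wavelengths"
            )
        if self.kind not in ("raw", "reflectance"):
            raise InputError(f"unknown cube kind {self.kind!r}")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationRefs:
    """Dark (0%) and white (99% standard) reference counts.

    ``dark``/``white`` may be scalars or per-pixel-per-band arrays
    broadcastable to the cube; per-pixel images are preferred because
    push-broom cameras show column nonuniformity.
    """

    dark: np.ndarray | float
    white: np.ndarray | float
    white_reflectance: float = 0.99


@dataclass
class SeedRegion:
    """One connected seed-occupied pixel region (0-based coordinates)."""

    id: int
    pixels: np.ndarray  # (n_pixels, 2) array of (line, sample)
    centroid: tuple[float, float]

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])


# ---------------------------------------------------------------------------
# ENVI-dialect I/O


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_cube(header_path, data_path=None) -> HyperCube:
    """Read an ENVI-style header + binary cube into memory order.

    The header must declare ``samples``, ``lines``, ``bands``,
    ``data type``, ``interleave`` and a ``wavelength`` list; the cube is
    returned as ``(line, sample, band)`` regardless of interleave.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"header {header_path} missing field {exc}") from exc
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unknown interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported data type code {dtype_code}")
    if "wavelength" not in fields:
        raise FormatError(f"header {header_path} lacks wavelengths")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array(
        [float(v) for v in wl_text.replace(",", " ").split()], dtype=float
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"{wavelengths.size} wavelengths for {bands} declared bands"
        )
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    byte_order = int(fields.get("byte order", 0))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    if data_path is None:
        stem = header_path.with_suffix("")
        for cand in (stem, stem.with_suffix(".dat"), stem.with_suffix(".img")):
            if cand.exists() and cand != header_path:
                data_path = cand
                break
        if data_path is None:
            raise FormatError(f"no cube file found next to {header_path}")
    raw = np.fromfile(data_path, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise FormatError(
            f"cube {data_path} holds {raw.size} values, expected {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)
    return HyperCube(data=np.ascontiguousarray(data), wavelengths=wavelengths)


def write_cube(
    header_path, cube: HyperCube, interleave: str = "bsq", data_path=None
) -> None:
    """Write an ENVI-style header/cube pair (testing and data exchange)."""
    header_path = Path(header_path)
    if interleave not in _INTERLEAVES:
        raise InputError(f"unknown interleave {interleave!r}")
    if data_path is None:
        data_path = header_path.with_suffix(".dat")
    data = cube.data.astype(np.float32)
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    out.tofile(data_path)
    wl = ", ".join(f"{v:.10g}" for v in cube.wavelengths)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cube.samples}\n"
        f"lines = {cube.lines}\n"
        f"bands = {cube.bands}\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength = {" + wl + "}\n"
    )


# ---------------------------------------------------------------------------
# Calibration, segmentation, spectrum extraction


def calibrate_reflectance(
    raw: HyperCube, refs: CalibrationRefs, clip_max: float = 1.2
) -> HyperCube:
    """Linear per-pixel-per-band calibration to absolute reflectance.

    ``reflectance = white_reflectance * (raw - dark) / (white - dark)``,
    clipped to ``[0, clip_max]`` (specular glints can exceed the 99%
    standard; clipping is logged).
    """
    if raw.kind != "raw":
        raise InputError("cube is already calibrated")
    dark = np.asarray(refs.dark, dtype=float)
    white = np.asarray(refs.white, dtype=float)
    span = np.broadcast_to(white - dark, raw.data.shape)
    if np.any(span <= 0):
        raise DegenerateDataError(
            "white reference does not exceed dark reference everywhere"
        )
    refl = refs.white_reflectance * (raw.data.astype(float) - dark) / span
    n_clip = int(np.sum((refl < 0) | (refl > clip_max)))
    if n_clip:
        logger.warning("clipped %d calibrated values to [0, %g]", n_clip, clip_max)
        refl = np.clip(refl, 0.0, clip_max)
    return HyperCube(data=refl, wavelengths=raw.wavelengths.copy(), kind="reflectance")


def segment_seeds(
    cube: HyperCube,
    band_window: tuple[float, float] | None = None,
    threshold: float | str = "otsu",
    min_area: int = 20,
) -> list[SeedRegion]:
    """Find seed-occupied pixel regions against the dark tray.

    Foreground is where the mean reflectance over ``band_window``
    (default: all bands) exceeds ``threshold`` (Otsu by default);
    4-connected components with at least ``min_area`` pixels become
    regions, ordered row-major by centroid.
    """
    if cube.kind != "reflectance":
        raise InputError("segmentation needs a calibrated reflectance cube")
    if band_window is None:
        mean_img = cube.data.mean(axis=2)
    else:
        lo, hi = band_window
        mask = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
        if not mask.any():
            raise InputError(f"band window {band_window} selects no bands")
        mean_img = cube.data[:, :, mask].mean(axis=2)
    if threshold == "otsu":
        if np.allclose(mean_img, mean_img.flat[0]):
            return []
        thr = threshold_otsu(mean_img)
    else:
        thr = float(threshold)
    fg = mean_img > thr
    if not fg.any():
        return []
    labeled = cc_label(fg, connectivity=1)
    regions = []
    for prop in regionprops(labeled):
        if prop.area < min_area:
            continue
        regions.append(
            SeedRegion(id=-1, pixels=prop.coords.copy(), centroid=tuple(prop.centroid))
        )
    regions.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    for i, region in enumerate(regions):
        region.id = i
    return regions


def well_regions(
    cube: HyperCube, layout: tuple[int, int], min_area: int = 1
) -> list[SeedRegion]:
    """Alternative segmentation for a known tray layout: split the image
    into a ``rows x cols`` grid of wells and treat each cell as one region."""
    n_rows, n_cols = layout
    if n_rows <= 0 or n_cols <= 0:
        raise InputError("layout must be positive")
    hs = np.linspace(0, cube.lines, n_rows + 1).astype(int)
    vs = np.linspace(0, cube.samples, n_cols + 1).astype(int)
    regions = []
    i = 0
    for r in range(n_rows):
        for c in range(n_cols):
            yy, xx = np.mgrid[hs[r] : hs[r + 1], vs[c] : vs[c + 1]]
            coords = np.column_stack([yy.ravel(), xx.ravel()])
            if coords.shape[0] < min_area:
                continue
            regions.append(
                SeedRegion(
                    id=i,
                    pixels=coords,
                    centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
                )
            )
            i += 1
    return regions


def extract_seed_spectra(cube: HyperCube, regions) -> SpectraMatrix:
    """Per-seed mean spectrum: unweighted average over region pixels."""
    if not regions:
        raise InputError("no regions to extract")
    rows = []
    for region in regions:
        if region.area == 0:
            raise InputError(f"region {region.id} is empty")
        px = region.pixels
        if (
            px[:, 0].min() < 0
            or px[:, 1].min() < 0
            or px[:, 0].max() >= cube.lines
            or px[:, 1].max() >= cube.samples
        ):
            raise InputError(f"region {region.id} exceeds cube bounds")
        rows.append(cube.data[px[:, 0], px[:, 1], :].mean(axis=0))
    return SpectraMatrix(
        wavelengths=cube.wavelengths.copy(),
        values=np.vstack(rows),
        seed_ids=np.array([r.id for r in regions]),
    )


# ---------------------------------------------------------------------------
# Score-map rendering


def render_score_map(
    cube: HyperCube,
    regions,
    scores,
    cmap: str = "viridis",
    background: str = "grayscale",
) -> np.ndarray:
    """Pseudo-color raster of per-seed relative scores (RGB uint8).

    Each region is filled with the colormap color of its min-max
    normalized score (equal scores map to mid-scale); the background
    shows the grayscale mean-reflectance image, or black.
    """
    from matplotlib import colormaps

    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size != len(regions):
        raise InputError(
            f"{scores.size} scores for {len(regions)} regions"
        )
    span = scores.max() - scores.min()
    rel = (
        (scores - scores.min()) / span if span > 0 else np.full(scores.size, 0.5)
    )
    colormap = colormaps[cmap]

    if background == "grayscale":
        mean_img = cube.data.mean(axis=2)
        lo, hi = mean_img.min(), mean_img.max()
        gray = (mean_img - lo) / (hi - lo) if hi > lo else np.zeros_like(mean_img)
        rgb = np.repeat((gray * 255).astype(np.uint8)[:, :, None], 3, axis=2)
    else:
        rgb = np.zeros((cube.lines, cube.samples, 3), dtype=np.uint8)
    for region, r in zip(regions, rel):
        color = (np.array(colormap(float(r))[:3]) * 255).astype(np.uint8)
        rgb[region.pixels[:, 0], region.pixels[:, 1]] = color
    return rgb


def save_score_map(path, rgb: np.ndarray) -> None:
    """Write an RGB raster to PNG."""
    import matplotlib.pyplot as plt

    plt.imsave(path, rgb)


def region_table(regions, scores=None) -> pd.DataFrame:
    """Region summary (id, centroid, area, score) as a table."""
    rows = {
        "id": [r.id for r in regions],
        "centroid_line": [r.centroid[0] for r in regions],
        "centroid_sample": [r.centroid[1] for r in regions],
        "area": [r.area for r in regions],
    }
    if scores is not None:
        scores = np.asarray(scores).ravel()
        if scores.size != len(regions):
            raise InputError("score count does not match regions")
        rows["score"] = scores
    return pd.DataFrame(rows)
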