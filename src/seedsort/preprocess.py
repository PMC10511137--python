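"""Spectral preprocessing: the 12 candidate explanatory-variable spectra.

Per-seed NIR reflectance spectra ``R`` are turned into twelve candidate
explanatory variables ``X1``--``X12`` by combining a base transform
(raw reflectance, reciprocal ``1/R``, or pseudo-absorbance ``-log10 R``)
with optional Savitzky--Golay smoothing (window 5, 3rd-order polynomial)
and optional standard normal variate (SNV) row standardization.

Index layout (blocks of four per base transform)::

    base            plain  +SG   +SNV  +SG+SNV
    reflectance      X1     X2    X3     X4
    reciprocal       X5     X6    X7     X8
    pseudo-abs       X9     X10   X11    X12

All variants are computed on the valid spectral range (980--2,200 nm,
201 wavebands on a 6 nm-pitch instrument grid), which makes the chain
compositional: ``X2 == sg_filter(X1)``, ``X4 == snv(sg_filter(X1))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import DegenerateDataError, DomainError, InputError

logger = logging.getLogger(__name__)

#: Valid spectral range in nm; SNV (and every variant) is computed on it.
VALID_RANGE = (980.0, 2200.0)

#: Waveband count of the valid range on the reference 6 nm-pitch grid.
VALID_RANGE_BANDS = 201

BASES = ("reflectance", "reciprocal", "pseudo_absorbance")

SG_WINDOW = 5
SG_POLYORDER = 3

_REFLECTANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class PreprocessSpec:
    """One of the twelve explanatory-variable recipes.

    Parameters
    ----------
    base : {"reflectance", "reciprocal", "pseudo_absorbance"}
        Elementwise base transform applied first.
    sg : bool
        Apply Savitzky--Golay smoothing (window 5, order 3).
    snv : bool
        Apply standard normal variate row standardization last.
    sg_first : bool
        When both flags are set, smooth before standardizing
        (the default); recorded so the order is auditable.
    """

    base: str
    sg: bool = False
    snv: bool = False
    sg_first: bool = True

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise InputError(f"unknown base transform {self.base!r}")

    @property
    def index(self) -> int:
        """Variant number 1--12."""
        return 4 * BASES.index(self.base) + int(self.sg) + 2 * int(self.snv) + 1

    @classmethod
    def from_index(cls, index: int, sg_first: bool = True) -> "PreprocessSpec":
        if not 1 <= int(index) <= 12:
            raise InputError(f"variant index must be 1..12, got {index}")
        i = int(index) - 1
        return cls(
            base=BASES[i // 4],
            sg=bool(i % 4 & 1),
            snv=bool(i % 4 & 2),
            sg_first=sg_first,
        )

    @property
    def label(self) -> str:
        return f"X{self.index}"


@dataclass
class SpectraMatrix:
    """Seeds-by-wavebands spectral matrix with its provenance.

    ``values`` has one row per seed; ``spec`` records which of the 12
    variants produced it (``None`` for raw reflectance straight from an
    image).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    spec: PreprocessSpec | None = None
    seed_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.wavelengths.size:
            raise InputError(
                f"{self.values.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise InputError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InputError("spectra contain non-finite values")

    @property
    def n_seeds(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


def _clip_positive(values: np.ndarray, wavelengths: np.ndarray | None) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    nonpos = values <= 0
    if np.any(nonpos):
        idx = int(np.argwhere(nonpos)[0][-1])
        where = (
            f"{wavelengths[idx]:g} nm" if wavelengths is not None else f"band {idx}"
        )
        raise DomainError(f"non-positive reflectance at {where}")
    tiny = values < _REFLECTANCE_FLOOR
    if np.any(tiny):
        logger.warning(
            "clipped %d reflectance value(s) below %g", tiny.sum(), _REFLECTANCE_FLOOR
        )
        values = np.maximum(values, _REFLECTANCE_FLOOR)
    return values


def base_transform(
    values: np.ndarray, base: str, wavelengths: np.ndarray | None = None
) -> np.ndarray:
    """Elementwise base transform: identity, ``1/R`` or ``-log10 R``."""
    values = np.asarray(values, dtype=float)
    if base == "reflectance":
        return values.copy()
    values = _clip_positive(values, wavelengths)
    if base == "reciprocal":
        return 1.0 / values
    if base == "pseudo_absorbance":
        return -np.log10(values)
    raise InputError(f"unknown base transform {base!r}")


def sg_filter(
    values: np.ndarray, window: int = SG_WINDOW, polyorder: int = SG_POLYORDER
) -> np.ndarray:
    """Savitzky--Golay smoothing along the waveband axis.

    Output length equals input length; edges are handled by mirror
    padding, which leaves interior points equal to the plain
    least-squares local polynomial fit.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] < window:
        raise InputError(
            f"need at least {window} wavebands for SG filtering, "
            f"got {values.shape[-1]}"
        )
    return savgol_filter(values, window, polyorder, axis=-1, mode="mirror")


def snv_transform(values: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (row) mean 0 / sd 1.

    Uses the sample standard deviation (ddof=1), the chemometric
    convention for SNV.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=-1, keepdims=True)
    sd = values.std(axis=-1, keepdims=True, ddof=1)
    if np.any(sd == 0):
        raise DegenerateDataError("zero-variance spectrum in SNV transform")
    return (values - mean) / sd


def restrict_valid_range(
    wavelengths: np.ndarray,
    values: np.ndarray,
    valid_range: tuple[float, float] = VALID_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict spectra to the closed valid interval (default 980-2,200 nm)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    lo, hi = valid_range
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    if not mask.any():
        raise InputError(f"no wavebands inside the valid range {valid_range}")
    n = int(mask.sum())
    if n != VALID_RANGE_BANDS:
        logger.warning(
            "valid range holds %d wavebands, not the reference %d; proceeding",
            n,
            VALID_RANGE_BANDS,
        )
    return wavelengths[mask], np.asarray(values, dtype=float)[..., mask]


def make_variant(
    wavelengths: np.ndarray,
    values: np.ndarray,
    spec: PreprocessSpec,
    valid_range: tuple[float, float] = VALID_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one preprocessing recipe to raw reflectance spectra.

    Returns the valid-range wavelength axis and the transformed values.
    """
    wl, vals = restrict_valid_range(wavelengths, values, valid_range)
    vals = base_transform(vals, spec.base, wl)
    steps = ["sg", "snv"] if spec.sg_first else ["snv", "sg"]
    for step in steps:
        if step == "sg" and spec.sg:
            vals = sg_filter(vals)
        elif step == "snv" and spec.snv:
            vals = snv_transform(vals)
    return wl, vals


def make_all_variants(
    spectra: SpectraMatrix,
    sg_first: bool = True,
    valid_range: tuple[float, float] = VALID_RANGE,
) -> dict[int, SpectraMatrix]:
    """Build all twelve variant matrices from raw reflectance.

    Returns a dict keyed 1..12 with a consistent waveband axis.
    """
    out: dict[int, SpectraMatrix] = {}
    for index in range(1, 13):
        spec = PreprocessSpec.from_index(index, sg_first=sg_first)
        wl, vals = make_variant(
            spectra.wavelengths, spectra.values, spec, valid_range
        )
        out[index] = SpectraMatrix(
            wavelengths=wl, values=vals, spec=spec, seed_ids=spectra.seed_ids
        )
    return out


# ---------------------------------------------------------------------------
# Tabular I/O

_META_COLUMNS = ("seed_id", "capture", "label")


def write_spectra_table(
    path,
    spectra: SpectraMatrix,
    labels: np.ndarray | None = None,
    capture_id: np.ndarray | None = None,
    float_format: str = "%.10g",
) -> None:
    """Write one-seed-per-row delimited text with a wavelength header.

    Columns: ``seed_id``, ``capture``, ``label`` (+1 eligible / -1
    ineligible / 0 unknown), then one column per waveband (nm).
    """
    n = spectra.n_seeds
    seed_ids = (
        spectra.seed_ids if spectra.seed_ids is not None else np.arange(n)
    )
    meta = pd.DataFrame(
        {
            "seed_id": np.asarray(seed_ids),
            "capture": np.ones(n, dtype=int)
            if capture_id is None
            else np.asarray(capture_id, dtype=int),
            "label": np.zeros(n, dtype=int)
            if labels is None
            else np.asarray(labels, dtype=int),
        }
    )
    bands = pd.DataFrame(
        spectra.values, columns=[f"{wl:.10g}" for wl in spectra.wavelengths]
    )
    pd.concat([meta, bands], axis=1).to_csv(
        path, index=False, float_format=float_format
    )


def read_spectra_table(path):
    """Read a spectra table written by :func:`write_spectra_table`.

    Returns ``(SpectraMatrix, labels, capture_id)``; labels are 0 when
    the table carries no eligibility information.
    """
    from .errors import FormatError

    frame = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"spectra table {path} lacks column(s) {missing}")
    band_cols = [c for c in frame.columns if c not in _META_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise InputError(f"non-numeric waveband column in {path}: {exc}") from exc
    spectra = SpectraMatrix(
        wavelengths=wavelengths,
        values=frame[band_cols].to_numpy(dtype=float),
        seed_ids=frame["seed_id"].to_numpy(),
    )
    labels = frame["label"].to_numpy(dtype=int)
    capture = frame["capture"].to_numpy(dtype=int)
    bad = ~np.isin(labels, (-1, 0, 1))
    if bad.any():
        raise InputError(f"labels must be in {{-1, 0, 1}}; offending row {bad.argmax()}")
    return spectra, labels, capture
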