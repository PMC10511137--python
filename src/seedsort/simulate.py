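"""Synthetic data: the hypothetical-model thought experiment and
planted-signal seed spectra / hypercubes for end-to-end testing.

The thought experiment evaluates the sorting metrics on three
hypothetical discriminant models of graded skill -- near-perfect (NP),
medium- (MP) and poor-performance (PP) -- that score eligible and
ineligible seeds from class-conditional normal distributions with a
common sd of 0.25 and symmetric means (+-1, +-0.2 and +-0.05).  The
canonical batches hold 65,535 seeds at initial eligibility rates of
80% (52,428 / 13,107) and 60% (39,321 / 26,214).

An analytic oracle computes the standard condition of any normal
mixture by root finding, independent of simulation.

The spectra generator emulates what the method sees in practice:
smooth per-seed NIR reflectance curves with class-dependent Gaussian
absorption dips at a few informative wavebands, per-seed baseline
offset/slope variation, iid measurement noise, and paired duplicate
captures of every tray (imaged twice for mutual outer
cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import DegenerateDataError, InputError
from .metrics import ScoredBatch
from .preprocess import SpectraMatrix

__all__ = [
    "HypotheticalModelSpec",
    "SyntheticSpectraSpec",
    "thought_experiment_specs",
    "simulate_hypothetical_scores",
    "analytic_standard_condition",
    "generate_synthetic_dataset",
    "generate_synthetic_cube",
]

#: Class-conditional score means (eligible, ineligible) of the three
#: hypothetical models; all share sd 0.25.
SCORE_MODELS = {"NP": (1.0, -1.0), "MP": (0.2, -0.2), "PP": (0.05, -0.05)}

#: Canonical thought-experiment batches: iP -> (n eligible, n ineligible).
BATCHES = {0.8: (52428, 13107), 0.6: (39321, 26214)}

HYPOTHETICAL_SIGMA = 0.25


@dataclass(frozen=True)
class HypotheticalModelSpec:
    """A class-conditional normal score model applied to one batch."""

    name: str
    mu_ok: float
    mu_ng: float
    sigma: float
    n_ok: int
    n_ng: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InputError("sigma must be positive")
        if self.n_ok + self.n_ng <= 0:
            raise InputError("batch must contain seeds")

    @property
    def iP(self) -> float:
        return self.n_ok / (self.n_ok + self.n_ng)

    @property
    def n(self) -> int:
        return self.n_ok + self.n_ng


def thought_experiment_specs() -> list[HypotheticalModelSpec]:
    """The six canonical (batch, model) rows: {80%, 60%} x {NP, MP, PP}."""
    out = []
    for _, (n_ok, n_ng) in sorted(BATCHES.items(), reverse=True):
        for name, (mu_ok, mu_ng) in SCORE_MODELS.items():
            out.append(
                HypotheticalModelSpec(
                    name=name,
                    mu_ok=mu_ok,
                    mu_ng=mu_ng,
                    sigma=HYPOTHETICAL_SIGMA,
                    n_ok=n_ok,
                    n_ng=n_ng,
                )
            )
    return out


def simulate_hypothetical_scores(
    spec: HypotheticalModelSpec, rng=None
) -> ScoredBatch:
    """Draw one realization of the hypothetical scoring experiment."""
    rng = np.random.default_rng(rng)
    scores = np.concatenate(
        [
            rng.normal(spec.mu_ok, spec.sigma, spec.n_ok),
            rng.normal(spec.mu_ng, spec.sigma, spec.n_ng),
        ]
    )
    labels = np.concatenate(
        [np.ones(spec.n_ok, dtype=int), -np.ones(spec.n_ng, dtype=int)]
    )
    return ScoredBatch(scores=scores, labels=labels)


def analytic_standard_condition(
    spec: HypotheticalModelSpec, xtol: float = 1e-10
) -> tuple[float, float]:
    """Population standard condition of the normal mixture.

    ``sLST`` solves ``iP * S_ok(t) + (1 - iP) * S_ng(t) = iP`` where
    ``S`` are the class survival functions (the population recovery rate
    at threshold ``t`` equals ``iP``); ``sP = S_ok(sLST)``.
    """
    iP = spec.iP
    if not 0.0 < iP < 1.0:
        raise DegenerateDataError("batch holds a single class")

    def g(t: float) -> float:
        return (
            iP * norm.sf((t - spec.mu_ok) / spec.sigma)
            + (1 - iP) * norm.sf((t - spec.mu_ng) / spec.sigma)
            - iP
        )

    lo = min(spec.mu_ok, spec.mu_ng) - 12 * spec.sigma
    hi = max(spec.mu_ok, spec.mu_ng) + 12 * spec.sigma
    if g(lo) * g(hi) > 0:
        raise DegenerateDataError("no standard-condition root in bracket")
    slst = brentq(g, lo, hi, xtol=xtol)
    return float(slst), float(norm.sf((slst - spec.mu_ok) / spec.sigma))


# ---------------------------------------------------------------------------
# Synthetic seed spectra with planted class signal


@dataclass
class SyntheticSpectraSpec:
    """Recipe for labeled synthetic seed reflectance spectra.

    Defaults emulate the qualitative structure of real seed spectra on
    the 980--2,200 nm valid range: reflectance around 0.45 with gentle
    curvature, informative Gaussian absorption dips centered near the
    C-H (1,200 / 1,730 nm) and amide (1,920 nm) overtone bands that are
    deeper for ineligible seeds, per-seed baseline offset and tilt, and
    band-wise measurement noise.  Two captures per tray are emulated by
    re-drawing the measurement noise plus a small capture-level offset.
    """

    n_seeds: int = 400
    iP: float = 0.7
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.linspace(980.0, 2200.0, 201)
    )
    informative_centers: tuple = (1200.0, 1730.0, 1920.0)
    informative_width: float = 18.0  # nm, Gaussian sd of each dip
    effect_size: float = 0.03  # extra dip depth (reflectance) when ineligible
    feature_depth_sd: float = 0.01  # per-seed, per-feature depth variability
    noise_sd: float = 0.01
    baseline_offset_sd: float = 0.02
    baseline_slope_sd: float = 0.01  # over the full wavelength span
    capture_noise_sd: float = 0.005
    base_level: float = 0.45

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if not 0.0 < self.iP < 1.0:
            raise InputError("iP must lie in (0, 1)")
        lo, hi = self.wavelengths.min(), self.wavelengths.max()
        if any(not lo <= c <= hi for c in self.informative_centers):
            raise InputError("informative band centers outside wavelength grid")

    @property
    def dip_profile(self) -> np.ndarray:
        """Unit-depth absorption profile of the informative bands."""
        wl = self.wavelengths
        prof = np.zeros_like(wl)
        for c in self.informative_centers:
            prof += np.exp(-0.5 * ((wl - c) / self.informative_width) ** 2)
        return prof

    @property
    def planted_bands(self) -> np.ndarray:
        """Indices where the class-mean difference exceeds half its peak."""
        prof = self.dip_profile
        return np.flatnonzero(prof >= 0.5 * prof.max())

    def feature_coverage(self, support) -> float:
        """Fraction of planted absorption features hit by a waveband support.

        An absorption band is a wavelength *region*: neighbouring
        channels inside one Gaussian dip are nearly collinear, so a
        sparse model that keeps any channel within a feature's half-max
        window has recovered that feature.  Returns the covered fraction
        of the planted features.
        """
        support = np.asarray(support, dtype=int)
        if support.size == 0:
            return 0.0
        wl_sel = self.wavelengths[support]
        half_width = self.informative_width * np.sqrt(2 * np.log(2.0))
        hits = [
            bool(np.any(np.abs(wl_sel - c) <= half_width))
            for c in self.informative_centers
        ]
        return float(np.mean(hits))


def _base_curve(spec: SyntheticSpectraSpec) -> np.ndarray:
    wl = spec.wavelengths
    u = (wl - wl.min()) / (wl.max() - wl.min())
    # smooth, slightly convex reflectance with a broad water-band dip
    return (
        spec.base_level
        + 0.05 * np.sin(np.pi * u)
        - 0.06 * np.exp(-0.5 * ((wl - 1940.0) / 90.0) ** 2)
    )


def generate_synthetic_dataset(spec: SyntheticSpectraSpec, rng=None):
    """Labeled paired-capture dataset with known informative bands.

    Returns a :class:`seedsort.model.LabeledDataset` with ``2 * n_seeds``
    rows (captures 1 and 2 of every seed) and a ``planted_bands``
    attribute holding the ground-truth informative band indices.
    """
    from .model import LabeledDataset  # local import to avoid a cycle

    rng = np.random.default_rng(rng)
    n = spec.n_seeds
    n_ok = int(round(spec.iP * n))
    labels = np.r_[np.ones(n_ok, dtype=int), -np.ones(n - n_ok, dtype=int)]
    rng.shuffle(labels)

    base = _base_curve(spec)
    wl = spec.wavelengths
    # one Gaussian absorption profile per informative feature
    feats = np.stack(
        [
            np.exp(-0.5 * ((wl - c) / spec.informative_width) ** 2)
            for c in spec.informative_centers
        ]
    )  # (n_features, n_bands)
    # every seed absorbs at the informative bands; ineligible seeds more
    # so.  Depths vary seed-to-seed and feature-to-feature (biochemical
    # composition is not identical across seeds), so no single feature
    # is a perfect surrogate of eligibility.
    depth = (
        0.02
        + np.where(labels == -1, spec.effect_size, 0.0)[:, None]
        + rng.normal(0.0, spec.feature_depth_sd, (n, feats.shape[0]))
    )  # (n_seeds, n_features)
    offset = rng.normal(0.0, spec.baseline_offset_sd, n)
    slope = rng.normal(0.0, spec.baseline_slope_sd, n)
    u = (wl - wl.mean()) / (wl.max() - wl.min())
    seed_true = (
        base[None, :]
        - depth @ feats
        + offset[:, None]
        + slope[:, None] * u[None, :]
    )

    rows, caps = [], []
    for capture in (1, 2):
        cap_shift = rng.normal(0.0, spec.capture_noise_sd, (n, 1))
        noise = rng.normal(0.0, spec.noise_sd, seed_true.shape)
        rows.append(np.clip(seed_true + cap_shift + noise, 1e-4, None))
        caps.append(np.full(n, capture, dtype=int))

    values = np.vstack(rows)
    seed_ids = np.r_[np.arange(n), np.arange(n)]
    spectra = SpectraMatrix(
        wavelengths=spec.wavelengths.copy(), values=values, seed_ids=seed_ids
    )
    dataset = LabeledDataset(
        spectra=spectra,
        y=np.r_[labels, labels],
        seed_ids=seed_ids,
        capture_id=np.concatenate(caps),
    )
    dataset.planted_bands = spec.planted_bands
    dataset.spectra_spec = spec
    return dataset


def generate_synthetic_cube(
    spec: SyntheticSpectraSpec,
    layout: tuple[int, int] | None = None,
    cell: int = 16,
    radius: tuple[int, int] = (5, 4),
    background: float = 0.02,
    pixel_noise_sd: float = 0.005,
    rng=None,
):
    """Hyperspectral tray image with elliptical seeds of known spectra.

    Returns ``(cube, regions, labels)`` where ``cube`` is a reflectance
    :class:`seedsort.hypercube.HyperCube`, ``regions`` the planted
    ground-truth pixel sets, and ``labels`` the per-seed eligibility.
    """
    from .hypercube import HyperCube, SeedRegion

    rng = np.random.default_rng(rng)
    n = spec.n_seeds
    if layout is None:
        cols = int(np.ceil(np.sqrt(n))) if n else 1
        layout = (int(np.ceil(n / cols)) if n else 1, cols)
    n_rows, n_cols = layout
    if n_rows * n_cols < n:
        raise InputError(f"layout {layout} cannot hold {n} seeds")
    ry, rx = radius
    if 2 * ry + 2 > cell or 2 * rx + 2 > cell:
        raise InputError("seed radius too large for the cell size: seeds overlap")

    dataset = generate_synthetic_dataset(spec, rng) if n else None
    lines, samples = n_rows * cell, n_cols * cell
    bands = spec.wavelengths.size
    data = np.full((lines, samples, bands), background)
    data += rng.normal(0.0, pixel_noise_sd / 2, data.shape)

    yy, xx = np.mgrid[0:lines, 0:samples]
    regions, labels = [], []
    for i in range(n):
        r, c = divmod(i, n_cols)
        cy, cx = r * cell + cell // 2, c * cell + cell // 2
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        # capture-1 spectrum of seed i, plus per-pixel noise
        spectrum = dataset.spectra.values[i]
        data[mask] = spectrum[None, :] + rng.normal(
            0.0, pixel_noise_sd, (int(mask.sum()), bands)
        )
        coords = np.argwhere(mask)
        regions.append(
            SeedRegion(
                id=i,
                pixels=coords,
                centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
            )
        )
        labels.append(int(dataset.y[i]))

    cube = HyperCube(
        data=np.clip(data, 0.0, None),
        wavelengths=spec.wavelengths.copy(),
        kind="reflectance",
    )
    # ground truth for extraction tests: the planted per-seed spectra
    cube.planted_spectra = (
        dataset.spectra.values[:n] if n else np.empty((0, bands))
    )
    return cube, regions, np.asarray(labels, dtype=int)
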