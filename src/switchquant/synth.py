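"""Synthetic-data generators for every pipeline stage.

These generators stand in for the study's instruments: overdamped
(Brownian) Langevin dynamics on a known 1-D potential replaces the
all-atom umbrella-sampling engine, log-normal mixtures emulate
list-mode cytometry acquisitions, a log-linear Ct model emulates qPCR
runs, and disk-on-background images emulate fluorescence micrographs.
Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy.integrate import quad

from .cyto import EventTable
from .imaging import LabeledImage
from .pmf import PmfProfile, Thermo, UmbrellaWindow, WhamGrid

__all__ = [
    "Potential1D",
    "LangevinSpec",
    "PopulationSpec",
    "CytometryPanelSpec",
    "QpcrSimSpec",
    "ImageSimSpec",
    "simulate_umbrella",
    "analytic_pmf",
    "simulate_cytometry",
    "simulate_qpcr",
    "simulate_microscopy",
    "double_well",
    "harmonic_potential",
]


# ---------------------------------------------------------------------------
# 1-D potential energy surfaces


@dataclass(frozen=True)
class Potential1D:
    """Sum of polynomial and Gaussian-well terms, in kcal/mol vs angstrom.

    ``terms`` is a tuple of ``("polynomial", coeffs)`` with coefficients of
    ascending powers of x, and/or ``("gaussian_well", depth, center, width)``
    contributing ``-depth * exp(-(x - center)^2 / (2 width^2))``.
    """

    terms: tuple

    def __post_init__(self) -> None:
        if len(self.terms) == 0:
            raise ValueError("potential needs at least one term")
        for t in self.terms:
            kind = t[0]
            if kind == "polynomial":
                if len(np.atleast_1d(t[1])) == 0:
                    raise ValueError("polynomial term needs coefficients")
            elif kind == "gaussian_well":
                _, depth, _, width = t
                if width <= 0:
                    raise ValueError("gaussian well width must be > 0")
            else:
                raise ValueError(f"unknown term kind {kind!r}")

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        u = np.zeros_like(x)
        for t in self.terms:
            if t[0] == "polynomial":
                u = u + npoly.polyval(x, np.asarray(t[1], dtype=float))
            else:
                _, depth, center, width = t
                u = u - depth * np.exp(-((x - center) ** 2) / (2.0 * width**2))
        return u

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for t in self.terms:
            if t[0] == "polynomial":
                g = g + npoly.polyval(x, npoly.polyder(np.asarray(t[1], dtype=float)))
            else:
                _, depth, center, width = t
                g = g + depth * (x - center) / width**2 * np.exp(
                    -((x - center) ** 2) / (2.0 * width**2)
                )
        return g

    def shifted(self, offset: float) -> "Potential1D":
        """Return the potential plus a constant (gauge change)."""
        return Potential1D(terms=self.terms + (("polynomial", (float(offset),)),))


def harmonic_potential(stiffness: float, center: float = 0.0) -> Potential1D:
    """U(x) = (1/2) stiffness (x - center)^2 as a polynomial term."""
    c = center
    coeffs = (0.5 * stiffness * c * c, -stiffness * c, 0.5 * stiffness)
    return Potential1D(terms=(("polynomial", coeffs),))


def double_well(c1: float = 5.0, c2: float = 9.0, barrier: float = 3.0) -> Potential1D:
    """Quartic double well a (x-c1)^2 (x-c2)^2 with the stated barrier height.

    The barrier sits midway between the minima: a ((c2-c1)/2)^4 = barrier.
    Defaults give a 3 kcal/mol barrier with minima at 5 and 9 angstrom,
    spanning the 4-10 angstrom window ladder.
    """
    a = barrier / ((c2 - c1) / 2.0) ** 4
    root1 = np.asarray([-c1, 1.0])
    root2 = np.asarray([-c2, 1.0])
    coeffs = a * npoly.polymul(npoly.polymul(root1, root1), npoly.polymul(root2, root2))
    return Potential1D(terms=(("polynomial", tuple(coeffs)),))


# ---------------------------------------------------------------------------
# Overdamped Langevin umbrella sampling


@dataclass(frozen=True)
class LangevinSpec:
    """Euler-Maruyama integration of overdamped Langevin dynamics.

    Parameters
    ----------
    diffusion_coefficient : float
        D in angstrom^2/ns.
    timestep : float
        dt in ns.  Stable when dt < 1 / (beta * D * max|U''|).
    n_steps : int
        Integration steps per window.
    sampling_interval : int
        Steps between saved points; the saved series has spacing
        ``timestep * sampling_interval`` ns.
    x_init : float or None
        Common starting coordinate; None starts each window at its own
        bias center.
    seed : int
        Seeds all noise for the call.
    """

    diffusion_coefficient: float = 1.0
    timestep: float = 0.002
    n_steps: int = 15_000
    sampling_interval: int = 1
    x_init: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be > 0")
        if self.n_steps < self.sampling_interval:
            raise ValueError("n_steps must be >= sampling_interval")
        if self.sampling_interval < 1:
            raise ValueError("sampling_interval must be >= 1")


def simulate_umbrella(
    potential: Potential1D,
    windows: Sequence[tuple[float, float]],
    spec: LangevinSpec,
    thermo: Thermo,
) -> list[UmbrellaWindow]:
    """Sample each harmonically restrained window by Brownian dynamics.

    The update is ``x <- x - beta D U'(x) dt + sqrt(2 D dt) xi`` with
    standard-normal xi and ``U = U0 + (1/2) k (x - center)^2``.  All
    windows integrate in lockstep from one seeded generator, so a given
    spec always reproduces the identical output.

    Raises
    ------
    FloatingPointError
        If the coordinate or energy becomes non-finite, naming the step
        and window.
    """
    if len(windows) == 0:
        raise ValueError("windows must be non-empty")
    centers = np.asarray([w[0] for w in windows], dtype=float)
    springs = np.asarray([w[1] for w in windows], dtype=float)
    if np.any(springs < 0):
        raise ValueError("spring constants must be >= 0")

    rng = np.random.default_rng(spec.seed)
    D = spec.diffusion_coefficient
    dt = spec.timestep
    drift = thermo.beta * D * dt
    noise_amp = math.sqrt(2.0 * D * dt)

    x = np.full(len(windows), spec.x_init, dtype=float) if spec.x_init is not None else centers.copy()
    n_saved = spec.n_steps // spec.sampling_interval
    saved = np.empty((n_saved, len(windows)))

    chunk = 50_000
    step = 0
    save_idx = 0
    while step < spec.n_steps:
        n = min(chunk, spec.n_steps - step)
        xi = rng.standard_normal((n, len(windows)))
        for j in range(n):
            grad = potential.gradient(x) + springs * (x - centers)
            x = x - drift * grad + noise_amp * xi[j]
            step += 1
            if not np.all(np.isfinite(x)):
                bad = int(np.flatnonzero(~np.isfinite(x))[0])
                raise FloatingPointError(
                    f"non-finite coordinate at step {step} in window {bad} "
                    f"(center {centers[bad]})"
                )
            if step % spec.sampling_interval == 0:
                saved[save_idx] = x
                save_idx += 1

    interval_ns = dt * spec.sampling_interval
    return [
        UmbrellaWindow(
            center=float(centers[w]),
            spring_constant=float(springs[w]),
            series=saved[:, w].copy(),
            sampling_interval_ns=interval_ns,
        )
        for w in range(len(windows))
    ]


def analytic_pmf(potential: Potential1D, grid: WhamGrid, thermo: Thermo) -> PmfProfile:
    """Ground-truth binned free energies by numeric quadrature.

    F_i = -kT ln integral_bin_i exp(-beta U0(x)) dx, offset so the
    minimum is zero; errors are zero by construction.  Serves as the
    oracle for parameter-recovery tests.
    """
    beta = thermo.beta
    # subtract the in-range minimum before exponentiating to avoid underflow
    xs = np.linspace(grid.lower, grid.upper, 2001)
    u0 = float(np.min(potential.energy(xs)))
    edges = grid.edges
    integrals = np.empty(grid.n_bins)
    for i in range(grid.n_bins):
        integrals[i], _ = quad(
            lambda x: math.exp(-beta * (float(potential.energy(x)) - u0)),
            edges[i],
            edges[i + 1],
            limit=200,
        )
    if np.all(integrals <= 0):
        raise ValueError("Boltzmann weight underflows in every bin")
    with np.errstate(divide="ignore"):
        F = np.where(integrals > 0, -thermo.kT * np.log(np.where(integrals > 0, integrals, 1.0)), np.nan)
    F = F - np.nanmin(F)
    return PmfProfile(
        bin_centers=grid.centers.copy(),
        F=F,
        sigma_F=np.zeros(grid.n_bins),
        n_blocks=0,
    )


# ---------------------------------------------------------------------------
# Flow cytometry


@dataclass(frozen=True)
class PopulationSpec:
    """Log-normal event population: bivariate scatter plus fluorescence.

    ``fsc_mu``/``ssc_mu`` are natural-log medians of the scatter channels,
    ``corr`` their log-space correlation; fluorescence is univariate
    log-normal with median ``fl_median``.
    """

    fsc_mu: float
    fsc_sigma: float
    ssc_mu: float
    ssc_sigma: float
    corr: float
    fl_median: float
    fl_sigma: float

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        cov = np.array(
            [
                [self.fsc_sigma**2, self.corr * self.fsc_sigma * self.ssc_sigma],
                [self.corr * self.fsc_sigma * self.ssc_sigma, self.ssc_sigma**2],
            ]
        )
        scatter = rng.multivariate_normal([self.fsc_mu, self.ssc_mu], cov, size=n)
        fl = rng.lognormal(math.log(self.fl_median), self.fl_sigma, size=n)
        return pd.DataFrame(
            {"FSC-H": np.exp(scatter[:, 0]), "SSC-H": np.exp(scatter[:, 1]), "FL1-H": fl}
        )


_CELL_SCATTER = dict(fsc_mu=math.log(5e4), fsc_sigma=0.25, ssc_mu=math.log(2e4), ssc_sigma=0.30, corr=0.6)

DEFAULT_OFF = PopulationSpec(**_CELL_SCATTER, fl_median=100.0, fl_sigma=0.35)
DEFAULT_ON = PopulationSpec(**_CELL_SCATTER, fl_median=5000.0, fl_sigma=0.35)
#: Broad, low-scatter debris so the density gate has something to exclude.
DEFAULT_DEBRIS = PopulationSpec(
    fsc_mu=math.log(8e3), fsc_sigma=0.8, ssc_mu=math.log(5e3), ssc_sigma=0.8, corr=0.2,
    fl_median=100.0, fl_sigma=0.35,
)


@dataclass(frozen=True)
class CytometryPanelSpec:
    """One synthetic list-mode acquisition: an OFF/ON mixture plus debris."""

    n_events: int = 10_000
    on_fraction: float = 0.0
    off_population: PopulationSpec = DEFAULT_OFF
    on_population: PopulationSpec = DEFAULT_ON
    debris_population: PopulationSpec = DEFAULT_DEBRIS
    debris_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.on_fraction <= 1.0:
            raise ValueError("on_fraction must be in [0, 1]")
        if not 0.0 <= self.debris_fraction < 1.0:
            raise ValueError("debris_fraction must be in [0, 1)")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.off_population.fl_median == self.on_population.fl_median:
            raise ValueError("OFF and ON fluorescence medians must be distinct")


def simulate_cytometry(
    spec: CytometryPanelSpec,
    sample_id: str = "sample",
    experiment_id: str = "expt",
    role: str = "test",
) -> EventTable:
    """Draw an event table; rows carry their true population label.

    Debris events are allocated first (``round(debris_fraction * n)``),
    then each remaining event is ON with probability ``on_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    n_debris = int(round(spec.debris_fraction * n))
    n_cells = n - n_debris
    is_on = rng.random(n_cells) < spec.on_fraction

    parts = []
    n_on = int(is_on.sum())
    n_off = n_cells - n_on
    if n_off:
        df = spec.off_population.sample(n_off, rng)
        df["true_population"] = "off"
        parts.append(df)
    if n_on:
        df = spec.on_population.sample(n_on, rng)
        df["true_population"] = "on"
        parts.append(df)
    if n_debris:
        df = spec.debris_population.sample(n_debris, rng)
        df["true_population"] = "debris"
        parts.append(df)
    data = pd.concat(parts, ignore_index=True)
    # shuffle so population blocks are not contiguous, as on a cytometer
    data = data.iloc[rng.permutation(len(data))].reset_index(drop=True)
    return EventTable(data=data, sample_id=sample_id, experiment_id=experiment_id, role=role)


# ---------------------------------------------------------------------------
# qPCR


#: Mixing ratios used for the excision standard curve.
DEFAULT_CALIBRATION_FRACTIONS = (0.0, 0.005, 0.01, 0.05, 0.10, 0.50, 0.70, 0.90, 1.0)


@dataclass(frozen=True)
class QpcrSimSpec:
    """Log-linear Ct model: Ct = intercept + slope log10(fraction) + noise.

    ``slope`` is cycles per decade of template (about -3.32 at 100%
    amplification efficiency); zero fractions never amplify and are
    emitted with a no-amplification marker (NaN Ct).
    """

    true_fraction: float = 0.3
    calibration_fractions: tuple = DEFAULT_CALIBRATION_FRACTIONS
    intercept_Ct: float = 20.0
    slope: float = -3.3219
    noise_sd: float = 0.15
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("slope must be < 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.true_fraction <= 1.0:
            raise ValueError("true_fraction must be in [0, 1]")
        if not any(f > 0 for f in self.calibration_fractions):
            raise ValueError("need at least one nonzero calibration fraction")


def _ct(fraction: float, spec: QpcrSimSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if fraction <= 0:
        return np.full(n, np.nan)
    base = spec.intercept_Ct + spec.slope * math.log10(fraction)
    return base + spec.noise_sd * rng.standard_normal(n)


def simulate_qpcr(spec: QpcrSimSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Return (calibration table, sample Ct replicates).

    The calibration table has columns ``known_quantity``, ``replicate``,
    ``Ct`` (NaN marks no amplification).  Sample Cts are drawn at
    ``true_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for frac in spec.calibration_fractions:
        cts = _ct(frac, spec, rng, spec.replicates)
        for r, ct in enumerate(cts):
            rows.append({"known_quantity": frac, "replicate": r, "Ct": ct})
    calibration = pd.DataFrame(rows)
    sample_cts = _ct(spec.true_fraction, spec, rng, spec.replicates)
    return calibration, sample_cts


# ---------------------------------------------------------------------------
# Microscopy


@dataclass(frozen=True)
class ImageSimSpec:
    """Disks of stated intensity on a noisy constant background."""

    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 12
    cell_radius: int = 9
    cell_intensities: tuple = tuple(range(100, 1300, 100))
    background_level: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0
    margin: int = 3

    def __post_init__(self) -> None:
        if self.n_cells > len(self.cell_intensities):
            raise ValueError("need one intensity per cell")
        if any(v < 0 for v in self.cell_intensities):
            raise ValueError("intensities must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")


class PlacementError(RuntimeError):
    pass


def simulate_microscopy(spec: ImageSimSpec, max_retries: int = 10_000) -> LabeledImage:
    """Render non-overlapping cells (label 1..n) over background (label 0).

    Pixel value = background + cell intensity + N(0, noise_sd), clipped at
    zero and rounded to 16-bit.  Placement is rejection-sampled with a
    retry bound; failure raises :class:`PlacementError`.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    r = spec.cell_radius
    lo = r + spec.margin
    min_sep = 2 * r + spec.margin

    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < spec.n_cells:
        cy = int(rng.integers(lo, h - lo))
        cx = int(rng.integers(lo, w - lo))
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append((cy, cx))
        else:
            tries += 1
            if tries > max_retries:
                raise PlacementError(
                    f"placed {len(centers)} of {spec.n_cells} cells after {max_retries} retries"
                )

    yy, xx = np.mgrid[0:h, 0:w]
    image = np.full((h, w), float(spec.background_level))
    mask = np.zeros((h, w), dtype=np.uint16)
    for label, (cy, cx) in enumerate(centers, start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        image[disk] += spec.cell_intensities[label - 1]
        mask[disk] = label
    if spec.noise_sd > 0:
        image = image + spec.noise_sd * rng.standard_normal((h, w))
    image = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    return LabeledImage(image=image, mask=mask)
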