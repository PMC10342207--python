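"""Ground-truthed synthetic TCSPC image generation.

Emulates two-channel (NAD(P)H, FAD) time-domain FLIM acquisitions at an 80 MHz
repetition rate: disk-shaped cells on a dark background, one biexponential
decay parameter draw per cell per channel, circular IRF convolution, and
independent Poisson photon noise per pixel and time channel.  Every field is
emitted together with its label mask and a ground-truth table so downstream
fitting, phasor and classification stages can be validated without microscope
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import BiexpParams, IRFCurve, TCSPCImage, TimeGrid
from .decay_model import mean_lifetime, model_curve
from .phasor import OMEGA_80MHZ, phasor_of_biexp, phasor_of_single_exp

__all__ = [
    "ChannelDecaySpec",
    "CellGeometry",
    "PhenotypeSpec",
    "SimulatedField",
    "SimulatedDataset",
    "make_irf",
    "simulate_decay",
    "simulate_field",
    "simulate_dataset",
    "solve_matched_decomposition",
    "matched_phasor_pair",
    "large_shift_pair",
    "macrophage_like_phenotypes",
    "gaussian_feature_table",
]

#: Hard parameter ranges used when truncating per-cell draws.
_ALPHA1_RANGE = (0.01, 0.99)
_TAU1_RANGE = (0.06, 1.45)
_TAU2_RANGE = (1.05, 7.9)

TRUTH_COLUMNS = ["cell_id", "phenotype", "channel", "alpha1", "tau1_ns", "tau2_ns", "tau_m_ns"]


@dataclass(frozen=True)
class ChannelDecaySpec:
    """Per-cell decay parameter distribution for one spectral channel.

    Each cell draws (alpha1, tau1, tau2) from independent normals with the
    given means and standard deviations, truncated to physically valid ranges
    (0 < alpha1 < 1, 0 < tau1 < tau2).
    """

    alpha1_mean: float
    tau1_mean: float
    tau2_mean: float
    alpha1_sd: float = 0.02
    tau1_sd: float = 0.03
    tau2_sd: float = 0.06

    def __post_init__(self) -> None:
        if min(self.alpha1_sd, self.tau1_sd, self.tau2_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        BiexpParams(self.alpha1_mean, self.tau1_mean, self.tau2_mean)  # validates means

    def draw(self, rng: np.random.Generator) -> BiexpParams:
        a1 = float(np.clip(rng.normal(self.alpha1_mean, self.alpha1_sd), *_ALPHA1_RANGE))
        t1 = float(np.clip(rng.normal(self.tau1_mean, self.tau1_sd), *_TAU1_RANGE))
        t2 = float(np.clip(rng.normal(self.tau2_mean, self.tau2_sd), *_TAU2_RANGE))
        if t2 <= t1 + 0.1:
            t2 = t1 + 0.1
        return BiexpParams(alpha1=a1, tau1=t1, tau2=t2)


@dataclass(frozen=True)
class CellGeometry:
    """Disk-cell placement parameters (pixel units)."""

    n_cells: int = 15
    radius_range: tuple = (3.0, 6.0)
    min_separation: float = 2.0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.radius_range
        if not 0 < lo <= hi:
            raise ValueError("radius_range must satisfy 0 < min <= max")


@dataclass(frozen=True)
class PhenotypeSpec:
    """One simulated cell phenotype: decay distributions, brightness, geometry.

    ``photons_per_pixel`` is the expected signal photon count per in-cell pixel
    (default 5,000 — a well-exposed TCSPC acquisition after binning);
    ``background_rate`` is the expected dark count per time channel outside
    cells.
    """

    name: str
    nadph: ChannelDecaySpec
    fad: ChannelDecaySpec
    photons_per_pixel: float = 5000.0
    background_rate: float = 0.02
    geometry: CellGeometry = field(default_factory=CellGeometry)

    def __post_init__(self) -> None:
        if not self.photons_per_pixel > 0:
            raise ValueError("photons_per_pixel must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")

    def channel(self, channel_name: str) -> ChannelDecaySpec:
        return {"NADPH": self.nadph, "FAD": self.fad}[channel_name]


@dataclass(frozen=True)
class SimulatedField:
    """One simulated two-channel field with its mask and ground truth."""

    nadph: TCSPCImage
    fad: TCSPCImage
    mask: np.ndarray
    truth: pd.DataFrame
    phenotype: str
    field_id: int = 0


@dataclass(frozen=True)
class SimulatedDataset:
    fields: tuple
    truth: pd.DataFrame


def make_irf(grid: TimeGrid, fwhm: float = 0.3, center: float = 1.0) -> IRFCurve:
    """Gaussian instrument response sampled at channel centers, unit-sum.

    A Gaussian of the given full width at half maximum centered at ``center``
    ns stands in for a measured second-harmonic-generation IRF.
    """
    if not 0 < center < grid.period:
        raise ValueError(f"IRF center {center} ns outside the window (0, {grid.period})")
    if not fwhm > 0:
        raise ValueError(f"IRF fwhm must be positive, got {fwhm}")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = grid.channel_centers
    counts = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return IRFCurve(counts=counts / counts.sum(), grid=grid)


def simulate_decay(
    params: BiexpParams,
    irf: IRFCurve,
    photons: float,
    grid: TimeGrid,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One Poisson realization of a single-pixel decay histogram.

    The expectation is ``photons * (wrapped biexp (*) IRF) + params.background``
    per channel; each channel is an independent Poisson draw.
    """
    if photons < 0:
        raise ValueError("photons must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected = model_curve(params, irf, grid, amplitude=photons)
    return rng.poisson(expected).astype(np.int64)


def _place_cells(shape, geometry: CellGeometry, rng: np.random.Generator):
    """Rejection-sample non-overlapping disk centers/radii; raises if infeasible."""
    ny, nx = shape
    placed = []  # (cy, cx, r)
    attempts = 0
    while len(placed) < geometry.n_cells:
        if attempts >= geometry.max_attempts:
            raise RuntimeError(
                f"could not place {geometry.n_cells} non-overlapping cells of radius "
                f"{geometry.radius_range} with separation {geometry.min_separation} "
                f"on a {ny}x{nx} field after {geometry.max_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(*geometry.radius_range)
        cy = rng.uniform(r, ny - r)
        cx = rng.uniform(r, nx - r)
        if all(
            np.hypot(cy - py, cx - px) >= r + pr + geometry.min_separation
            for py, px, pr in placed
        ):
            placed.append((cy, cx, r))
    return placed


def simulate_field(
    specs,
    phenotype: str,
    image_shape=(64, 64),
    grid: TimeGrid | None = None,
    seed: int | np.random.SeedSequence = 0,
    irf: IRFCurve | None = None,
    field_id: int = 0,
) -> SimulatedField:
    """Simulate one two-channel field of the named phenotype.

    All pixels of a cell share that cell's drawn decay parameters per channel;
    off-cell pixels contain only Poisson background.  Mask labels run 1..n_cells
    and match the ground-truth table's cell ids exactly.
    """
    by_name = {s.name: s for s in ([specs] if isinstance(specs, PhenotypeSpec) else specs)}
    if phenotype not in by_name:
        raise KeyError(f"phenotype {phenotype!r} not among specs {sorted(by_name)}")
    spec = by_name[phenotype]
    grid = grid or TimeGrid()
    irf = irf or make_irf(grid)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    ny, nx = image_shape
    cells = _place_cells((ny, nx), spec.geometry, rng)
    mask = np.zeros((ny, nx), dtype=np.uint16)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for label, (cy, cx, r) in enumerate(cells, start=1):
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = label

    images = {}
    truth_rows = []
    for channel in ("NADPH", "FAD"):
        counts = rng.poisson(spec.background_rate, size=(ny, nx, grid.n_channels))
        for label in range(1, len(cells) + 1):
            params = spec.channel(channel).draw(rng)
            expected = model_curve(params, irf, grid, amplitude=spec.photons_per_pixel)
            inside = mask == label
            counts[inside] = rng.poisson(expected, size=(int(inside.sum()), grid.n_channels))
            truth_rows.append(
                {
                    "cell_id": label,
                    "phenotype": phenotype,
                    "channel": channel,
                    "alpha1": params.alpha1,
                    "tau1_ns": params.tau1,
                    "tau2_ns": params.tau2,
                    "tau_m_ns": mean_lifetime(params),
                }
            )
        images[channel] = TCSPCImage(
            counts=counts.astype(np.int64), grid=grid, channel_name=channel
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedField(
        nadph=images["NADPH"],
        fad=images["FAD"],
        mask=mask,
        truth=truth,
        phenotype=phenotype,
        field_id=field_id,
    )


def simulate_dataset(
    specs,
    n_fields_per_phenotype: int,
    grid: TimeGrid | None = None,
    seed: int = 0,
    image_shape=(64, 64),
    irf: IRFCurve | None = None,
) -> SimulatedDataset:
    """Simulate ``n_fields_per_phenotype`` fields for every phenotype spec.

    Per-field seeds are spawned deterministically from the master seed, so any
    field can be regenerated in isolation and the whole dataset is reproducible.
    """
    if n_fields_per_phenotype < 1:
        raise ValueError("n_fields_per_phenotype must be >= 1")
    specs = [specs] if isinstance(specs, PhenotypeSpec) else list(specs)
    grid = grid or TimeGrid()
    irf = irf or make_irf(grid)
    fields = []
    tables = []
    field_id = 0
    for spec in specs:
        for k in range(n_fields_per_phenotype):
            child = np.random.SeedSequence([int(seed), field_id])
            fld = simulate_field(
                specs, spec.name, image_shape, grid, child, irf, field_id=field_id
            )
            fields.append(fld)
            table = fld.truth.copy()
            table.insert(0, "field_id", field_id)
            tables.append(table)
            field_id += 1
    return SimulatedDataset(fields=tuple(fields), truth=pd.concat(tables, ignore_index=True))


# ---------------------------------------------------------------------------
# Phenotype constructors for benchmarking the two feature routes.


def solve_matched_decomposition(
    base: BiexpParams, tau1_new: float, omega: float = OMEGA_80MHZ
) -> BiexpParams:
    """A different (alpha1, tau1, tau2) decomposition with the same phasor.

    The phasor is a 2-D projection of the 3-parameter biexponential model, so a
    one-parameter family of decompositions shares any interior phasor point.
    Given a new short lifetime, solves for the long lifetime and fraction whose
    chord passes through the base parameters' phasor, by root-finding on the
    chord's cross product.
    """
    target = phasor_of_biexp(base, omega)
    p1 = phasor_of_single_exp(tau1_new, omega)

    def cross(tau2_new):
        p2 = phasor_of_single_exp(tau2_new, omega)
        return (target.g - p1.g) * (p2.s - p1.s) - (target.s - p1.s) * (p2.g - p1.g)

    lo, hi = max(base.tau1, tau1_new) + 0.05, 7.5
    grid_t = np.linspace(lo, hi, 400)
    vals = np.array([cross(t) for t in grid_t])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError(
            f"no matched decomposition with tau1={tau1_new}; choose a different short lifetime"
        )
    i = sign_change[0]
    tau2_new = brentq(cross, grid_t[i], grid_t[i + 1])
    p2 = phasor_of_single_exp(tau2_new, omega)
    chord = np.array([p2.g - p1.g, p2.s - p1.s])
    t_frac = float(
        np.dot([target.g - p1.g, target.s - p1.s], chord) / np.dot(chord, chord)
    )
    if not 0.0 < t_frac < 1.0:
        raise ValueError("matched phasor point falls outside the new chord")
    f1 = 1.0 - t_frac  # intensity fraction on the short-lifetime endpoint
    a1 = (f1 / tau1_new) / (f1 / tau1_new + (1.0 - f1) / tau2_new)
    return BiexpParams(alpha1=a1, tau1=tau1_new, tau2=tau2_new)


def gaussian_feature_table(
    n_per_class: int = 200,
    shift_features=(),
    delta_sd: float = 0.0,
    seed: int = 0,
    groups=("ctrl", "case"),
) -> pd.DataFrame:
    """Synthetic per-cell feature table of unit Gaussians, optionally shifted.

    A tabular-level generator for calibrating the classification layer without
    running the image pipeline: every feature column is standard normal, and
    ``shift_features`` are shifted by ``delta_sd`` standard deviations in the
    second group.  With no shift the two classes are statistically identical
    (a null dataset); with a large shift they are trivially separable.
    """
    from .features import FEATURE_COLUMNS

    rng = np.random.default_rng(seed)
    frames = []
    for gi, group in enumerate(groups):
        data = {"field_id": gi, "cell_id": np.arange(n_per_class), "group": group}
        for col in FEATURE_COLUMNS:
            x = rng.normal(size=n_per_class)
            if gi == 1 and col in shift_features:
                x = x + delta_sd
            data[col] = x
        frames.append(pd.DataFrame(data))
    table = pd.concat(frames, ignore_index=True)
    table["n_valid_pixels"] = 50
    return table


def _default_fad() -> ChannelDecaySpec:
    return ChannelDecaySpec(alpha1_mean=0.75, tau1_mean=0.35, tau2_mean=2.8)


def matched_phasor_pair(
    omega: float = OMEGA_80MHZ, tau1_alt: float = 0.9, **spec_kwargs
) -> tuple:
    """Two phenotypes with identical NAD(P)H phasor position but different decompositions.

    Phenotype "degenA" uses the free/bound NAD(P)H anchor (0.7, 0.5 ns, 3.0 ns);
    "degenB" is the matched decomposition at a longer short lifetime.  The FAD
    channel is identical in both, so only the NAD(P)H decay decomposition — a
    signal the first-harmonic phasor projects away — separates the classes.
    """
    base = BiexpParams(0.7, 0.5, 3.0)
    alt = solve_matched_decomposition(base, tau1_alt, omega)
    fad = _default_fad()
    spec_a = PhenotypeSpec(
        name="degenA",
        nadph=ChannelDecaySpec(base.alpha1, base.tau1, base.tau2),
        fad=fad,
        **spec_kwargs,
    )
    spec_b = PhenotypeSpec(
        name="degenB",
        nadph=ChannelDecaySpec(alt.alpha1, alt.tau1, alt.tau2),
        fad=fad,
        **spec_kwargs,
    )
    return spec_a, spec_b


def large_shift_pair(**spec_kwargs) -> tuple:
    """Two phenotypes separated by a large shift visible to both feature routes.

    Emulates a strongly polarized comparison (M1-versus-M2-like): both the
    fitted lifetimes and the phasor position move by many per-cell standard
    deviations in both channels, so fit-derived and phasor-derived features
    should classify near-perfectly.
    """
    spec_c = PhenotypeSpec(
        name="shiftC",
        nadph=ChannelDecaySpec(0.70, 0.50, 3.0),
        fad=ChannelDecaySpec(0.75, 0.35, 2.8),
        **spec_kwargs,
    )
    spec_d = PhenotypeSpec(
        name="shiftD",
        nadph=ChannelDecaySpec(0.45, 0.45, 2.3),
        fad=ChannelDecaySpec(0.60, 0.30, 2.3),
        **spec_kwargs,
    )
    return spec_c, spec_d


def macrophage_like_phenotypes(**spec_kwargs) -> tuple:
    """M0/M1/M2-analog phenotypes with qualitative NAD(P)H and FAD shifts.

    M1 has a lower free-NAD(P)H fraction; both polarized states have a shorter
    free NAD(P)H lifetime; M2 has a shorter bound NAD(P)H lifetime (hence the
    shortest mean lifetime); M1's FAD decomposition is shifted relative to the
    similar M0 and M2.
    """
    m0 = PhenotypeSpec(
        name="M0",
        nadph=ChannelDecaySpec(0.75, 0.55, 3.1),
        fad=ChannelDecaySpec(0.70, 0.40, 2.9),
        **spec_kwargs,
    )
    m1 = PhenotypeSpec(
        name="M1",
        nadph=ChannelDecaySpec(0.70, 0.45, 3.1),
        fad=ChannelDecaySpec(0.80, 0.45, 2.6),
        **spec_kwargs,
    )
    m2 = PhenotypeSpec(
        name="M2",
        nadph=ChannelDecaySpec(0.75, 0.45, 2.7),
        fad=ChannelDecaySpec(0.72, 0.40, 2.85),
        **spec_kwargs,
    )
    return m0, m1, m2
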