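"""Synthetic FT-NIR mixture spectra with known adulterant fractions.

The generator emulates a powder-adulteration study: peanut-skin powder cut
with two starches (sweet potato, "A"; corn, "B") at fifteen total-adulteration
levels from 40% down to 0%, five A:B mass ratios, and fifteen replicates per
level (225 samples).  Each pure component is modelled as a sum of Gaussian
absorption bands on a descending wavenumber grid (10,000 → 4,000 cm⁻¹); a
sample's ideal spectrum is the Beer–Lambert linear mixture of the pure-component
spectra weighted by mass fraction.  On top of the ideal spectrum the generator
adds the artifacts NIR preprocessing is designed to remove:

* a multiplicative gain (particle-size scatter), ``gain ~ 1 + N(0, gain_sd²)``,
* an additive offset, ``offset ~ N(0, offset_sd²)``,
* a linear baseline tilt, ``slope · (ν − ν̄)`` with ``slope ~ N(0, slope_sd²)``,
* white Gaussian noise per wavelength, sd ``noise_sd``.

Everything is driven by an explicit integer seed, so a run is reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import SpectraSet
from .errors import DesignError, DomainError, GridError

# --------------------------------------------------------------------- grid

GRID_MAX = 10_000.0  # cm^-1
GRID_MIN = 4_000.0  # cm^-1

#: Default number of grid points.  An 8 cm⁻¹-resolution FT-NIR export over
#: 10,000–4,000 cm⁻¹ yields 1,557 variables (spacing ≈ 3.856 cm⁻¹ after the
#: instrument's internal zero-filling), which is the variable count the
#: selection-fraction bookkeeping assumes.
DEFAULT_N_POINTS = 1557


def make_wavenumber_grid(n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Equally spaced descending wavenumber grid from 10,000 to 4,000 cm⁻¹.

    Parameters
    ----------
    n_points
        Number of grid points, at least 3 (both endpoints are always included).

    Returns
    -------
    ndarray of shape ``(n_points,)``, strictly decreasing.
    """
    if not isinstance(n_points, (int, np.integer)) or n_points < 3:
        raise GridError(f"n_points must be an integer >= 3, got {n_points!r}")
    return np.linspace(GRID_MAX, GRID_MIN, int(n_points))


# ---------------------------------------------------------------- endmembers


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: center (cm⁻¹), width (Gaussian sd, cm⁻¹), height (AU)."""

    center: float
    width: float
    height: float


COMPONENTS = ("peanut_skin", "sweet_potato_starch", "corn_starch")


@dataclass
class EndmemberModel:
    """Pure-component band models plus the global artifact magnitudes.

    The band tables are illustrative synthetic stand-ins: band *positions*
    follow the qualitative description of the pure-material NIR spectra
    (peanut skin has a cis-fatty-acid marker near 4,700 cm⁻¹, two strong C–H
    overtone peaks in 5,000–6,000 cm⁻¹ and a smooth 8,200–8,400 cm⁻¹ region;
    the starches show more symmetric O–H/C–H bands), while widths and heights
    are invented, chosen only to give the three components distinct,
    partially overlapping signatures.

    Artifact magnitudes (all configurable):

    gain_sd
        Sd of the multiplicative scatter gain around 1 (dimensionless, 0.05).
    offset_sd
        Sd of the additive baseline offset (absorbance units, 0.01).
    slope_sd
        Sd of the linear baseline slope (absorbance per cm⁻¹, 1e-6).
    noise_sd
        Sd of per-wavelength white noise (absorbance units, 0.002).
    """

    bands: dict[str, list[GaussianBand]] = field(default_factory=lambda: {
        "peanut_skin": [
            GaussianBand(4700.0, 60.0, 0.50),   # cis double-bond fatty-acid marker
            GaussianBand(5200.0, 90.0, 0.60),   # C-H overtone (first of two)
            GaussianBand(5700.0, 80.0, 0.55),   # C-H overtone (second of two)
            GaussianBand(6900.0, 300.0, 0.25),  # broad O-H background
            GaussianBand(8300.0, 200.0, 0.10),  # smooth long-chain region
        ],
        "sweet_potato_starch": [
            GaussianBand(4300.0, 70.0, 0.45),   # C-H first overtone
            GaussianBand(5200.0, 90.0, 0.70),   # symmetric O-H combination
            GaussianBand(6800.0, 120.0, 0.50),  # O-H second stretching overtone
        ],
        "corn_starch": [
            GaussianBand(4450.0, 70.0, 0.40),   # C-H combination
            GaussianBand(5350.0, 90.0, 0.70),   # symmetric C-H second overtone
            GaussianBand(8000.0, 160.0, 0.35),  # O-H / C-H combination band
        ],
    })
    gain_sd: float = 0.05
    offset_sd: float = 0.01
    slope_sd: float = 1e-6
    noise_sd: float = 0.002

    def __post_init__(self) -> None:
        missing = [c for c in COMPONENTS if c not in self.bands]
        if missing:
            raise DesignError(f"endmember model missing components {missing}")
        for name, bands in self.bands.items():
            for b in bands:
                if b.height <= 0 or b.width <= 0:
                    raise DesignError(f"{name}: band heights and widths must be > 0")
                if not (GRID_MIN <= b.center <= GRID_MAX):
                    raise DesignError(
                        f"{name}: band center {b.center} outside "
                        f"[{GRID_MIN}, {GRID_MAX}] cm^-1"
                    )

    def spectrum(self, component: str, grid: np.ndarray) -> np.ndarray:
        """Noise-free pure-component spectrum on ``grid``."""
        out = np.zeros_like(grid, dtype=float)
        for b in self.bands[component]:
            out += b.height * np.exp(-0.5 * ((grid - b.center) / b.width) ** 2)
        return out

    def noiseless(self) -> "EndmemberModel":
        """Copy with every artifact magnitude set to zero."""
        return replace(self, gain_sd=0.0, offset_sd=0.0, slope_sd=0.0, noise_sd=0.0)


def default_endmembers(**overrides) -> EndmemberModel:
    """The shipped endmember fixture, optionally with artifact-sd overrides."""
    return replace(EndmemberModel(), **overrides) if overrides else EndmemberModel()


# -------------------------------------------------------------------- design

#: The fifteen total-adulteration levels (mass %), highest first.
DEFAULT_LEVELS = (40, 36, 30, 24, 20, 16, 12, 8, 6, 4, 3, 2, 1, 0.5, 0)

#: The five sweet-potato : corn mass ratios used in the mixture design.
RATIOS = {
    "1:1": (1, 1),
    "2:3": (2, 3),
    "3:2": (3, 2),
    "2:1": (2, 1),
    "1:3": (1, 3),
}


def default_ratio_assignment(levels=DEFAULT_LEVELS) -> dict[float, str]:
    """Default level → A:B ratio map.

    The two highest levels are pinned (40% → 2:3, 36% → 1:3) so that the
    corn-starch fraction reaches 24% and 27% — a long-tailed corn distribution
    whose two largest values stand out as boxplot outliers, as in the study
    design this generator emulates.  The remaining nonzero levels cycle
    through the five ratios; level 0 is pure peanut skin and needs no ratio.
    """
    assignment: dict[float, str] = {}
    cycle = list(RATIOS)
    j = 0
    for lv in levels:
        lv = float(lv)
        if lv == 0:
            continue
        if lv == 40.0:
            assignment[lv] = "2:3"
        elif lv == 36.0:
            assignment[lv] = "1:3"
        else:
            assignment[lv] = cycle[j % len(cycle)]
            j += 1
    return assignment


@dataclass
class MixtureDesign:
    """Per-sample ground-truth fractions of the mixture design.

    ``table`` has one row per sample with columns ``level``, ``ratio``,
    ``fA``, ``fB``, ``fC`` (mass %).
    """

    table: pd.DataFrame
    levels: tuple
    replicates_per_level: int

    @property
    def n_samples(self) -> int:
        return len(self.table)


def build_design(
    replicates_per_level: int = 15,
    ratio_assignment: dict | None = None,
    levels=DEFAULT_LEVELS,
) -> MixtureDesign:
    """Expand the level × ratio × replicate design into per-sample fractions.

    For a level ``L`` with ratio ``a:b`` the sweet-potato fraction is
    ``fA = L·a/(a+b)`` and the corn fraction ``fB = L·b/(a+b)``, so
    ``fA + fB = L`` exactly.  Level 0 is pure peanut skin.
    """
    if not isinstance(replicates_per_level, (int, np.integer)) or replicates_per_level < 1:
        raise DesignError(f"replicates_per_level must be >= 1, got {replicates_per_level!r}")
    if ratio_assignment is None:
        ratio_assignment = default_ratio_assignment(levels)
    ratio_assignment = {float(k): v for k, v in ratio_assignment.items()}
    rows = []
    for lv in levels:
        lv = float(lv)
        if lv < 0 or lv > 100:
            raise DesignError(f"adulteration level {lv} outside [0, 100] mass %")
        if lv == 0:
            ratio, fa, fb = "-", 0.0, 0.0
        else:
            ratio = ratio_assignment.get(lv)
            if ratio not in RATIOS:
                raise DesignError(f"level {lv} has no valid ratio (got {ratio!r})")
            a, b = RATIOS[ratio]
            fa = lv * a / (a + b)
            fb = lv * b / (a + b)
        for _ in range(int(replicates_per_level)):
            rows.append((lv, ratio, fa, fb, fa + fb))
    table = pd.DataFrame(rows, columns=["level", "ratio", "fA", "fB", "fC"])
    return MixtureDesign(table, tuple(levels), int(replicates_per_level))


# ------------------------------------------------------------------ simulate


def simulate_spectra(
    design: MixtureDesign,
    endmembers: EndmemberModel | None = None,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> SpectraSet:
    """Generate one noisy spectrum per design row.

    The ideal spectrum is the mass-fraction-weighted sum of the pure-component
    spectra (peanut-skin fraction = ``1 − fC/100``); the observed spectrum is

    ``gain · s(ν) + offset + slope · (ν − ν̄) + ε(ν)``

    with per-sample ``gain ~ 1 + N(0, gain_sd²)``, ``offset ~ N(0, offset_sd²)``,
    ``slope ~ N(0, slope_sd²)`` and i.i.d. ``ε ~ N(0, noise_sd²)``.

    Identical ``seed`` values produce bit-identical output.
    """
    if design.n_samples == 0:
        raise DesignError("empty design")
    if endmembers is None:
        endmembers = default_endmembers()
    if grid is None:
        grid = make_wavenumber_grid()
    fa = design.table["fA"].to_numpy(float)
    fb = design.table["fB"].to_numpy(float)
    fc = design.table["fC"].to_numpy(float)
    if ((fa < 0) | (fb < 0) | (fc > 100)).any():
        raise DomainError("mass fractions must lie in [0, 100]")
    fractions = np.column_stack([1.0 - fc / 100.0, fa / 100.0, fb / 100.0])
    E = np.vstack([endmembers.spectrum(c, grid) for c in COMPONENTS])
    ideal = fractions @ E

    rng = np.random.default_rng(seed)
    n, p = ideal.shape
    gain = 1.0 + rng.normal(0.0, endmembers.gain_sd, n)
    offset = rng.normal(0.0, endmembers.offset_sd, n)
    slope = rng.normal(0.0, endmembers.slope_sd, n)
    noise = rng.normal(0.0, endmembers.noise_sd, (n, p)) if endmembers.noise_sd > 0 else 0.0
    nu_centered = grid - grid.mean()
    observed = gain[:, None] * ideal + offset[:, None] + slope[:, None] * nu_centered[None, :]
    observed = observed + noise

    levels = design.table["level"].to_numpy()
    reps_seen: dict[float, int] = {}
    ids = []
    for lv in levels:
        k = reps_seen.get(lv, 0)
        reps_seen[lv] = k + 1
        lv_str = f"{lv:g}".replace(".", "p")
        ids.append(f"L{lv_str}_r{k:02d}")
    targets = design.table[["fA", "fB", "fC"]].copy()
    return SpectraSet(grid, observed, targets, ids)


def simulate_default_study(seed: int = 0, n_points: int = DEFAULT_N_POINTS,
                           replicates_per_level: int = 15,
                           endmembers: EndmemberModel | None = None) -> SpectraSet:
    """Convenience wrapper: default design + default endmembers at one seed."""
    design = build_design(replicates_per_level=replicates_per_level)
    return simulate_spectra(design, endmembers=endmembers,
                            grid=make_wavenumber_grid(n_points), seed=seed)


def spacing(grid: np.ndarray) -> float:
    """Absolute grid step in cm⁻¹ (grids are equally spaced by construction)."""
    return abs(float(grid[1] - grid[0]))
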