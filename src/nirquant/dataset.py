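"""The :class:`SpectraSet` container — the currency passed between pipeline stages.

A ``SpectraSet`` bundles a descending wavenumber grid (cm⁻¹), an absorbance
matrix (one row per sample), and the three regression targets used throughout
the adulteration study:

* ``fA`` — sweet-potato-starch mass fraction (%),
* ``fB`` — corn-starch mass fraction (%),
* ``fC`` — total adulterant mass fraction (%), always ``fA + fB``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError

TARGET_COLUMNS = ("fA", "fB", "fC")

#: Accepted aliases for the three targets.
TARGET_ALIASES = {
    "A": "fA",
    "B": "fB",
    "C": "fC",
    "fA": "fA",
    "fB": "fB",
    "fC": "fC",
}

#: Tolerance for the fC = fA + fB consistency check (mass %).
FC_TOL = 1e-6


def resolve_target(name: str) -> str:
    """Map a target alias (``"A"``, ``"fB"``, ...) to its canonical column."""
    try:
        return TARGET_ALIASES[name]
    except KeyError:
        raise KeyError(
            f"unknown target {name!r}; expected one of {sorted(TARGET_ALIASES)}"
        ) from None


@dataclass
class SpectraSet:
    """Wavenumber grid + absorbance matrix + per-sample target fractions.

    Parameters
    ----------
    wavenumbers
        Strictly descending grid in cm⁻¹, shape ``(n_points,)``.
    absorbance
        Dimensionless absorbance, shape ``(n_samples, n_points)``.
    targets
        DataFrame with columns ``fA``, ``fB``, ``fC`` in mass %.
    sample_ids
        Unique per-sample labels, length ``n_samples``.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    targets: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.size == 0:
            self.absorbance = self.absorbance.reshape(0, self.wavenumbers.size)
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise DimensionError(
                f"absorbance has {self.absorbance.shape[1]} columns but the grid "
                f"has {self.wavenumbers.size} points"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{i:03d}" for i in range(self.absorbance.shape[0])]
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise DimensionError("sample_ids length does not match absorbance rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("sample_ids are not unique")
        self.targets = self.targets.reset_index(drop=True)
        missing = [c for c in TARGET_COLUMNS if c not in self.targets.columns]
        if missing:
            raise FormatError(f"targets missing columns {missing}")
        if len(self.targets) != self.absorbance.shape[0]:
            raise DimensionError("targets row count does not match absorbance rows")
        if self.n_samples:
            if not np.isfinite(self.absorbance).all():
                raise FormatError("absorbance contains non-finite values")
            t = self.targets[list(TARGET_COLUMNS)].to_numpy(dtype=float)
            if not np.isfinite(t).all():
                raise FormatError("targets contain non-finite values")
            bad = np.abs(t[:, 0] + t[:, 1] - t[:, 2]) > FC_TOL
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise FormatError(
                    f"fC != fA + fB for sample {self.sample_ids[row]!r} (row {row})"
                )

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    def target(self, name: str) -> np.ndarray:
        """Return one target vector by name or alias (``"A"`` → ``fA`` ...)."""
        return self.targets[resolve_target(name)].to_numpy(dtype=float)

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Copy of this set with a replaced absorbance matrix (same grid)."""
        return SpectraSet(
            self.wavenumbers.copy(),
            np.asarray(absorbance, dtype=float),
            self.targets.copy(),
            list(self.sample_ids),
        )

    def take(self, rows) -> "SpectraSet":
        """Row subset (e.g. a calibration or prediction partition)."""
        rows = np.asarray(rows, dtype=int)
        return SpectraSet(
            self.wavenumbers.copy(),
            self.absorbance[rows],
            self.targets.iloc[rows].reset_index(drop=True),
            [self.sample_ids[i] for i in rows],
        )

    def select_variables(self, cols) -> "SpectraSet":
        """Column subset (e.g. CARS-selected wavelengths)."""
        cols = np.asarray(cols, dtype=int)
        return SpectraSet(
            self.wavenumbers[cols],
            self.absorbance[:, cols],
            self.targets.copy(),
            list(self.sample_ids),
        )

    def equals(self, other: "SpectraSet", tol: float = 1e-9) -> bool:
        """Approximate equality on grid, absorbance and targets."""
        return (
            self.wavenumbers.shape == other.wavenumbers.shape
            and np.allclose(self.wavenumbers, other.wavenumbers, atol=1e-3, rtol=0)
            and self.absorbance.shape == other.absorbance.shape
            and np.allclose(self.absorbance, other.absorbance, atol=tol, rtol=0)
            and np.allclose(
                self.targets[list(TARGET_COLUMNS)].to_numpy(float),
                other.targets[list(TARGET_COLUMNS)].to_numpy(float),
                atol=tol,
                rtol=0,
            )
            and self.sample_ids == other.sample_ids
        )
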