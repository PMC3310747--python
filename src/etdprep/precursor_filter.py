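"""Removal of charge-reduced precursor peaks and their neutral losses.

Before an ETD spectrum is submitted to a sequence-library search, the
intense charge-reduced precursor ladder and its associated neutral-loss
peaks should be stripped, otherwise they are scored as if they were
fragment signal.  Two window constructions are provided:

``omssa``
    A variable-width window per reduced precursor MH(z+): peaks are removed
    in ``(MH(z+) - N1/z, MH(z+) + M/(W*z))`` for z = 1, 2 and in
    ``(MH(z+) - N2/z, MH(z+) + M/(W*z))`` for z = 3..n.  The upstream
    extent ``M/(W*z)`` scales with the peptide mass, tracking the width of
    the isotopic envelope; the downstream extent covers the neutral-loss
    region (a wide N1 = 60 Da blanket for the 1+ and 2+ species, a narrow
    N2 = 18 Da water-loss window for higher charges).

``good``
    The fixed-width comparison scheme: ``(MH(z+) - 3.1, MH(z+) + 3.1)``
    around each reduced precursor plus ``(MH(z+) - N1/z, MH(z+))`` for the
    neutral losses, for every z.

``none``
    Passthrough.

All windows use strict inequalities; a peak exactly on a boundary survives.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import (PROTON_MASS, MassWindow, Spectrum, WindowPurpose, mh,
                      neutral_mass)

__all__ = [
    "omssa_removal_windows",
    "good_removal_windows",
    "removal_windows",
    "apply_precursor_filter",
    "PrecursorFilter",
]

Variant = Literal["omssa", "good", "none"]


def omssa_removal_windows(
    M: float,
    n: int,
    W: float = 500.0,
    N1: float = 60.0,
    N2: float = 18.0,
    proton_mass: float = PROTON_MASS,
) -> list[MassWindow]:
    """Variable-width removal windows around MH(z+) for z = 1..n.

    The downstream (low-m/z) half-width is ``N1/z`` for z <= 2 and ``N2/z``
    for z >= 3; the upstream half-width is the mass-proportional
    ``X(M, z) = M/(W*z)``.
    """
    if not (W > 0 and N1 > 0 and N2 > 0):
        raise ValueError("W, N1 and N2 must be positive")
    if N1 < N2:
        raise ValueError("N1 must be at least N2")
    windows = []
    for z in range(1, n + 1):
        center = mh(M, z, proton_mass)
        down = N1 / z if z <= 2 else N2 / z
        windows.append(MassWindow(center - down, center + M / (W * z),
                                  WindowPurpose.PRECURSOR_REMOVAL))
    windows.sort(key=lambda w: w.lo)
    return windows


def good_removal_windows(
    M: float,
    n: int,
    N1: float = 60.0,
    half_width: float = 3.1,
    proton_mass: float = PROTON_MASS,
) -> list[MassWindow]:
    """Fixed ±3.1 Da precursor windows plus ``N1/z``-wide neutral-loss
    windows below each MH(z+), for z = 1..n (two windows per z)."""
    windows = []
    for z in range(1, n + 1):
        center = mh(M, z, proton_mass)
        windows.append(MassWindow(center - half_width, center + half_width,
                                  WindowPurpose.PRECURSOR_REMOVAL))
        windows.append(MassWindow(center - N1 / z, center,
                                  WindowPurpose.NEUTRAL_LOSS_REMOVAL))
    windows.sort(key=lambda w: w.lo)
    return windows


def removal_windows(
    precursor_mz: float,
    n: int,
    variant: Variant = "omssa",
    W: float = 500.0,
    N1: float = 60.0,
    N2: float = 18.0,
    proton_mass: float = PROTON_MASS,
) -> list[MassWindow]:
    """Removal windows for a precursor observed at ``precursor_mz`` with
    parent charge ``n``, under the selected filter variant."""
    if variant == "none":
        return []
    M = neutral_mass(precursor_mz, n, proton_mass)
    if variant == "omssa":
        return omssa_removal_windows(M, n, W, N1, N2, proton_mass)
    if variant == "good":
        return good_removal_windows(M, n, N1, proton_mass=proton_mass)
    raise ValueError(f"unknown precursor filter variant: {variant!r}")


def _filter_charge(spectrum: Spectrum) -> int:
    if spectrum.precursor_charge is not None:
        return spectrum.precursor_charge
    if spectrum.charge_candidates:
        # Conservative choice: the largest candidate's window set covers
        # every shared reduced-precursor position of the smaller hypotheses.
        return max(spectrum.charge_candidates)
    raise ValueError(
        f"spectrum {spectrum.scan_id!r} has unknown precursor charge; run "
        "charge determination first or set the maximum of the search range")


def apply_precursor_filter(
    spectrum: Spectrum,
    n: int | None = None,
    variant: Variant = "omssa",
    W: float = 500.0,
    N1: float = 60.0,
    N2: float = 18.0,
) -> Spectrum:
    """Return a copy of ``spectrum`` with all peaks strictly inside any
    removal window deleted.  ``n`` defaults to the spectrum's precursor
    charge (or the largest charge candidate).  Variant ``"none"`` returns
    an unmodified copy."""
    if variant == "none":
        return spectrum.replace_peaks(spectrum.mz, spectrum.intensity)
    if n is None:
        n = _filter_charge(spectrum)
    windows = removal_windows(spectrum.precursor_mz, n, variant, W, N1, N2)
    keep = np.ones(len(spectrum), dtype=bool)
    for w in windows:
        keep &= ~((spectrum.mz > w.lo) & (spectrum.mz < w.hi))
    return spectrum.replace_peaks(spectrum.mz[keep], spectrum.intensity[keep])


class PrecursorFilter(BaseEstimator, TransformerMixin):
    """Transformer stripping charge-reduced precursors and neutral losses.

    Stateless (``fit`` is a no-op); operates on lists of
    :class:`~etdprep.spectra.Spectrum`.

    Parameters
    ----------
    variant : {"omssa", "good", "none"}
        Window construction, see module docstring.
    W : float
        Mass divisor of the upstream window width ``X(M, z) = M/(W*z)``.
    N1, N2 : float
        Neutral-loss extents in Da below MH(z+): ``N1/z`` for z <= 2,
        ``N2/z`` for z >= 3 (``omssa``); ``good`` uses N1 for all z.
    """

    def __init__(self, variant: Variant = "omssa", W: float = 500.0,
                 N1: float = 60.0, N2: float = 18.0) -> None:
        self.variant = variant
        self.W = W
        self.N1 = N1
        self.N2 = N2

    def fit(self, X: Sequence[Spectrum], y=None) -> "PrecursorFilter":
        return self

    def transform(self, X: Sequence[Spectrum]) -> list[Spectrum]:
        return [apply_precursor_filter(s, None, self.variant, self.W,
                                       self.N1, self.N2) for s in X]
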