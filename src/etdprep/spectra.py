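"""Core domain objects for ETD tandem mass spectra.

An electron-transfer-dissociation (ETD) spectrum of a peptide of neutral
monoisotopic mass ``M`` carrying ``n`` protons contains, besides the c/z·/y
backbone fragments, a ladder of intense *charge-reduced precursor* ions.
These are intact precursors that captured one or more electrons without
dissociating; the species with ``z`` remaining charges appears at

    MH(z+) = (M + z * H) / z        for z = 1 .. n,

where ``H`` is the proton mass.  Everything in this package — precursor
removal windows, neutral-loss windows, the charge-determination features —
is arithmetic on this ladder, so it lives here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "PROTON_MASS",
    "Peak",
    "Spectrum",
    "MassWindow",
    "WindowPurpose",
    "mh",
    "neutral_mass",
    "reduced_precursor_series",
]

#: Monoisotopic proton mass in Da.
PROTON_MASS = 1.007276466


class Peak(NamedTuple):
    """A single centroided peak: m/z in Thomson, intensity in arbitrary units."""

    mz: float
    intensity: float


class WindowPurpose(enum.Enum):
    PRECURSOR_REMOVAL = "precursor_removal"
    NEUTRAL_LOSS_REMOVAL = "neutral_loss_removal"
    CP_FEATURE = "cp_feature"
    NL_FEATURE = "nl_feature"


@dataclass(frozen=True)
class MassWindow:
    """An open m/z interval ``(lo, hi)``.

    Peak-removal and feature-summation windows use strict inequalities on
    both sides, so a peak sitting exactly on a boundary is *outside*.
    """

    lo: float
    hi: float
    purpose: WindowPurpose = WindowPurpose.PRECURSOR_REMOVAL

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"empty mass window: lo={self.lo} >= hi={self.hi}")

    def contains(self, mz: float) -> bool:
        return self.lo < mz < self.hi


class Spectrum:
    """One MS/MS scan: a sorted peak list plus precursor information.

    Parameters
    ----------
    mz, intensity : array-like
        Peak positions (Thomson) and intensities.  Peaks are sorted by m/z
        on construction; peaks with identical m/z are merged by summing
        their intensities, so the peak list behaves as a set.
    precursor_mz : float
        Observed precursor m/z.
    precursor_charge : int or None
        Parent precursor charge ``n``; ``None`` means unknown (the common
        case on low-resolution ion traps).
    charge_candidates : sequence of int, optional
        Candidate charges attached by the charge-determination step or read
        from a multi-charge MGF ``CHARGE`` line.
    scan_id : str
        Opaque identifier carried through the pipeline.
    """

    __slots__ = ("mz", "intensity", "precursor_mz", "precursor_charge",
                 "charge_candidates", "scan_id")

    def __init__(
        self,
        mz: Iterable[float],
        intensity: Iterable[float],
        precursor_mz: float,
        precursor_charge: int | None = None,
        charge_candidates: Sequence[int] = (),
        scan_id: str = "",
    ) -> None:
        mz = np.asarray(list(mz) if not isinstance(mz, np.ndarray) else mz,
                        dtype=float)
        intensity = np.asarray(
            list(intensity) if not isinstance(intensity, np.ndarray) else intensity,
            dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and (np.any(mz <= 0) or np.any(intensity < 0)):
            raise ValueError("peaks require mz > 0 and intensity >= 0")
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        if mz.size:
            uniq, inverse = np.unique(mz, return_inverse=True)
            if uniq.size != mz.size:  # merge duplicate m/z values
                merged = np.zeros(uniq.size)
                np.add.at(merged, inverse, intensity)
                mz, intensity = uniq, merged
        self.mz = mz
        self.intensity = intensity
        if not precursor_mz > 0:
            raise ValueError("precursor_mz must be positive")
        self.precursor_mz = float(precursor_mz)
        if precursor_charge is not None and precursor_charge < 1:
            raise ValueError("precursor_charge must be a positive integer or None")
        self.precursor_charge = precursor_charge
        self.charge_candidates = tuple(int(c) for c in charge_candidates)
        self.scan_id = str(scan_id)

    # -- convenience -------------------------------------------------------

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all peak intensities."""
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return int(self.mz.size)

    def replace_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> "Spectrum":
        """New spectrum with the same precursor metadata but a new peak list."""
        return Spectrum(mz, intensity, self.precursor_mz, self.precursor_charge,
                        self.charge_candidates, self.scan_id)

    def __repr__(self) -> str:
        ch = self.precursor_charge if self.precursor_charge is not None else "?"
        return (f"Spectrum(scan_id={self.scan_id!r}, peaks={len(self)}, "
                f"precursor={self.precursor_mz:.4f} m/z, charge={ch})")


def mh(M: float, z: int, proton_mass: float = PROTON_MASS) -> float:
    """m/z of the peptide of neutral mass ``M`` carrying ``z`` protons.

    ``MH(z+) = (M + z * H) / z``.  ``proton_mass`` may be overridden (e.g.
    ``1.0`` for back-of-envelope binning arithmetic).
    """
    if not M > 0:
        raise ValueError(f"neutral mass must be positive, got {M}")
    if not z >= 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (M + z * proton_mass) / z


def neutral_mass(precursor_mz: float, z: int,
                 proton_mass: float = PROTON_MASS) -> float:
    """Neutral peptide mass implied by a precursor at ``precursor_mz`` with
    charge ``z``: the inverse of :func:`mh`, ``M = z * (precursor_mz - H)``."""
    if not z >= 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    if not precursor_mz > proton_mass:
        raise ValueError("precursor_mz must exceed the proton mass")
    return z * precursor_mz - z * proton_mass


def reduced_precursor_series(
    precursor_mz: float, n: int, proton_mass: float = PROTON_MASS
) -> list[tuple[int, float]]:
    """The charge-reduced precursor ladder for a parent charge ``n``.

    Returns ``[(z, MH(z+)) for z in 1..n]`` where the neutral mass is the
    one implied by ``precursor_mz`` at charge ``n``; the ``z = n`` element
    reproduces ``precursor_mz`` exactly.  m/z is strictly decreasing in z.
    """
    M = neutral_mass(precursor_mz, n, proton_mass)
    return [(z, mh(M, z, proton_mass)) for z in range(1, n + 1)]
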