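"""Two-stage noise filtering: deisotoping, then sliding-window thinning.

Stage one removes isotope satellites: peaks lying 1 or 2 Da above a more
intense peak (ion-trap product ions are singly deconvoluted, so the
spacing of interest is 1-2 Da; charge-dependent 1/z spacings are out of
scope).  Stage two keeps, around every peak, only the ``h`` most intense
peaks within a ±27 Da window (when the downstream search looks for 1+
product ions) or a ±14 Da window (2+ product ions).  ``h`` should equal
the number of ion series expected in a region: 2 for a c/z·-only search,
3 when y ions are searched as well.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import Spectrum

__all__ = ["deisotope", "window_filter", "apply_noise_filter", "NoiseFilter"]


def deisotope(spectrum: Spectrum, isotope_tol: float = 0.2) -> Spectrum:
    """Remove isotope peaks sitting 1.0±tol or 2.0±tol Da above a more
    intense retained peak.

    Peaks are visited in descending intensity order (ties: lower m/z
    first); only peaks still retained act as isotope anchors, so a removed
    satellite cannot shadow further peaks.  The most intense peak of each
    cluster — taken to be the monoisotopic one — is always retained.
    """
    mz, inten = spectrum.mz, spectrum.intensity
    keep = np.ones(mz.size, dtype=bool)
    order = np.lexsort((mz, -inten))
    for i in order:
        if not keep[i]:
            continue
        for spacing in (1.0, 2.0):
            lo = np.searchsorted(mz, mz[i] + spacing - isotope_tol, side="left")
            hi = np.searchsorted(mz, mz[i] + spacing + isotope_tol, side="right")
            for j in range(lo, hi):
                if keep[j] and inten[j] < inten[i]:
                    keep[j] = False
    return spectrum.replace_peaks(mz[keep], inten[keep])


def window_filter(spectrum: Spectrum, half_width: float, h: int) -> np.ndarray:
    """Mask of peaks ranking in the top ``h`` by intensity within the
    ±``half_width`` window centred on themselves.

    Every peak gets its own window ``[mz - half_width, mz + half_width]``
    (inclusive); ties in intensity are broken toward lower m/z.
    """
    if h < 1:
        raise ValueError("h must be at least 1")
    mz, inten = spectrum.mz, spectrum.intensity
    keep = np.zeros(mz.size, dtype=bool)
    los = np.searchsorted(mz, mz - half_width, side="left")
    his = np.searchsorted(mz, mz + half_width, side="right")
    for i in range(mz.size):
        sl = slice(los[i], his[i])
        better = np.count_nonzero(
            (inten[sl] > inten[i])
            | ((inten[sl] == inten[i]) & (mz[sl] < mz[i])))
        keep[i] = better < h
    return keep


def apply_noise_filter(
    spectrum: Spectrum,
    h1: int = 2,
    h2: int = 2,
    window_1plus: float = 27.0,
    window_2plus: float = 14.0,
    isotope_tol: float = 0.2,
) -> tuple[Spectrum, Spectrum]:
    """Deisotope, then produce the two filtered views used by a search:
    one thinned with ±``window_1plus``/``h1`` for matching 1+ product ions
    and one with ±``window_2plus``/``h2`` for 2+ product ions."""
    deiso = deisotope(spectrum, isotope_tol)
    m1 = window_filter(deiso, window_1plus, h1)
    m2 = window_filter(deiso, window_2plus, h2)
    return (deiso.replace_peaks(deiso.mz[m1], deiso.intensity[m1]),
            deiso.replace_peaks(deiso.mz[m2], deiso.intensity[m2]))


class NoiseFilter(BaseEstimator, TransformerMixin):
    """Transformer applying deisotoping plus sliding-window thinning.

    ``transform`` returns, per input spectrum, the ``(1+ view, 2+ view)``
    pair.  Defaults ``h1 = h2 = 2`` reproduce the classic c/z·-only
    behaviour; set both to 3 when y ions are also searched.
    """

    def __init__(self, h1: int = 2, h2: int = 2, window_1plus: float = 27.0,
                 window_2plus: float = 14.0, isotope_tol: float = 0.2) -> None:
        self.h1 = h1
        self.h2 = h2
        self.window_1plus = window_1plus
        self.window_2plus = window_2plus
        self.isotope_tol = isotope_tol

    def fit(self, X: Sequence[Spectrum], y=None) -> "NoiseFilter":
        return self

    def transform(self, X: Sequence[Spectrum]) -> list[tuple[Spectrum, Spectrum]]:
        return [apply_noise_filter(s, self.h1, self.h2, self.window_1plus,
                                   self.window_2plus, self.isotope_tol)
                for s in X]
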