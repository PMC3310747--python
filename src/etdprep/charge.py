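"""Parent precursor charge determination for ETD spectra.

On a low-resolution ion trap the precursor charge ``n`` is usually not
measured, yet the charge-reduced precursor ladder in the MS/MS scan is a
fingerprint of it: a precursor observed at ``p`` m/z with true charge
``n`` produces intense peaks at MH(z+) for z = 1..n, with the neutral mass
``M = n*(p - H)`` depending on the hypothesised ``n``.  For each candidate
charge ``c`` we therefore sum spectrum intensity inside two window sets
built under the hypothesis ``M_c = c*(p - H)``:

* charge-reduced precursor (CP) windows
  ``(MH(z+) - tolp/z,  MH(z+) + M_c/(W*z) + tolp/z)``, z = 1..c;
* neutral-loss (NL) windows centred ``N2/z`` below each MH(z+) with
  half-width ``tol/z`` — wide enough to cover both water (−18 Da) and
  ammonia (−17 Da) losses.

Both sums are normalised by the spectrum's total ion current, giving one
CP and one NL feature per candidate charge.  The NL features disambiguate
"multiples" (a 3+ precursor shares its reduced-precursor bins with the 6+
hypothesis, but the neutral losses fall 18/z versus 18/(2z) below the
shared bins).  A linear discriminant classifier over these features yields
posterior probabilities per charge, which drive three assignment
strategies: Top 1 (always the best charge), Top 1/Top 2 (add the runner-up
when the best posterior is below ``t1``), and 1/2/All (fall back to the
full search range when it drops below ``t2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .spectra import PROTON_MASS, MassWindow, Spectrum, WindowPurpose, mh, neutral_mass

__all__ = [
    "cp_feature_windows",
    "nl_feature_windows",
    "extract_features",
    "ChargeFeatureExtractor",
    "LinearDiscriminantChargeClassifier",
    "ChargeAssignment",
    "assign_charges",
    "save_model",
    "load_model",
]

DEFAULT_CHARGE_RANGE: tuple[int, ...] = (3, 4, 5, 6, 7)


def cp_feature_windows(
    precursor_mz: float,
    c: int,
    W: float = 500.0,
    tolp: float = 2.0,
    proton_mass: float = PROTON_MASS,
) -> list[MassWindow]:
    """Charge-reduced precursor windows under the hypothesis that the
    precursor at ``precursor_mz`` carries charge ``c``.

    For z = 1..c the window is
    ``(MH(z+) - tolp/z, MH(z+) + M/(W*z) + tolp/z)`` with the neutral mass
    ``M`` implied by the hypothesis; the mass-proportional term
    ``X(M, z) = M/(W*z)`` accommodates the isotopic envelope of heavy
    precursors.
    """
    M = neutral_mass(precursor_mz, c, proton_mass)
    return [
        MassWindow(mh(M, z, proton_mass) - tolp / z,
                   mh(M, z, proton_mass) + M / (W * z) + tolp / z,
                   WindowPurpose.CP_FEATURE)
        for z in range(1, c + 1)
    ]


def nl_feature_windows(
    precursor_mz: float,
    c: int,
    N2: float = 18.0,
    tol: float = 4.0,
    proton_mass: float = PROTON_MASS,
) -> list[MassWindow]:
    """Neutral-loss windows under hypothesis ``c``: for z = 1..c, centred
    at ``MH(z+) - N2/z`` with half-width ``tol/z`` (covers both the −18 Da
    water and −17 Da ammonia losses)."""
    M = neutral_mass(precursor_mz, c, proton_mass)
    return [
        MassWindow(mh(M, z, proton_mass) - N2 / z - tol / z,
                   mh(M, z, proton_mass) - N2 / z + tol / z,
                   WindowPurpose.NL_FEATURE)
        for z in range(1, c + 1)
    ]


def _window_sum(spectrum: Spectrum, windows: Sequence[MassWindow]) -> float:
    inside = np.zeros(len(spectrum), dtype=bool)
    for w in windows:
        inside |= (spectrum.mz > w.lo) & (spectrum.mz < w.hi)
    return float(spectrum.intensity[inside].sum())


def extract_features(
    spectrum: Spectrum,
    candidate_charges: Sequence[int] = DEFAULT_CHARGE_RANGE,
    include_nl: bool = True,
    W: float = 500.0,
    tolp: float = 2.0,
    N2: float = 18.0,
    tol: float = 4.0,
) -> np.ndarray:
    """TIC-normalised CP (and optionally NL) intensity sums, one per
    candidate charge.

    Returns ``[cp(c1)..cp(ck), nl(c1)..nl(ck)]`` (or the CP half alone),
    every component in [0, 1].
    """
    tic = spectrum.tic
    if not tic > 0:
        raise ValueError(
            f"spectrum {spectrum.scan_id!r} has zero total ion current")
    cp = [_window_sum(spectrum, cp_feature_windows(spectrum.precursor_mz, c,
                                                   W, tolp)) / tic
          for c in candidate_charges]
    if not include_nl:
        return np.asarray(cp)
    nl = [_window_sum(spectrum, nl_feature_windows(spectrum.precursor_mz, c,
                                                   N2, tol)) / tic
          for c in candidate_charges]
    return np.asarray(cp + nl)


class ChargeFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping spectra to the CP/NL feature matrix.

    Parameters
    ----------
    candidate_charges : tuple of int
        Hypothesised charges, ascending (default 3..7).
    include_nl : bool
        Whether to append the neutral-loss features (recommended; CP-only
        cannot separate charge multiples such as 3+ from 6+).
    W, tolp : float
        CP window geometry, see :func:`cp_feature_windows`.
    N2, tol : float
        NL window geometry, see :func:`nl_feature_windows`.
    """

    def __init__(self, candidate_charges: Sequence[int] = DEFAULT_CHARGE_RANGE,
                 include_nl: bool = True, W: float = 500.0, tolp: float = 2.0,
                 N2: float = 18.0, tol: float = 4.0) -> None:
        self.candidate_charges = tuple(candidate_charges)
        self.include_nl = include_nl
        self.W = W
        self.tolp = tolp
        self.N2 = N2
        self.tol = tol

    def fit(self, X: Sequence[Spectrum], y=None) -> "ChargeFeatureExtractor":
        if not self.candidate_charges or \
                list(self.candidate_charges) != sorted(set(self.candidate_charges)):
            raise ValueError("candidate_charges must be non-empty and ascending")
        return self

    def transform(self, X: Sequence[Spectrum]) -> np.ndarray:
        return np.vstack([
            extract_features(s, self.candidate_charges, self.include_nl,
                             self.W, self.tolp, self.N2, self.tol)
            for s in X
        ])


class LinearDiscriminantChargeClassifier(BaseEstimator, ClassifierMixin):
    """Gaussian linear discriminant classifier with charge-state classes.

    Classic LDA: classes share a pooled within-class covariance, so the
    discriminants ``d_k(x) = x' S^-1 m_k - m_k' S^-1 m_k / 2 + log pi_k``
    are linear and the posteriors are their softmax.  The pooled covariance
    is ridged by ``ridge * I`` before inversion; ``ridge="auto"`` uses
    ``1e-6 * trace(S) / n_features``.

    Fitted attributes: ``classes_``, ``means_``, ``covariance_``,
    ``cov_inv_``, ``priors_``, ``ridge_``.
    """

    def __init__(self, priors: Sequence[float] | None = None,
                 ridge: float | str = "auto") -> None:
        self.priors = priors
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "LinearDiscriminantChargeClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label in y")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 charge classes to fit")
        if np.any(counts < 2):
            short = classes[counts < 2].tolist()
            raise ValueError(f"classes {short} have fewer than 2 samples")
        n, d = X.shape
        means = np.vstack([X[y == k].mean(axis=0) for k in classes])
        scatter = np.zeros((d, d))
        for k, m in zip(classes, means):
            diff = X[y == k] - m
            scatter += diff.T @ diff
        cov = scatter / (n - classes.size)
        ridge = (1e-6 * np.trace(cov) / d if self.ridge == "auto"
                 else float(self.ridge))
        cov = cov + ridge * np.eye(d)
        # symmetric PD check via Cholesky; failure means degenerate features
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("pooled covariance singular even after ridge; "
                             "features are degenerate") from err
        if self.priors is None:
            priors = counts / n
        else:
            priors = np.asarray(self.priors, dtype=float)
            if priors.shape != classes.shape or not np.isclose(priors.sum(), 1.0):
                raise ValueError("priors must have one entry per class and sum to 1")
        self.classes_ = classes
        self.means_ = means
        self.covariance_ = cov
        self.cov_inv_ = np.linalg.inv(cov)
        self.priors_ = priors
        self.ridge_ = ridge
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "cov_inv_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means_.shape[1]:
            raise ValueError(
                f"expected {self.means_.shape[1]} features, got {X.shape[1]}")
        lin = self.cov_inv_ @ self.means_.T                      # (d, K)
        const = -0.5 * np.einsum("kd,dk->k", self.means_, lin) \
            + np.log(self.priors_)
        return X @ lin + const

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X)
        d -= d.max(axis=1, keepdims=True)
        e = np.exp(d)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


@dataclass
class ChargeAssignment:
    """Outcome of a charge-assignment strategy for one spectrum."""

    scan_id: str
    posteriors: dict[int, float]
    assigned: tuple[int, ...]
    strategy: str
    t1: float = 0.99
    t2: float = 0.9

    def __post_init__(self) -> None:
        if not self.assigned:
            raise ValueError("assignment must contain at least one charge")


def assign_charges(
    posteriors: Sequence[float],
    classes: Sequence[int],
    strategy: str = "all",
    t1: float = 0.99,
    t2: float = 0.9,
    full_range: Sequence[int] | None = None,
    scan_id: str = "",
) -> ChargeAssignment:
    """Turn class posteriors into a candidate-charge set.

    * ``"top1"`` — always the single best charge.
    * ``"top2"`` (Top 1/Top 2) — the best charge alone when its posterior
      is at least ``t1``, otherwise the top two.
    * ``"all"`` (1/2/All) — the best charge when its posterior exceeds
      ``t1``; the top two when it lies in [``t2``, ``t1``]; the entire
      ``full_range`` (ascending) below ``t2``.

    Ties in posterior are broken toward the lower charge.
    """
    if not t1 > t2:
        raise ValueError(f"t1 must exceed t2 (got t1={t1}, t2={t2})")
    p = np.asarray(posteriors, dtype=float)
    classes = np.asarray(classes)
    if p.shape != classes.shape:
        raise ValueError("posteriors and classes must align")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("posteriors must sum to 1")
    order = np.lexsort((classes, -p))          # descending p, lower charge first
    best = order[0]
    top2 = tuple(int(classes[i]) for i in order[:2])
    pbest = float(p[best])
    if strategy == "top1":
        assigned = (int(classes[best]),)
    elif strategy == "top2":
        assigned = (int(classes[best]),) if pbest >= t1 else top2
    elif strategy == "all":
        if pbest > t1:
            assigned = (int(classes[best]),)
        elif pbest >= t2:
            assigned = top2
        else:
            rng = full_range if full_range is not None else sorted(classes.tolist())
            assigned = tuple(int(c) for c in sorted(rng))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return ChargeAssignment(scan_id=scan_id,
                            posteriors={int(c): float(q)
                                        for c, q in zip(classes, p)},
                            assigned=assigned, strategy=strategy, t1=t1, t2=t2)


# -- model persistence -----------------------------------------------------

def save_model(path, classifier: LinearDiscriminantChargeClassifier,
               extractor: ChargeFeatureExtractor) -> None:
    """Persist a fitted classifier plus its feature geometry as plain-text
    YAML so predictions are reproducible without retraining."""
    check_is_fitted(classifier, "cov_inv_")
    payload = {
        "classes": classifier.classes_.tolist(),
        "priors": classifier.priors_.tolist(),
        "means": classifier.means_.tolist(),
        "covariance": classifier.covariance_.tolist(),
        "ridge": float(classifier.ridge_),
        "features": {
            "candidate_charges": list(extractor.candidate_charges),
            "include_nl": bool(extractor.include_nl),
            "W": extractor.W, "tolp": extractor.tolp,
            "N2": extractor.N2, "tol": extractor.tol,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def load_model(path) -> tuple[LinearDiscriminantChargeClassifier,
                              ChargeFeatureExtractor]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    clf = LinearDiscriminantChargeClassifier()
    clf.classes_ = np.asarray(payload["classes"])
    clf.priors_ = np.asarray(payload["priors"], dtype=float)
    clf.means_ = np.asarray(payload["means"], dtype=float)
    clf.covariance_ = np.asarray(payload["covariance"], dtype=float)
    clf.cov_inv_ = np.linalg.inv(clf.covariance_)
    clf.ridge_ = float(payload["ridge"])
    feats = payload["features"]
    extractor = ChargeFeatureExtractor(
        candidate_charges=tuple(feats["candidate_charges"]),
        include_nl=feats["include_nl"], W=feats["W"], tolp=feats["tolp"],
        N2=feats["N2"], tol=feats["tol"])
    return clf, extractor
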