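"""End-to-end processing: charge determination, then filtering, then export.

Stage order matters and is fixed: charge features are extracted from the
RAW spectrum (the precursor filter would otherwise delete the very peaks
the classifier reads), the precursor filter then removes the reduced
precursor ladder using the assigned charge (largest candidate when several
were assigned), and the noise filter thins what remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .charge import (ChargeAssignment, ChargeFeatureExtractor,
                     LinearDiscriminantChargeClassifier, assign_charges,
                     load_model)
from .noise_filter import apply_noise_filter, deisotope, window_filter
from .precursor_filter import apply_precursor_filter
from .spectra import Spectrum

__all__ = ["PipelineConfig", "run_pipeline", "predict_assignments",
           "evaluate_assignments"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end run (YAML-loadable; flags override)."""

    input: str = ""
    output_mgf: str = "filtered.mgf"
    output_assignments: str = "assignments.tsv"
    model: str = ""
    precursor_filter: str = "omssa"          # omssa | good | none
    W: float = 500.0
    N1: float = 60.0
    N2: float = 18.0
    h1: int = 3
    h2: int = 3
    window_1plus: float = 27.0
    window_2plus: float = 14.0
    isotope_tol: float = 0.2
    strategy: str = "all"                    # top1 | top2 | all
    t1: float = 0.99
    t2: float = 0.9
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def predict_assignments(
    spectra: Sequence[Spectrum],
    classifier: LinearDiscriminantChargeClassifier,
    extractor: ChargeFeatureExtractor,
    strategy: str = "all",
    t1: float = 0.99,
    t2: float = 0.9,
) -> list[ChargeAssignment]:
    """Posterior-based charge assignment for each spectrum (raw spectra —
    the features need the precursor and neutral-loss peaks intact)."""
    X = extractor.transform(spectra)
    P = classifier.predict_proba(X)
    full_range = sorted(int(c) for c in classifier.classes_)
    return [assign_charges(P[i], classifier.classes_, strategy, t1, t2,
                           full_range, scan_id=s.scan_id)
            for i, s in enumerate(spectra)]


def run_pipeline(config: PipelineConfig,
                 spectra: Sequence[Spectrum] | None = None) -> dict:
    """Run charge determination + filtering over an MGF (or given spectra).

    Writes the filtered MGF (precursor-filtered, deisotoped, thinned with
    the 1+ window/h1 settings; charge lines carry the assigned candidate
    sets) plus the assignment TSV, and returns a summary dictionary.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    if spectra is None:
        spectra = list(_io.read_mgf(config.input))
    n_in = len(spectra)
    spectra = [s for s in spectra if s.tic > 0]
    skipped = n_in - len(spectra)
    if skipped:
        logger.warning("skipped %d empty spectra", skipped)

    assignments: list[ChargeAssignment] | None = None
    if config.model:
        classifier, extractor = load_model(config.model)
        assignments = predict_assignments(spectra, classifier, extractor,
                                          config.strategy, config.t1, config.t2)
        for s, a in zip(spectra, assignments):
            s.charge_candidates = tuple(a.assigned)
            if len(a.assigned) == 1:
                s.precursor_charge = a.assigned[0]

    removed = {"precursor_filter": 0, "deisotoping": 0, "window_filter": 0}
    out_spectra: list[Spectrum] = []
    for s in spectra:
        filt = apply_precursor_filter(s, None, config.precursor_filter,
                                      config.W, config.N1, config.N2)
        removed["precursor_filter"] += len(s) - len(filt)
        deiso = deisotope(filt, config.isotope_tol)
        removed["deisotoping"] += len(filt) - len(deiso)
        mask = window_filter(deiso, config.window_1plus, config.h1)
        removed["window_filter"] += len(deiso) - int(mask.sum())
        out_spectra.append(deiso.replace_peaks(deiso.mz[mask],
                                               deiso.intensity[mask]))

    _io.write_mgf(out_spectra, config.output_mgf, assignments)
    summary: dict = {
        "spectra_in": n_in,
        "spectra_out": len(out_spectra),
        "skipped": skipped,
        "peaks_removed": removed,
    }
    if assignments is not None:
        _io.write_assignments(assignments, config.output_assignments)
        hist = {"1": 0, "2": 0, "all": 0}
        full = len(assignments[0].posteriors) if assignments else 0
        for a in assignments:
            key = ("1" if len(a.assigned) == 1
                   else "2" if len(a.assigned) == 2 else "all")
            hist[key] += 1
        summary["assignment_histogram"] = hist
    return summary


def evaluate_assignments(
    assignments: Sequence[ChargeAssignment],
    true_charges: Sequence[int],
) -> dict:
    """Confusion matrix (best predicted vs true charge) and the
    misclassification rate, defined as the fraction of spectra whose true
    charge is absent from the assigned candidate set."""
    if len(assignments) != len(true_charges):
        raise ValueError("assignments and true charges must align")
    best = [max(a.posteriors, key=lambda c: (a.posteriors[c], -c))
            for a in assignments]
    missed = sum(1 for a, t in zip(assignments, true_charges)
                 if int(t) not in a.assigned)
    labels = sorted({*best, *map(int, true_charges)})
    cm = pd.DataFrame(0, index=labels, columns=labels)
    for b, t in zip(best, true_charges):
        cm.loc[int(t), b] += 1
    cm.index.name = "true"
    cm.columns.name = "best_predicted"
    return {
        "confusion_matrix": cm,
        "misclassification_rate": missed / len(assignments),
        "n": len(assignments),
    }
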