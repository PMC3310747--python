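"""Reading and writing MGF peak lists and sidecar truth/assignment tables."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from pyteomics.auxiliary import ChargeList

from .charge import ChargeAssignment
from .simulate import SpectrumTruth
from .spectra import Spectrum

__all__ = ["read_mgf", "write_mgf", "write_truth_table", "read_truth_table",
           "write_assignments", "read_assignments"]

logger = logging.getLogger(__name__)


def read_mgf(path) -> Iterator[Spectrum]:
    """Yield one :class:`Spectrum` per ``BEGIN IONS`` block.

    ``PEPMASS`` (first token) becomes the precursor m/z; a block without it
    is skipped with a warning.  A single ``CHARGE`` value sets
    ``precursor_charge``; a multi-charge list (``CHARGE=3+ and 4+``) is
    stored as ``charge_candidates`` with the charge left unknown.  Peaks
    are sorted and exact-duplicate m/z values merged on construction.
    """
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"index={i}"))
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                logger.warning("skipping MGF block %r: no PEPMASS", title)
                continue
            charge = params.get("charge")
            precursor_charge = None
            candidates: tuple[int, ...] = ()
            if charge:
                values = tuple(int(c) for c in charge)
                if len(values) == 1:
                    precursor_charge = values[0]
                else:
                    candidates = values
            yield Spectrum(entry["m/z array"], entry["intensity array"],
                           precursor_mz=float(pepmass[0]),
                           precursor_charge=precursor_charge,
                           charge_candidates=candidates,
                           scan_id=title)


def write_mgf(
    spectra: Iterable[Spectrum],
    path,
    assignments: Sequence[ChargeAssignment] | None = None,
) -> None:
    """Write spectra as MGF.  When ``assignments`` is given (aligned with
    ``spectra``), each block's ``CHARGE`` line lists the assigned candidate
    charges ascending in the ``3+ and 4+`` dialect; otherwise the
    spectrum's own charge (if known) is written."""
    entries = []
    for i, s in enumerate(spectra):
        if assignments is not None:
            charges = sorted(assignments[i].assigned)
        elif s.precursor_charge is not None:
            charges = [s.precursor_charge]
        elif s.charge_candidates:
            charges = sorted(s.charge_candidates)
        else:
            charges = None
        params = {"title": s.scan_id, "pepmass": (s.precursor_mz,)}
        if charges:
            params["charge"] = ChargeList(charges)
        entries.append({"params": params, "m/z array": s.mz,
                        "intensity array": s.intensity})
    import io as _stringio

    buf = _stringio.StringIO()
    _mgf.write(entries, buf)
    text = "\n".join(
        line.replace(", ", " and ") if line.startswith("CHARGE=") else line
        for line in buf.getvalue().splitlines())
    with open(path, "w") as fh:
        fh.write(text + "\n")


def write_truth_table(truths: Sequence[SpectrumTruth], path) -> None:
    """TSV with one row per spectrum: scan id, true charge, neutral mass,
    and the comma-joined per-peak annotations."""
    df = pd.DataFrame({
        "scan_id": [t.scan_id for t in truths],
        "true_charge": [t.charge for t in truths],
        "neutral_mass": [round(t.neutral_mass, 6) for t in truths],
        "annotations": [",".join(t.annotations) for t in truths],
    })
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"scan_id": str})
    required = {"scan_id", "true_charge"}
    if not required.issubset(df.columns):
        raise ValueError(f"truth table must have columns {sorted(required)}")
    return df


def write_assignments(assignments: Sequence[ChargeAssignment], path) -> None:
    """TSV of charge assignments: scan id, strategy, assigned charges
    (comma-joined ascending) and the per-class posteriors."""
    rows = []
    for a in assignments:
        row = {"scan_id": a.scan_id, "strategy": a.strategy,
               "assigned": ",".join(str(c) for c in sorted(a.assigned))}
        for c, p in sorted(a.posteriors.items()):
            row[f"p{c}"] = round(p, 6)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"scan_id": str})
    df["assigned"] = df["assigned"].map(
        lambda s: tuple(int(c) for c in str(s).split(",")))
    return df
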