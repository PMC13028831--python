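"""Reading, writing, windowing, masking and referencing of 1D spectra.

A processed frequency-domain proton spectrum is represented by
:class:`Spectrum1D`: a strictly monotone, descending chemical-shift axis
(ppm) with one real intensity per point.  Spectra are exchanged as plain
two-column text (ppm, intensity), whitespace- or comma-separated, with
``#`` comment headers — the dialect produced by common processed-spectrum
exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Global chemical-shift window used throughout the analysis (ppm).
GLOBAL_WINDOW = (-0.5, 11.0)

SOLVENTS = ("aqueous_buffer", "cdcl3")
REFERENCES = ("tsp", "residual_solvent")


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file or axis violates the format contract."""


@dataclass(frozen=True)
class Spectrum1D:
    """A referenced frequency-domain trace on a descending ppm axis.

    Parameters
    ----------
    ppm : numpy.ndarray
        Strictly monotonically decreasing chemical-shift axis, ppm.
    intensity : numpy.ndarray
        Real intensities (a.u.), same length as ``ppm``.
    solvent : str
        ``"aqueous_buffer"`` (polar fraction) or ``"cdcl3"`` (apolar).
    reference : str
        ``"tsp"`` or ``"residual_solvent"``.
    sample_id : str
        Free-text sample identifier.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    solvent: str = "aqueous_buffer"
    reference: str = "tsp"
    sample_id: str = ""

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or intensity.ndim != 1:
            raise SpectrumFormatError("ppm and intensity must be 1-D vectors")
        if len(ppm) != len(intensity):
            raise SpectrumFormatError(
                f"axis/intensity length mismatch: {len(ppm)} vs {len(intensity)}"
            )
        if len(ppm) >= 2:
            d = np.diff(ppm)
            if not (np.all(d < 0) or np.all(d > 0)):
                raise SpectrumFormatError("chemical-shift axis is not strictly monotone")
            if d[0] > 0:  # normalise to descending ppm
                ppm = ppm[::-1].copy()
                intensity = intensity[::-1].copy()
        if not np.all(np.isfinite(intensity)):
            raise SpectrumFormatError("non-finite intensities")
        if not np.all(np.isfinite(ppm)):
            raise SpectrumFormatError("non-finite chemical shifts")
        if self.solvent not in SOLVENTS:
            raise SpectrumFormatError(f"unknown solvent {self.solvent!r}")
        if self.reference not in REFERENCES:
            raise SpectrumFormatError(f"unknown reference {self.reference!r}")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return len(self.ppm)


@dataclass(frozen=True)
class ExclusionMask:
    """Chemical-shift intervals to drop from feature matrices.

    ``regions`` is a list of ``(low_ppm, high_ppm)`` pairs; overlapping
    regions are interpreted with union semantics.
    """

    regions: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        regions = tuple((float(lo), float(hi)) for lo, hi in self.regions)
        lo_g, hi_g = GLOBAL_WINDOW
        for lo, hi in regions:
            if not lo < hi:
                raise ValueError(f"mask region ({lo}, {hi}): low must be < high")
            if hi < lo_g or lo > hi_g:
                raise ValueError(
                    f"mask region ({lo}, {hi}) outside global window {GLOBAL_WINDOW}"
                )
        object.__setattr__(self, "regions", regions)

    def covers(self, ppm: np.ndarray) -> np.ndarray:
        """Boolean vector: True where ``ppm`` falls inside any region."""
        ppm = np.asarray(ppm, dtype=float)
        hit = np.zeros(ppm.shape, dtype=bool)
        for lo, hi in self.regions:
            hit |= (ppm >= lo) & (ppm <= hi)
        return hit


#: Default exclusions for polar (aqueous) spectra: residual water and the
#: TSP reference singlet.  Bounds are configuration, not data.
DEFAULT_POLAR_MASK = ExclusionMask(regions=((4.70, 5.00), (-0.05, 0.05)))
#: Default exclusion for apolar spectra: residual CHCl3.
DEFAULT_APOLAR_MASK = ExclusionMask(regions=((7.24, 7.30),))


def read_spectrum_text(path, solvent: str = "aqueous_buffer") -> Spectrum1D:
    """Read a two-column (ppm, intensity) text spectrum.

    Lines starting with ``#`` are treated as comments; ``# key: value``
    headers for ``sample_id``, ``solvent`` and ``reference`` are honoured.
    The axis is normalised to descending ppm.
    """
    path = Path(path)
    meta = {"solvent": solvent, "reference": "tsp" if solvent == "aqueous_buffer" else "residual_solvent", "sample_id": path.stem}
    ppm, inten = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip().lower()
                    if key in meta:
                        meta[key] = val.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumFormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                ppm.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if not ppm:
        raise SpectrumFormatError(f"{path}: no data rows")
    return Spectrum1D(np.array(ppm), np.array(inten), **meta)


def write_spectrum_text(sp: Spectrum1D, path) -> None:
    """Write a spectrum in the two-column text dialect (round-trip safe)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {sp.sample_id}\n")
        fh.write(f"# solvent: {sp.solvent}\n")
        fh.write(f"# reference: {sp.reference}\n")
        for x, y in zip(sp.ppm, sp.intensity):
            fh.write(f"{x:.10f} {y:.12e}\n")


def window_spectrum(sp: Spectrum1D, low_ppm: float = GLOBAL_WINDOW[0],
                    high_ppm: float = GLOBAL_WINDOW[1]) -> Spectrum1D:
    """Retain only points with ``low_ppm <= ppm <= high_ppm``."""
    if not low_ppm < high_ppm:
        raise ValueError(f"degenerate window ({low_ppm}, {high_ppm}): low must be < high")
    keep = (sp.ppm >= low_ppm) & (sp.ppm <= high_ppm)
    if not keep.any():
        raise ValueError(f"window ({low_ppm}, {high_ppm}) retains no points")
    return replace(sp, ppm=sp.ppm[keep], intensity=sp.intensity[keep])


def reference_to_tsp(sp: Spectrum1D, search_halfwidth_ppm: float = 0.1) -> Spectrum1D:
    """Shift the axis so the reference maximum near 0 ppm sits at 0.00 ppm.

    The apex is the maximum intensity within ``±search_halfwidth_ppm`` of
    0 ppm.  Ties break deterministically to the most downfield (largest
    ppm) candidate.
    """
    if search_halfwidth_ppm <= 0:
        raise ValueError("search_halfwidth_ppm must be positive")
    in_win = np.abs(sp.ppm) <= search_halfwidth_ppm
    if not in_win.any():
        raise ValueError("no points within the TSP search window")
    idx = np.flatnonzero(in_win)
    vals = sp.intensity[idx]
    vmax = vals.max()
    # ppm is descending, so the first index at the max is the most downfield
    apex = idx[np.flatnonzero(vals == vmax)[0]]
    shift = sp.ppm[apex]
    return replace(sp, ppm=sp.ppm - shift)


def apply_mask(matrix, mask: ExclusionMask):
    """Drop feature-matrix columns whose ppm labels fall in any masked region.

    Operates on :class:`gonadnmr.chemometrics.FeatureMatrix` with numeric
    (ppm) column labels.  Returns a new matrix; the number of removed
    columns is logged.
    """
    labels = np.asarray(matrix.var_labels, dtype=float)
    drop = mask.covers(labels)
    if drop.all():
        raise ValueError("exclusion mask removes every column")
    n_drop = int(drop.sum())
    logger.info("apply_mask: removed %d of %d columns", n_drop, len(labels))
    return matrix.select_vars(~drop)


def common_grid(spectra: Sequence[Spectrum1D]) -> np.ndarray:
    """Validate that spectra share one axis and return it."""
    ref = spectra[0].ppm
    for sp in spectra[1:]:
        if len(sp.ppm) != len(ref) or not np.allclose(sp.ppm, ref, atol=1e-12):
            raise SpectrumFormatError("spectra are not on a common chemical-shift grid")
    return ref
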