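"""Curated peak tables and peak-height feature extraction.

The package ships two versioned, checksummed CSV tables: the polar-extract
resonance list (72 entries: chemical shift, multiplicity, proposed
metabolite, moiety, confidence grade) and the apolar lipid-motif
annotation layer (29 entries).  They are the citable reference layer of
the analysis; peak-height features for supervised modelling are extracted
at the annotated shifts.

Unique-metabolite counting collapses qualifier suffixes under explicit,
inspectable rules (see :func:`canonical_name`): parenthetical qualifiers
such as "(tentative)" are stripped, "-related"/"-like"/" region"
suffixes removed, composite rows naming several distinct candidates
("X and/or Y") are treated as ambiguous and excluded, and a small alias
map resolves the remaining composite labels (e.g. the AMP-like adenine
nucleotide row counts as AMP).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from gonadnmr.spectra import Spectrum1D

MULTIPLICITIES = ("s", "d", "t", "m", "dm", "sm", "unknown")
CONFIDENCES = ("assigned", "tentative", "putative", "unassigned")

_BUNDLED = {"polar": "polar_peaks.csv", "apolar": "apolar_peaks.csv"}


class TableIntegrityError(RuntimeError):
    """Raised when a bundled table fails its checksum."""


@dataclass(frozen=True)
class AnnotatedPeak:
    peak_no: int
    delta_ppm: float
    multiplicity: str
    metabolite: str
    moiety: str = ""
    confidence: str = "assigned"
    lipid_class: str = ""

    def __post_init__(self) -> None:
        if self.multiplicity not in MULTIPLICITIES:
            raise ValueError(f"peak {self.peak_no}: bad multiplicity {self.multiplicity!r}")
        if self.confidence not in CONFIDENCES:
            raise ValueError(f"peak {self.peak_no}: bad confidence {self.confidence!r}")


@dataclass(frozen=True)
class PeakTable:
    fraction: str  # "polar" or "apolar"
    peaks: tuple

    def __post_init__(self) -> None:
        if self.fraction not in ("polar", "apolar"):
            raise ValueError(f"unknown fraction {self.fraction!r}")
        lo, hi = (-0.5, 11.0) if self.fraction == "polar" else (0.0, 10.0)
        nos = [p.peak_no for p in self.peaks]
        if len(set(nos)) != len(nos):
            raise ValueError("duplicate peak_no")
        shifts = [p.delta_ppm for p in self.peaks]
        order = sorted(range(len(nos)), key=lambda i: nos[i])
        if any(shifts[order[i]] > shifts[order[i + 1]] for i in range(len(order) - 1)):
            raise ValueError("shifts must be non-decreasing in peak_no order")
        for p in self.peaks:
            if not lo <= p.delta_ppm <= hi:
                raise ValueError(f"peak {p.peak_no} at {p.delta_ppm} ppm outside [{lo}, {hi}]")

    def __len__(self) -> int:
        return len(self.peaks)

    def peak(self, peak_no: int) -> AnnotatedPeak:
        for p in self.peaks:
            if p.peak_no == peak_no:
                return p
        raise KeyError(peak_no)

    def shifts(self) -> np.ndarray:
        return np.array([p.delta_ppm for p in self.peaks])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.peaks]).set_index("peak_no")


def _read_checksums() -> dict:
    text = resources.files("gonadnmr.data").joinpath("checksums.sha256").read_text()
    out = {}
    for line in text.splitlines():
        if line.strip():
            digest, name = line.split()
            out[name] = digest
    return out


def load_bundled_table(fraction: str) -> PeakTable:
    """Load the packaged polar (72-entry) or apolar (29-entry) peak table.

    The file's SHA-256 digest is verified against the shipped checksum;
    a mismatch raises :class:`TableIntegrityError`.
    """
    if fraction not in _BUNDLED:
        raise ValueError(f"fraction must be one of {sorted(_BUNDLED)}")
    name = _BUNDLED[fraction]
    raw = resources.files("gonadnmr.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _read_checksums()[name]
    if digest != expected:
        raise TableIntegrityError(f"{name}: checksum {digest} != expected {expected}")
    df = pd.read_csv(pd.io.common.BytesIO(raw), keep_default_na=False)
    peaks = []
    for _, row in df.iterrows():
        peaks.append(AnnotatedPeak(
            peak_no=int(row["peak_no"]),
            delta_ppm=float(row["delta_ppm"]),
            multiplicity=str(row["multiplicity"]),
            metabolite=str(row["metabolite"]),
            moiety=str(row["moiety"]),
            confidence=str(row["confidence"]),
            lipid_class=str(row.get("lipid_class", "")),
        ))
    return PeakTable(fraction=fraction, peaks=tuple(peaks))


# ---------------------------------------------------------------------------
# peak-height extraction
# ---------------------------------------------------------------------------

def extract_peak_heights(sp: Spectrum1D, table: PeakTable,
                         tol_ppm: float = 0.005) -> pd.Series:
    """Baseline-subtracted peak heights at the annotated shifts.

    For each annotated shift the height is the maximum intensity within
    ``±tol_ppm`` minus a local baseline (median intensity in flanking
    bands 0.02–0.03 ppm either side).  Shifts whose window contains no
    grid point are reported as NaN (absent), never as zero.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    heights = {}
    ppm = sp.ppm
    inten = sp.intensity
    for p in table.peaks:
        d = np.abs(ppm - p.delta_ppm)
        win = d <= tol_ppm
        if not win.any():
            heights[p.peak_no] = np.nan
            continue
        flank = (d >= 0.02) & (d <= 0.03)
        baseline = float(np.median(inten[flank])) if flank.any() else 0.0
        heights[p.peak_no] = float(inten[win].max() - baseline)
    return pd.Series(heights, name=sp.sample_id)


def peak_height_matrix(spectra, table: PeakTable, tol_ppm: float = 0.005,
                       y=None):
    """Stack per-spectrum peak heights into a FeatureMatrix.

    Columns with any absent (NaN) height are dropped; remaining columns
    are labelled by peak_no.
    """
    from gonadnmr.chemometrics import FeatureMatrix

    rows = [extract_peak_heights(sp, table, tol_ppm) for sp in spectra]
    df = pd.DataFrame(rows)
    df = df.dropna(axis=1)
    return FeatureMatrix(
        X=df.to_numpy(), var_labels=df.columns.to_numpy(),
        y=None if y is None else np.asarray(y),
        sample_ids=np.array([sp.sample_id for sp in spectra]),
    )


# ---------------------------------------------------------------------------
# unique-metabolite counting
# ---------------------------------------------------------------------------

#: Composite labels naming several distinct candidates: ambiguous, excluded
#: from the unique count.
AMBIGUOUS_LABELS = frozenset({
    "Choline (tentative)/methylamine region",
    "Pyrimidine nucleoside (uridine/cytidine-like)",
    "Xanthine and/or Tryptophan",
})

#: Explicit resolutions for composite or qualified labels the general
#: rules cannot collapse on their own.
NAME_ALIASES = {
    "Methanol (shoulder)/unassigned": "Methanol",
    "Choline/choline derivatives": "Choline",
    "Choline-related (probable)": "Choline",
    "Purine riboside/ribonucleotide (inosine/IMP-like)": "Purine riboside",
    "Phenolic aromatic (vanillic/vanillin-like, putative)": "Vanillic acid",
    "Trehalose/carbohydrate (putative)": "Trehalose",
    "Adenine nucleotide (AMP-like)": "AMP",
    "Kynurenine-like (HSQC-consistent; downfield-shifted)": "Kynurenine",
    "Trimethylamine oxide (TMAO)": "TMAO",
}

_PAREN = re.compile(r"\s*\([^)]*\)")


def canonical_name(raw: str) -> Optional[str]:
    """Collapse a table label to a canonical metabolite name.

    Returns None for unassigned or ambiguous labels.  Rules, in order:
    alias map; drop "Unassigned"; ambiguous composites excluded; strip
    parenthetical qualifiers; strip "-related"/"-like"/" region"
    suffixes; collapse duplicate "/"-separated tokens.
    """
    raw = raw.strip()
    if not raw:
        return None
    if raw in NAME_ALIASES:
        return NAME_ALIASES[raw]
    if raw in AMBIGUOUS_LABELS:
        return None
    if raw.lower().startswith("unassigned"):
        return None
    name = _PAREN.sub("", raw).strip()
    if " and/or " in name:
        return None
    name = re.sub(r"-(related|like)$", "", name)
    name = re.sub(r"\s+region$", "", name)
    if "/" in name:
        tokens = {t.strip().lower() for t in name.split("/") if t.strip()}
        if len(tokens) != 1:
            return None
        name = name.split("/")[0].strip()
    return name or None


def count_unique_metabolites(table: PeakTable) -> int:
    """Number of distinct metabolites named by the table.

    Unassigned entries and ambiguous composite rows are excluded; the
    collapsing rules are those of :func:`canonical_name`.  The count is
    reported as computed — any discrepancy with an externally quoted
    figure is for the caller to surface, not silently forced.
    """
    names = {canonical_name(p.metabolite) for p in table.peaks}
    names.discard(None)
    return len(names)
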