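"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a two-site sea-urchin gonad study: 37
samples (23 male, 14 female) with per-sex biometrics, a polar aqueous
spectrum per sample built from Lorentzian multiplets at the curated
resonance shifts with log-normal inter-individual variation and sex-shifted
concentrations of the discriminant metabolites, and an apolar CDCl3
spectrum composed from a known lipid composition (mol% unsaturated,
saturated, omega-3, DHA).

Line shapes are Lorentzian with a default half-width at half-maximum of
0.003 ppm (≈1.2 Hz at a 400 MHz field, matching 0.3 Hz exponential line
broadening on natural linewidths); multiplets are binomial-weighted stick
patterns (d 1:1, t 1:2:1, m an unresolved five-stick cluster) with a
default 7 Hz coupling (0.0175 ppm at 400 MHz).

Apolar diagnostic peaks are rendered with finite support clipped to their
own integration window and renormalised on the grid, so each region's
trapezoidal integral equals its stoichiometric target exactly in the
noise-free limit — the property the downstream balance-equation solver is
tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from gonadnmr.spectra import Spectrum1D, GLOBAL_WINDOW
from gonadnmr.lipids import (
    RegionWindows, Stoichiometry, DEFAULT_STOICHIOMETRY,
)

#: default Lorentzian HWHM (ppm); ~1.2 Hz at 400 MHz
DEFAULT_HWHM = 0.003
#: default 3J(H,H) coupling, ppm at 400 MHz (7 Hz / 400 MHz)
DEFAULT_J_PPM = 0.0175

_MULTIPLET_PATTERNS = {
    "s": ((0.0,), (1.0,)),
    "d": ((-0.5, 0.5), (1.0, 1.0)),
    "t": ((-1.0, 0.0, 1.0), (1.0, 2.0, 1.0)),
    # unresolved cluster: five sticks at half-J spacing
    "m": ((-1.0, -0.5, 0.0, 0.5, 1.0), (1.0, 2.0, 3.0, 2.0, 1.0)),
}
_MULT_FALLBACK = {"dm": "m", "sm": "m", "unknown": "s"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakShape:
    """One resonance: position, multiplicity, coupling, width, proton count."""

    center_ppm: float
    multiplicity: str = "s"
    J_ppm: float = DEFAULT_J_PPM
    halfwidth_ppm: float = DEFAULT_HWHM
    protons: int = 1

    def __post_init__(self) -> None:
        if self.halfwidth_ppm <= 0:
            raise ValueError("halfwidth_ppm must be positive")
        if self.protons < 1:
            raise ValueError("protons must be >= 1")
        if self.J_ppm < 0:
            raise ValueError("J_ppm must be >= 0")
        m = self.multiplicity
        if m not in _MULTIPLET_PATTERNS and m not in _MULT_FALLBACK:
            raise ValueError(f"unknown multiplicity {m!r}")

    def sticks(self) -> Tuple[np.ndarray, np.ndarray]:
        """(offsets_ppm, area_fractions) of the multiplet stick pattern."""
        m = _MULT_FALLBACK.get(self.multiplicity, self.multiplicity)
        offsets, weights = _MULTIPLET_PATTERNS[m]
        offs = np.asarray(offsets) * (0.0 if m == "s" else self.J_ppm)
        w = np.asarray(weights, dtype=float)
        return self.center_ppm + offs, w / w.sum()


@dataclass(frozen=True)
class MetaboliteSpec:
    """A metabolite's peaks plus its cohort-level concentration model."""

    name: str
    peaks: Tuple[PeakShape, ...]
    base_conc: float = 1.0
    sex_log2fc: float = 0.0
    cv_biological: float = 0.3

    def __post_init__(self) -> None:
        if self.base_conc <= 0:
            raise ValueError(f"{self.name}: base_conc must be positive")
        if self.cv_biological < 0:
            raise ValueError(f"{self.name}: cv_biological must be >= 0")
        lo, hi = GLOBAL_WINDOW
        for p in self.peaks:
            if not lo <= p.center_ppm <= hi:
                raise ValueError(
                    f"{self.name}: peak at {p.center_ppm} ppm outside window {GLOBAL_WINDOW}")
        object.__setattr__(self, "peaks", tuple(self.peaks))


@dataclass(frozen=True)
class LipidComposition:
    """Ground-truth acyl-chain composition, mol% of total chains."""

    n_unsat: float
    s_sat: float
    omega3: float
    dha: float
    mean_db_per_unsat_chain: float = 3.0
    glyceride_fraction: float = 0.9

    def __post_init__(self) -> None:
        if abs(self.n_unsat + self.s_sat - 100.0) > 1e-9:
            raise ValueError("n_unsat + s_sat must equal 100 exactly")
        if not 0 <= self.dha <= self.omega3 <= self.n_unsat <= 100:
            raise ValueError(
                "composition must satisfy 0 <= dha <= omega3 <= n_unsat <= 100")
        if self.mean_db_per_unsat_chain < 1:
            raise ValueError("mean_db_per_unsat_chain must be >= 1")
        if not 0 <= self.glyceride_fraction <= 1:
            raise ValueError("glyceride_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SexStats:
    """Per-sex biometric mean/sd (units in the field names)."""

    diameter_mm: tuple
    height_mm: tuple
    weight_g: tuple
    gonad_g: tuple


#: Cohort biometrics emulating the study table (mean ± sd).
DEFAULT_BIOMETRICS = {
    "M": SexStats(diameter_mm=(48.7, 6.5), height_mm=(27.5, 3.7),
                  weight_g=(50.0, 15.4), gonad_g=(4.0, 2.3)),
    "F": SexStats(diameter_mm=(52.5, 6.5), height_mm=(29.6, 4.2),
                  weight_g=(54.5, 20.5), gonad_g=(3.7, 2.7)),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort shape and acquisition-level nuisance parameters."""

    n_male: int = 23
    n_female: int = 14
    seed: int = 0
    noise_sd: float = 0.5
    baseline_amp: float = 0.0
    grid_points: int = 32768
    biometrics_model: Dict[str, SexStats] = field(
        default_factory=lambda: dict(DEFAULT_BIOMETRICS))

    def __post_init__(self) -> None:
        if self.n_male < 1 or self.n_female < 1:
            raise ValueError("need at least one sample per sex")
        if self.grid_points < 1024:
            raise ValueError("grid_points must be >= 1024")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SampleMeta:
    sample_id: str
    sex: str
    site: str
    diameter_mm: float
    height_mm: float
    weight_g: float
    gonad_g: float
    gsi_pct: float


# ---------------------------------------------------------------------------
# grid / rendering helpers
# ---------------------------------------------------------------------------

def make_grid(grid_points: int) -> np.ndarray:
    """Ascending ppm grid spanning the global window."""
    lo, hi = GLOBAL_WINDOW
    return np.linspace(lo, hi, grid_points)


def _add_lorentzian(grid: np.ndarray, out: np.ndarray, center: float,
                    area: float, hw: float, support: float = 0.4) -> None:
    """Accumulate a Lorentzian of given total area, rendered within
    ``±support`` ppm of its centre (tails beyond are negligible)."""
    i0, i1 = np.searchsorted(grid, (center - support, center + support))
    x = grid[i0:i1] - center
    out[i0:i1] += (area * hw / math.pi) / (x * x + hw * hw)


def _add_window_normalised_peaks(grid: np.ndarray, out: np.ndarray,
                                 centers: Sequence[float], weights: Sequence[float],
                                 window: Tuple[float, float], area: float,
                                 hw: float) -> None:
    """Render Lorentzians confined to ``window`` whose on-grid trapezoidal
    integral over the window equals ``area`` exactly."""
    lo, hi = window
    sel = (grid >= lo) & (grid <= hi)
    if sel.sum() < 2:
        raise ValueError(f"window ({lo}, {hi}) has fewer than 2 grid points")
    x = grid[sel]
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    shape = np.zeros_like(x)
    for c, wt in zip(centers, w):
        shape += wt * (hw / math.pi) / ((x - c) ** 2 + hw * hw)
    raw = np.trapezoid(shape, x)
    out[sel] += shape * (area / raw)


def _baseline(grid: np.ndarray, amp: float, rng: np.random.Generator) -> np.ndarray:
    if amp == 0:
        return np.zeros_like(grid)
    lo, hi = grid[0], grid[-1]
    u = 2 * (grid - lo) / (hi - lo) - 1.0
    coef = rng.normal(0.0, 1.0, size=4)
    return amp * np.polynomial.polynomial.polyval(u, coef)


# ---------------------------------------------------------------------------
# polar spectra
# ---------------------------------------------------------------------------

#: area of the TSP reference singlet (9 equivalent protons at 0.5 mM,
#: arbitrary units consistent with base_conc ~ 1)
TSP_AREA = 4.5


def generate_polar_spectrum(specs: Sequence[MetaboliteSpec],
                            concentrations: Dict[str, float],
                            cfg: CohortConfig, seed: int,
                            sample_id: str = "") -> Spectrum1D:
    """Render one polar aqueous spectrum from metabolite concentrations.

    Each multiplet's total area is concentration x protons; a TSP
    reference singlet is added at 0.00 ppm.  Identical seeds give
    bit-identical spectra.
    """
    grid = make_grid(cfg.grid_points)
    out = np.zeros_like(grid)
    for spec in specs:
        conc = concentrations[spec.name]
        if conc <= 0:
            raise ValueError(f"{spec.name}: concentration must be positive")
        for peak in spec.peaks:
            centers, fracs = peak.sticks()
            total = conc * peak.protons
            for c, f in zip(centers, fracs):
                _add_lorentzian(grid, out, c, total * f, peak.halfwidth_ppm)
    _add_lorentzian(grid, out, 0.0, TSP_AREA, DEFAULT_HWHM)
    rng = np.random.default_rng(seed)
    out += _baseline(grid, cfg.baseline_amp, rng)
    if cfg.noise_sd > 0:
        out += rng.normal(0.0, cfg.noise_sd, size=out.shape)
    return Spectrum1D(ppm=grid, intensity=out, solvent="aqueous_buffer",
                      reference="tsp", sample_id=sample_id)


# ---------------------------------------------------------------------------
# apolar spectra
# ---------------------------------------------------------------------------

#: diagnostic peak positions per region (from the apolar annotation layer)
REGION_PEAKS = {
    "A": ((0.9739,), (1.0,)),
    "B": ((0.8806,), (1.0,)),
    "C": ((1.2563, 1.3022), (1.0, 1.0)),
    "D": ((1.6032, 1.6757), (1.5, 1.0)),
    "E": ((2.0202, 2.0780), (1.0, 1.0)),
    "F": ((2.3079,), (1.0,)),
    "Fprime": ((2.3869,), (1.0,)),
    "G": ((2.7722, 2.8094, 2.8424), (1.0, 1.0, 1.0)),
    "H": ((4.1673, 4.2848), (1.0, 1.0)),
    "I": ((5.2784,), (1.0,)),
    "J": ((5.3654,), (1.0,)),
}

#: out-of-region motifs added for realism (sterols, phospholipid headgroups);
#: (centre, area) pairs with narrow support so they never touch a window
_EXTRA_APOLAR_PEAKS = ((0.6803, 6.0), (3.3273, 8.0), (3.5343, 1.5), (3.9490, 3.0))

#: bulk methylene-envelope protons per chain (chain-length proxy) for region C
C_PROTONS_PER_CHAIN = 16.0
#: beta-methylene protons per chain for region D
D_PROTONS_PER_CHAIN = 2.0


def region_target_areas(comp: LipidComposition,
                        stoich: Stoichiometry = DEFAULT_STOICHIOMETRY) -> Dict[str, float]:
    """Proton-stoichiometric target area per region, per 100 acyl chains."""
    db_total = comp.mean_db_per_unsat_chain * comp.n_unsat
    glycerols = comp.glyceride_fraction * 100.0 / 3.0
    return {
        "A": stoich.k_terminal * comp.omega3,
        "B": stoich.k_terminal * (100.0 - comp.omega3),
        "C": C_PROTONS_PER_CHAIN * 100.0,
        "D": D_PROTONS_PER_CHAIN * 100.0,
        "E": stoich.k_E * comp.n_unsat,
        "F": 2.0 * (100.0 - comp.dha),
        "Fprime": stoich.k_Fprime * comp.dha,
        "G": max(2.0 * (comp.mean_db_per_unsat_chain - 1.0), 0.0) * comp.n_unsat,
        "H": 4.0 * glycerols,
        "I": 1.0 * glycerols,
        "J": 2.0 * db_total,
    }


def generate_apolar_spectrum(comp: LipidComposition, cfg: CohortConfig,
                             seed: int, sample_id: str = "",
                             windows: Optional[RegionWindows] = None,
                             stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
                             scale: float = 1.0) -> Spectrum1D:
    """Render one apolar CDCl3 spectrum from a lipid composition.

    Region integrals follow the shared stoichiometry table exactly in the
    noise-free limit (peaks are window-confined and grid-renormalised);
    deterministic under ``seed``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    windows = windows or RegionWindows()
    grid = make_grid(cfg.grid_points)
    out = np.zeros_like(grid)
    targets = region_target_areas(comp, stoich)
    for letter, (centers, weights) in REGION_PEAKS.items():
        area = targets[letter] * scale
        if area <= 0:
            continue
        _add_window_normalised_peaks(grid, out, centers, weights,
                                     windows[letter], area, DEFAULT_HWHM)
    for center, area in _EXTRA_APOLAR_PEAKS:
        _add_lorentzian(grid, out, center, area * scale, DEFAULT_HWHM,
                        support=0.03)
    rng = np.random.default_rng(seed)
    out += _baseline(grid, cfg.baseline_amp, rng)
    if cfg.noise_sd > 0:
        out += rng.normal(0.0, cfg.noise_sd, size=out.shape)
    return Spectrum1D(ppm=grid, intensity=out, solvent="cdcl3",
                      reference="residual_solvent", sample_id=sample_id)


# ---------------------------------------------------------------------------
# default metabolite panel
# ---------------------------------------------------------------------------

#: sex effects (log2 fold change, female vs male) seeded into the default
#: panel; the remaining metabolites carry no effect.  Magnitudes are
#: placeholders in the 0.5–1.0 range, not measured values.
DEFAULT_SEX_EFFECTS = {
    "Glycine": 1.0,
    "Alanine": -0.8,
    "Creatine": 0.7,
    "Betaine": 0.6,
    "TMAO": 0.6,
    "Histidine": -0.5,
    "Lysine": -0.6,
}


def default_metabolite_specs() -> List[MetaboliteSpec]:
    """Build the default panel from the bundled polar peak table.

    One spec per distinct table label (unassigned rows become single-peak
    pseudo-metabolites), all at unit base concentration with cv 0.3, with
    the discriminant sex effects applied by canonical name.
    """
    from gonadnmr.annotation import load_bundled_table, canonical_name

    table = load_bundled_table("polar")
    groups: Dict[str, list] = {}
    for p in table.peaks:
        label = p.metabolite
        if label.lower().startswith("unassigned"):
            label = f"peak{p.peak_no}_unassigned"
        groups.setdefault(label, []).append(p)
    specs = []
    for label, rows in groups.items():
        peaks = tuple(
            PeakShape(center_ppm=r.delta_ppm, multiplicity=r.multiplicity,
                      J_ppm=DEFAULT_J_PPM, halfwidth_ppm=DEFAULT_HWHM, protons=1)
            for r in rows)
        canon = canonical_name(rows[0].metabolite)
        fc = DEFAULT_SEX_EFFECTS.get(canon, 0.0) if canon else 0.0
        specs.append(MetaboliteSpec(name=label, peaks=peaks, base_conc=1.0,
                                    sex_log2fc=fc, cv_biological=0.3))
    return specs


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _positive_normal(rng, mean, sd, floor=0.1):
    return float(max(rng.normal(mean, sd), floor))


def _sample_meta(i: int, sex: str, cfg: CohortConfig,
                 rng: np.random.Generator) -> SampleMeta:
    stats = cfg.biometrics_model[sex]
    weight = _positive_normal(rng, *stats.weight_g, floor=5.0)
    gonad = _positive_normal(rng, *stats.gonad_g, floor=0.2)
    return SampleMeta(
        sample_id=f"PL{i + 1:03d}", sex=sex,
        site="alicante" if i % 2 == 0 else "javea",
        diameter_mm=_positive_normal(rng, *stats.diameter_mm, floor=20.0),
        height_mm=_positive_normal(rng, *stats.height_mm, floor=10.0),
        weight_g=weight, gonad_g=gonad, gsi_pct=100.0 * gonad / weight,
    )


def generate_cohort(cfg: CohortConfig,
                    specs: Optional[Sequence[MetaboliteSpec]] = None
                    ) -> Tuple[List[SampleMeta], List[Spectrum1D]]:
    """Generate the polar cohort: metadata plus one spectrum per sample.

    Per-sample concentrations are ``base_conc * 2^(±sex_log2fc/2)`` (plus
    half the fold change to each sex) with a multiplicative log-normal
    factor of coefficient of variation ``cv_biological``.  Deterministic
    under ``cfg.seed``.
    """
    if specs is None:
        specs = default_metabolite_specs()
    ss = np.random.SeedSequence(cfg.seed)
    n = cfg.n_male + cfg.n_female
    children = ss.spawn(n)
    sexes = ["M"] * cfg.n_male + ["F"] * cfg.n_female
    metas, spectra = [], []
    for i, (sex, child) in enumerate(zip(sexes, children)):
        rng = np.random.default_rng(child)
        meta = _sample_meta(i, sex, cfg, rng)
        sign = 1.0 if sex == "F" else -1.0
        conc = {}
        for spec in specs:
            mu = spec.base_conc * 2.0 ** (sign * spec.sex_log2fc / 2.0)
            if spec.cv_biological > 0:
                sigma = math.sqrt(math.log(1.0 + spec.cv_biological ** 2))
                mu *= math.exp(rng.normal(0.0, sigma))
            conc[spec.name] = mu
        spectrum_seed = int(rng.integers(0, 2 ** 31))
        spectra.append(generate_polar_spectrum(
            specs, conc, cfg, seed=spectrum_seed, sample_id=meta.sample_id))
        metas.append(meta)
    return metas, spectra


#: per-sex median lipid compositions for the default apolar cohort
DEFAULT_SEX_COMPOSITION = {
    "M": {"n_unsat": 66.6, "omega3": 21.6, "dha": 1.74},
    "F": {"n_unsat": 57.9, "omega3": 19.4, "dha": 1.52},
}

#: inter-individual spread (sd, mol%) of the composition draws
DEFAULT_COMPOSITION_SD = {"n_unsat": 6.0, "omega3": 1.2, "dha": 0.3}


def generate_apolar_cohort(cfg: CohortConfig,
                           sex_medians: Optional[Dict[str, Dict[str, float]]] = None,
                           composition_sd: Optional[Dict[str, float]] = None,
                           windows: Optional[RegionWindows] = None,
                           stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
                           ) -> Tuple[List[SampleMeta], List[Spectrum1D], List[LipidComposition]]:
    """Generate the apolar cohort with per-sample ground-truth compositions.

    Per-sample mol% values are Gaussian draws around the per-sex medians,
    clipped to preserve ``dha <= omega3 <= n_unsat``.  Returns metadata,
    spectra and the generating compositions.
    """
    sex_medians = sex_medians or DEFAULT_SEX_COMPOSITION
    sd = composition_sd or DEFAULT_COMPOSITION_SD
    ss = np.random.SeedSequence(cfg.seed)
    n = cfg.n_male + cfg.n_female
    children = ss.spawn(n)
    sexes = ["M"] * cfg.n_male + ["F"] * cfg.n_female
    metas, spectra, comps = [], [], []
    for i, (sex, child) in enumerate(zip(sexes, children)):
        rng = np.random.default_rng(child)
        meta = _sample_meta(i, sex, cfg, rng)
        med = sex_medians[sex]
        n_unsat = float(np.clip(rng.normal(med["n_unsat"], sd["n_unsat"]), 5.0, 95.0))
        omega3 = float(np.clip(rng.normal(med["omega3"], sd["omega3"]), 0.5, n_unsat))
        dha = float(np.clip(rng.normal(med["dha"], sd["dha"]), 0.0, omega3))
        comp = LipidComposition(n_unsat=n_unsat, s_sat=100.0 - n_unsat,
                                omega3=omega3, dha=dha)
        spectrum_seed = int(rng.integers(0, 2 ** 31))
        spectra.append(generate_apolar_spectrum(
            comp, cfg, seed=spectrum_seed, sample_id=meta.sample_id,
            windows=windows, stoich=stoich))
        metas.append(meta)
        comps.append(comp)
    return metas, spectra, comps


def full_resolution_matrix(spectra: Sequence[Spectrum1D], y=None):
    """Stack spectra on their common grid into a FeatureMatrix with ppm labels."""
    from gonadnmr.chemometrics import FeatureMatrix
    from gonadnmr.spectra import common_grid

    grid = common_grid(spectra)
    X = np.vstack([sp.intensity for sp in spectra])
    return FeatureMatrix(
        X=X, var_labels=grid,
        y=None if y is None else np.asarray(y),
        sample_ids=np.array([sp.sample_id for sp in spectra]))
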