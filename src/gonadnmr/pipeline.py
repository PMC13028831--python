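"""Orchestration of the two analysis arms plus report generation.

The polar arm runs the sex-discrimination workflow: window/reference the
aqueous spectra, build both the full-resolution pointwise matrix and the
annotated peak-height matrix, exclude masked regions, fit PLS-LDA,
validate by k-fold CV (pareto scaling) and Monte Carlo CV (autoscaling),
rank peak-level variables by SPA/COSS, and test the selected peaks
univariately (two-sided Mann–Whitney).

The apolar arm integrates the diagnostic lipid regions, solves the
balance equations, QC-filters, and produces sex-stratified summaries with
a fish-oil benchmark block.

Reports are Markdown plus CSV tables (a diff-able surface); every output
records the seed and a hash of the configuration.  Pathway analysis is
not performed; instead the annotated metabolite names behind the selected
variables are exported as a compound list usable by external
over-representation tools.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from gonadnmr import __version__
from gonadnmr.spectra import (
    Spectrum1D, read_spectrum_text, write_spectrum_text, window_spectrum,
    reference_to_tsp, apply_mask, DEFAULT_POLAR_MASK, ExclusionMask,
)
from gonadnmr.annotation import load_bundled_table, peak_height_matrix, canonical_name
from gonadnmr.chemometrics import (
    ScalingSpec, scale_matrix, fit_pls_nipals, vip_scores, cross_validate, mccv,
)
from gonadnmr.spa import SPAConfig, run_spa, mann_whitney
from gonadnmr.lipids import (
    RegionWindows, Stoichiometry, DEFAULT_STOICHIOMETRY,
    integrate_regions, solve_indices, summarize_batch,
)
from gonadnmr.synth import (
    CohortConfig, SampleMeta, generate_cohort, generate_apolar_cohort,
    full_resolution_matrix,
)

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["id", "sex", "site", "diameter_mm", "height_mm",
                    "weight_g", "gonad_g", "gsi_pct"]


@dataclass
class RunConfig:
    """Everything a run needs; the seed is recorded in every output."""

    mode: str = "full"
    seed: int = 0
    input_dir: Optional[str] = None
    out_dir: Optional[str] = None
    cohort: CohortConfig = None
    scaling_cv: str = "pareto"
    scaling_mccv: str = "auto"
    a_max: int = 6
    cv_k: int = 5
    mccv_reps: int = 100
    mccv_fraction: float = 0.8
    spa: SPAConfig = None
    windows: RegionWindows = None
    polar_mask: ExclusionMask = DEFAULT_POLAR_MASK
    peak_tol_ppm: float = 0.005

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "polar", "apolar", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)
        if self.spa is None:
            self.spa = SPAConfig(seed=self.seed)
        if self.windows is None:
            self.windows = RegionWindows()

    def config_hash(self) -> str:
        blob = json.dumps(_serialisable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        cohort = raw.pop("cohort", None)
        spa = raw.pop("spa", None)
        windows = raw.pop("windows", None)
        cfg = cls(**raw)
        if cohort:
            cfg.cohort = CohortConfig(**{**cohort, "seed": cohort.get("seed", cfg.seed)})
        if spa:
            cfg.spa = SPAConfig(**{**spa, "seed": spa.get("seed", cfg.seed)})
        if windows:
            cfg.windows = RegionWindows(windows={**dict(cfg.windows.windows), **windows})
        return cfg


def _serialisable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _serialisable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _serialisable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialisable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# simulate mode: write a cohort to disk
# ---------------------------------------------------------------------------

def simulate(cfg: RunConfig) -> Path:
    """Generate both arms of a synthetic cohort and write them to out_dir."""
    out = Path(cfg.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    metas, polar = generate_cohort(cfg.cohort)
    _, apolar, _ = generate_apolar_cohort(
        dataclasses.replace(cfg.cohort, seed=cfg.cohort.seed + 1))
    rows = []
    for meta, sp_p, sp_a in zip(metas, polar, apolar):
        write_spectrum_text(sp_p, out / f"{meta.sample_id}_polar.txt")
        write_spectrum_text(sp_a, out / f"{meta.sample_id}_apolar.txt")
        rows.append({"id": meta.sample_id, "sex": meta.sex, "site": meta.site,
                     "diameter_mm": meta.diameter_mm, "height_mm": meta.height_mm,
                     "weight_g": meta.weight_g, "gonad_g": meta.gonad_g,
                     "gsi_pct": meta.gsi_pct})
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(out / "metadata.csv", index=False)
    logger.info("simulate: wrote %d samples to %s", len(rows), out)
    return out


def load_cohort(input_dir, fraction: str):
    """Load metadata.csv plus per-sample spectra; reconcile ids strictly.

    Raises with the lists of orphans when metadata rows and spectrum files
    do not match one-to-one.
    """
    input_dir = Path(input_dir)
    meta_path = input_dir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata table: {meta_path}")
    meta = pd.read_csv(meta_path)
    suffix = f"_{fraction}.txt"
    files = {p.name[:-len(suffix)]: p for p in input_dir.glob(f"*{suffix}")}
    ids = list(meta["id"].astype(str))
    missing = [i for i in ids if i not in files]
    orphans = [k for k in files if k not in ids]
    if missing or orphans:
        raise ValueError(
            f"metadata/spectra mismatch: no spectrum for {missing or 'none'}; "
            f"no metadata for {orphans or 'none'}")
    solvent = "aqueous_buffer" if fraction == "polar" else "cdcl3"
    spectra = [read_spectrum_text(files[i], solvent=solvent) for i in ids]
    return meta, spectra


def _sex_labels(meta: pd.DataFrame) -> np.ndarray:
    return np.where(meta["sex"].astype(str).str.upper().str.startswith("F"), 1, -1)


# ---------------------------------------------------------------------------
# polar arm
# ---------------------------------------------------------------------------

def run_polar_arm(cfg: RunConfig, meta: Optional[pd.DataFrame] = None,
                  spectra: Optional[Sequence[Spectrum1D]] = None) -> Dict:
    """Full-spectrum PLS-LDA validation plus SPA/COSS on peak heights."""
    if spectra is None:
        if cfg.input_dir:
            meta, spectra = load_cohort(cfg.input_dir, "polar")
        else:
            metas, spectra = generate_cohort(cfg.cohort)
            meta = pd.DataFrame([dataclasses.asdict(m) for m in metas]).rename(
                columns={"sample_id": "id"})
    y = _sex_labels(meta)
    spectra = [reference_to_tsp(window_spectrum(sp)) for sp in spectra]

    # full-resolution pointwise matrix, masked
    fm = full_resolution_matrix(spectra, y=y)
    fm = apply_mask(fm, cfg.polar_mask)

    spec_cv = ScalingSpec(scale=cfg.scaling_cv)
    Xs, _ = scale_matrix(fm.X, spec_cv)
    model = fit_pls_nipals(Xs, y, min(cfg.a_max, len(y) - 1))
    vip = vip_scores(model)
    cv = cross_validate(fm.X, y, spec_cv, A_max=cfg.a_max, k=cfg.cv_k)
    mc = mccv(fm.X, y, ScalingSpec(scale=cfg.scaling_mccv), A_max=cfg.a_max,
              split_fraction=cfg.mccv_fraction, n_reps=cfg.mccv_reps,
              seed=cfg.seed)

    # peak-level dataset from the curated table
    table = load_bundled_table("polar")
    pm = peak_height_matrix(spectra, table, tol_ppm=cfg.peak_tol_ppm, y=y)
    Xp, _ = scale_matrix(pm.X, ScalingSpec(scale="auto"))
    spa = run_spa(Xp, y, cfg.spa, var_labels=pm.var_labels)

    by_no = {p.peak_no: p for p in table.peaks}
    spa_rows = []
    for idx in spa.ranking():
        no = int(spa.var_labels[idx])
        spa_rows.append({
            "peak_no": no, "delta_ppm": by_no[no].delta_ppm,
            "metabolite": by_no[no].metabolite,
            "p_value": spa.p_value[idx], "coss": spa.coss[idx],
            "selected": bool(spa.selected[idx]),
            "n_inclusions": int(spa.n_inclusions[idx]),
        })
    spa_table = pd.DataFrame(spa_rows)

    # univariate Mann-Whitney on the selected peaks (raw heights)
    uni_rows = []
    heights = pd.DataFrame(pm.X, columns=pm.var_labels)
    for row in spa_rows:
        if not row["selected"]:
            continue
        vals = heights[row["peak_no"]].to_numpy()
        res = mann_whitney(vals[y == 1], vals[y == -1], sided="two-sided")
        uni_rows.append({"peak_no": row["peak_no"], "delta_ppm": row["delta_ppm"],
                         "metabolite": row["metabolite"],
                         "median_F": res.group_medians[0],
                         "median_M": res.group_medians[1],
                         "p_mwu": res.p_two_sided, "method": res.method})
    univariate = pd.DataFrame(
        uni_rows, columns=["peak_no", "delta_ppm", "metabolite", "median_F",
                           "median_M", "p_mwu", "method"])

    compounds = sorted({
        canonical_name(by_no[int(r["peak_no"])].metabolite) or ""
        for r in spa_rows if r["selected"]
    } - {""})

    section = {
        "n_samples": len(y),
        "n_female": int((y == 1).sum()), "n_male": int((y == -1).sum()),
        "n_vars_full": fm.n_vars, "n_vars_peaks": pm.n_vars,
        "r2x": model.r2x.tolist(), "r2y": model.r2y.tolist(),
        "r2x_cum": float(model.r2x[:2].sum()), "r2y_cum": float(model.r2y[:2].sum()),
        "vip_max_ppm": float(fm.var_labels[int(np.argmax(vip))]),
        "cv": cv, "mccv": mc,
        "spa_table": spa_table, "univariate": univariate,
        "n_selected": int(spa.selected.sum()),
        "pathway_export": compounds,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir); out.mkdir(parents=True, exist_ok=True)
        spa_table.to_csv(out / "spa_table.csv", index=False)
        univariate.to_csv(out / "univariate.csv", index=False)
        pd.DataFrame({"ppm": fm.var_labels, "vip": vip}).to_csv(
            out / "vip_full_resolution.csv", index=False)
        (out / "pathway_compound_list.txt").write_text("\n".join(compounds) + "\n")
    return section


# ---------------------------------------------------------------------------
# apolar arm
# ---------------------------------------------------------------------------

def run_apolar_arm(cfg: RunConfig, meta: Optional[pd.DataFrame] = None,
                   spectra: Optional[Sequence[Spectrum1D]] = None,
                   stoich: Stoichiometry = DEFAULT_STOICHIOMETRY) -> Dict:
    """Integrate -> solve -> QC filter -> sex-stratified summaries."""
    if spectra is None:
        if cfg.input_dir:
            meta, spectra = load_cohort(cfg.input_dir, "apolar")
        else:
            metas, spectra, _ = generate_apolar_cohort(
                dataclasses.replace(cfg.cohort, seed=cfg.cohort.seed + 1),
                windows=cfg.windows, stoich=stoich)
            meta = pd.DataFrame([dataclasses.asdict(m) for m in metas]).rename(
                columns={"sample_id": "id"})
    sexes = ["F" if s else "M" for s in
             meta["sex"].astype(str).str.upper().str.startswith("F")]
    results = []
    for sp in spectra:
        ri = integrate_regions(window_spectrum(sp), cfg.windows)
        results.append(solve_indices(ri, stoich))
    batch = summarize_batch(results, sexes)
    section = {"n_samples": len(results), **batch, "indices": results}
    if cfg.out_dir:
        out = Path(cfg.out_dir); out.mkdir(parents=True, exist_ok=True)
        batch["summary"].to_csv(out / "lipid_summary.csv")
        batch["qc_log"].to_csv(out / "lipid_qc_log.csv", index=False)
        per_sample = pd.DataFrame([{
            "id": r.spectrum_id, "sex": s, "n_unsat": r.n_unsat,
            "s_sat": r.s_sat, "omega3": r.omega3, "dha": r.dha,
            "excluded": r.excluded, "flags": ";".join(r.qc_flags)}
            for r, s in zip(results, sexes)])
        per_sample.to_csv(out / "lipid_indices.csv", index=False)
    return section


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def write_report(cfg: RunConfig, polar: Optional[Dict], apolar: Optional[Dict]) -> Path:
    out = Path(cfg.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    lines = [
        "# gonadnmr run report", "",
        f"- software version: {__version__}",
        f"- seed: {cfg.seed}",
        f"- config hash: {cfg.config_hash()}", "",
    ]
    if polar:
        cv, mc = polar["cv"], polar["mccv"]
        lines += [
            "## Polar arm (sex discrimination)", "",
            f"- samples: {polar['n_samples']} "
            f"({polar['n_male']} M / {polar['n_female']} F)",
            f"- full-resolution variables after masking: {polar['n_vars_full']}",
            f"- R2X per LV: {np.round(polar['r2x'], 4).tolist()} "
            f"(cum 2 LV: {polar['r2x_cum']:.4f})",
            f"- R2Y per LV: {np.round(polar['r2y'], 4).tolist()} "
            f"(cum 2 LV: {polar['r2y_cum']:.4f})",
            f"- CV ({cfg.scaling_cv}): optLV={cv.optLV}, error_min={cv.error_min:.4f}, "
            f"sens={cv.sensitivity}, spec={cv.specificity}, AUC={cv.auc}",
            f"- MCCV ({cfg.scaling_mccv}): optLV={mc.optLV}, error_min={mc.error_min:.4f}",
            f"- SPA: {polar['n_selected']} selected variable(s) "
            f"of {polar['n_vars_peaks']} peaks", "",
        ]
    if apolar:
        lines += [
            "## Apolar arm (lipid indices)", "",
            f"- spectra: {apolar['n_total']} total, {apolar['n_used']} after QC",
            "", apolar["summary"].to_markdown(), "",
            "### Fish-oil benchmark", "",
            "```json", json.dumps(apolar["benchmark"], indent=2), "```", "",
        ]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path


def run(cfg: RunConfig) -> Dict:
    """Execute the configured mode end to end."""
    if cfg.mode == "simulate":
        return {"out": simulate(cfg)}
    polar = run_polar_arm(cfg) if cfg.mode in ("polar", "full") else None
    apolar = run_apolar_arm(cfg) if cfg.mode in ("apolar", "full") else None
    report = write_report(cfg, polar, apolar)
    return {"polar": polar, "apolar": apolar, "report": report}
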