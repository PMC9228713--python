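"""End-to-end analysis: spectra + thicknesses → orientation report.

Chain: preprocess peak table → fit PCA on reference + sample spectra →
identify coverage/orientation components → per-sample mean orientation
scores → convert thicknesses to Γ → three-regime segmentation →
two-point f_Fc calibration → vertical-regime head-on/tail-on unmixing →
comparison of observed transition densities with packing-model critical
densities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pca as pca_mod
from .ellipsometry import CuypersParams, thickness_to_gamma
from .orientation import (
    MixtureEndmembers,
    RegimeSegmentation,
    SampleRecord,
    calibrate,
    invert_mixture,
    score_to_ffc,
    segment_regimes,
)
from .packing import PackingParams, critical_density
from .spectra_io import PeakTable, normalize_to_selected_sum, select_peaks

logger = logging.getLogger("igg_orient")

SCHEMA_VERSION = 1

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compare_packing"]


@dataclass
class RunConfig:
    """Knobs of one analysis run (everything else is data)."""

    peak_list: list[str] | None = None      # default: all peaks in the table
    n_components: int | None = None         # default: min(8, rank bound)
    f_flat: float = 0.28
    f_side: float = 0.34
    endmembers: MixtureEndmembers = field(default_factory=MixtureEndmembers)
    alpha: float = 0.05
    cuypers: CuypersParams = field(default_factory=CuypersParams)
    packing: PackingParams = field(default_factory=PackingParams)
    coverage_correction: bool = True
    min_protein_share: float = 0.05         # clip for the coverage correction
    seed: int = 0


@dataclass
class PipelineResult:
    model: pca_mod.PCAModel
    selection: pca_mod.PCSelection
    records: list[SampleRecord]
    segmentation: RegimeSegmentation
    report: pd.DataFrame
    summary: dict


def _per_sample_mean_scores(
    table: PeakTable, scores: np.ndarray, component: int, sign: int
) -> pd.Series:
    df = pd.DataFrame(
        {"sample_id": table.meta["sample_id"], "score": sign * scores[:, component]}
    )
    return df.groupby("sample_id", sort=False)["score"].mean()


def _coverage_corrected_scores(
    table: PeakTable,
    scores: np.ndarray,
    selection: pca_mod.PCSelection,
    mean_scores: pd.Series,
    min_share: float,
) -> tuple[pd.Series, pd.Series]:
    """Remove the substrate dilution from orientation scores.

    A spectrum of a partially covered surface is a linear blend
    ``x = w·protein + (1−w)·substrate`` of the pure-protein and bare
    spectra, so every linear score is diluted by the protein share ``w``:
    at low coverage the orientation score of a flat-on layer is dragged
    toward the bare-substrate level, confounding orientation with
    coverage.  ``w`` is estimated per sample from its coverage-PC score,
    placed between the bare reference and the saturated (reference)
    layers, and the orientation score is deprojected,

        s_protein = s_bare + (s − s_bare) / w.

    Shares below ``min_share`` are clipped: such samples are essentially
    bare and their corrected scores are noise-amplified.
    """
    groups = table.meta["group"].to_numpy()
    cov = scores[:, selection.coverage_pc]
    ori = selection.orientation_sign * scores[:, selection.orientation_pc]
    c_bare = float(cov[groups == "bare"].mean())
    c_sat = float(cov[np.isin(groups, ("fc_ref", "fab2_ref"))].mean())
    if c_sat == c_bare:
        raise ValueError("degenerate coverage axis: references coincide")
    s_bare = float(ori[groups == "bare"].mean())

    cov_by_sample = pd.DataFrame(
        {"sample_id": table.meta["sample_id"], "cov": cov}
    ).groupby("sample_id", sort=False)["cov"].mean()
    shares = ((cov_by_sample - c_bare) / (c_sat - c_bare)).clip(lower=min_share)
    corrected = s_bare + (mean_scores - s_bare) / shares
    return corrected, shares


def run_pipeline(
    table: PeakTable,
    thickness: pd.DataFrame,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full orientation analysis on a peak table + thickness table.

    ``table`` holds reference spectra (bare, fc_ref, fab2_ref) and IgG
    sample spectra; ``thickness`` maps IgG sample_ids to layer thickness
    d_nm.  Deterministic for fixed inputs.
    """
    config = config or RunConfig()

    # --- preprocessing -------------------------------------------------
    peak_list = config.peak_list or list(table.peaks)
    selected = select_peaks(table, peak_list)
    normalized = normalize_to_selected_sum(selected)

    # --- PCA model on reference + sample spectra -----------------------
    n, p = normalized.intensities.shape
    rank_bound = min(n - 1, p)
    k = config.n_components or min(8, rank_bound)
    model = pca_mod.fit_pca_on_table(normalized, k)
    selection = pca_mod.select_pcs(model)
    logger.info(
        "PCA: coverage PC%d, orientation PC%d (sign %+d)",
        selection.coverage_pc + 1,
        selection.orientation_pc + 1,
        selection.orientation_sign,
    )

    # --- per-sample orientation scores ---------------------------------
    # Coverage-corrected scores drive segmentation and calibration: raw
    # low-coverage scores are diluted toward the bare-substrate level,
    # which confounds orientation with coverage.  Raw scores are kept in
    # the report for plotting against the uncorrected literature style.
    scores = pca_mod.project(model, normalized)
    raw_scores = _per_sample_mean_scores(
        normalized, scores, selection.orientation_pc, selection.orientation_sign
    )
    if config.coverage_correction:
        work_scores, shares = _coverage_corrected_scores(
            normalized, scores, selection, raw_scores, config.min_protein_share
        )
    else:
        work_scores, shares = raw_scores, None

    # --- surface densities ---------------------------------------------
    thick = thickness.set_index("sample_id")["d_nm"]
    igg_mask = (normalized.meta["group"] == "igg").to_numpy()
    igg_ids = list(dict.fromkeys(normalized.meta.loc[igg_mask, "sample_id"]))
    missing = [s for s in igg_ids if s not in thick.index]
    if missing:
        raise ValueError(f"no thickness for sample(s): {missing}")

    records = []
    for sid in igg_ids:
        d = float(thick.loc[sid])
        records.append(
            SampleRecord(
                sample_id=sid,
                gamma=thickness_to_gamma(d, config.cuypers),
                d_nm=d,
                score=float(work_scores.loc[sid]),
            )
        )
    records.sort(key=lambda r: r.gamma)

    # --- segmentation, calibration, unmixing ---------------------------
    seg = segment_regimes(records, alpha=config.alpha)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "n_spectra": int(n),
        "n_samples": len(records),
        "pc_selection": {
            "coverage_pc": selection.coverage_pc,
            "orientation_pc": selection.orientation_pc,
            "orientation_sign": selection.orientation_sign,
            "variance_fractions": model.variance_fractions.tolist(),
        },
        "segmentation": {
            "significant": seg.significant,
            "boundaries": list(seg.boundaries) if seg.boundaries else None,
            "f_statistic": seg.f_statistic,
            "p_value": seg.p_value,
            "pairwise_p": seg.pairwise_p,
            "group_mean_scores": seg.group_means,
        },
    }

    if seg.significant:
        cal = calibrate(
            seg.group_means["flat_on"],
            seg.group_means["side_on"],
            f_flat=config.f_flat,
            f_side=config.f_side,
        )
        for rec in records:
            rec.f_fc = float(score_to_ffc(cal, rec.score))
        f_vertical = float(score_to_ffc(cal, seg.group_means["vertical"]))
        em = config.endmembers
        mixture: dict = {"f_fc_vertical": f_vertical, "h": em.h, "t": em.t}
        try:
            p_head = invert_mixture(f_vertical, em)
            mixture["head_fraction"] = p_head
            mixture["head_to_tail"] = (
                p_head / (1.0 - p_head) if p_head < 1.0 else float("inf")
            )
            for rec in records:
                if rec.regime == "vertical":
                    rec.head_fraction = p_head
        except ValueError as err:
            mixture["error"] = str(err)
        out_of_range = [r.sample_id for r in records if not 0 <= (r.f_fc or 0) <= 1]
        summary["calibration"] = {
            "s_flat": cal.s_flat,
            "s_side": cal.s_side,
            "slope": cal.slope,
            "intercept": cal.intercept,
            "f_fc_out_of_range_samples": out_of_range,
        }
        summary["mixture"] = mixture
        summary["packing_comparison"] = compare_packing(seg.boundaries, config.packing)
    else:
        logger.warning("no significant three-regime segmentation")

    report = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "gamma_mg_m2": r.gamma,
                "d_nm": r.d_nm,
                "score": r.score,
                "f_fc": r.f_fc,
                "regime": r.regime,
                "head_fraction": r.head_fraction,
            }
            for r in records
        ]
    )
    report["raw_score"] = report["sample_id"].map(raw_scores).astype(float)
    if shares is not None:
        report["protein_share"] = report["sample_id"].map(shares).astype(float)
    summary["coverage_correction"] = bool(config.coverage_correction)
    return PipelineResult(
        model=model,
        selection=selection,
        records=records,
        segmentation=seg,
        report=report,
        summary=summary,
    )


def compare_packing(
    boundaries: tuple[float, float],
    packing: PackingParams,
    phi_values: tuple[float, ...] = (0.55, 0.91),
) -> list[dict]:
    """Observed transition densities vs packing-model critical densities.

    For each orientation whose saturation ends a regime (flat-on ends at
    the first boundary, side-on at the second) and each candidate packing
    fraction, tabulate the predicted Γ_c = Γ_ind·Φ∞ and its deviation
    from the observed boundary; flag the closest Φ∞.
    """
    obs = {"flat_on": boundaries[0], "side_on": boundaries[1]}
    out = []
    for orientation, observed in obs.items():
        gamma_ind = packing.gamma_ind(orientation)
        rows = []
        for phi in phi_values:
            predicted = critical_density(gamma_ind, phi)
            rows.append(
                {
                    "orientation": orientation,
                    "phi_infinity": phi,
                    "gamma_ind": gamma_ind,
                    "gamma_critical_pred": predicted,
                    "gamma_observed": observed,
                    "abs_deviation": abs(predicted - observed),
                }
            )
        best = min(range(len(rows)), key=lambda i: rows[i]["abs_deviation"])
        for i, row in enumerate(rows):
            row["closest"] = i == best
        out.extend(rows)
    return out


def write_outputs(result: PipelineResult, outdir) -> dict[str, str]:
    """Write report CSV, JSON summary and the serialized PCA model."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": str(outdir / "sample_report.csv"),
        "summary": str(outdir / "summary.json"),
        "model": str(outdir / "pca_model.json"),
    }
    result.report.to_csv(paths["report"], index=False)
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary, fh, indent=2)
    pca_mod.save_model(result.model, paths["model"])
    return paths


def config_digest(config: RunConfig) -> str:
    """Stable short hash of a run config, for the run log."""
    import hashlib

    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    blob = json.dumps(enc(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
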