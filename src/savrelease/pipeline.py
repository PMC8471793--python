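"""End-to-end analysis pipeline: fits, correlations, predictions, validation.

One :func:`run_pipeline` call takes a dissolution study (tidy CSV),
fits the configured release model per SA/V level on replicate-mean profiles,
builds the MDT–SA/V and constant–SA/V power laws, predicts MDT and complete
profiles for requested SA/V ratios, scores predictions against held-out
profiles (RMSEP, f2), and writes all artifacts with a machine-readable
manifest (package version, config hash, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation import (
    ConstantCorrelations,
    PowerLaw,
    build_constant_correlations,
    fit_power_law,
    predict_profile,
    predict_scalar,
)
from .exceptions import DomainError, StageError
from .io import read_profiles, write_profiles
from .metrics import f2 as f2_score
from .metrics import mdt, rmsep, select_f2_points
from .models import ModelFit, fit_release, shared_exponent_fit
from .profiles import ReleaseProfile, mean_profile

__all__ = ["RunConfig", "PredictionReport", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str
    output_dir: str
    formulation: str | None = None  # default: the only formulation in the file
    family: str = "peppas_sahlin"  # model used for constant correlations
    fit_cap: float | None = None
    predict_sav: tuple[float, ...] = ()
    holdout_sav: tuple[float, ...] = ()  # SA/V levels excluded from calibration
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class PredictionReport:
    """Predicted MDT/profile at one SA/V with held-out validation scores."""

    sav: float
    predicted_mdt: float
    profile: ReleaseProfile
    rmsep_pct: float | None = None  # vs held-out replicate-mean profile
    f2: float | None = None


@dataclass(frozen=True)
class PipelineResult:
    mdt_law: PowerLaw
    correlations: ConstantCorrelations
    n_bar: float | None
    fits_by_sav: dict[float, ModelFit]
    mdt_by_sav: dict[float, float]
    reports: list[PredictionReport]
    manifest: dict


def _group_by_sav(profiles: list[ReleaseProfile]) -> dict[float, list[ReleaseProfile]]:
    groups: dict[float, list[ReleaseProfile]] = {}
    for p in profiles:
        if p.sav is None:
            raise DomainError(f"profile {p.label()} lacks a SA/V ratio")
        groups.setdefault(round(p.sav, 9), []).append(p)
    return groups


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; artifacts land in ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- load ---------------------------------------------------------------
    try:
        profiles = read_profiles(config.input_path)
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    if config.formulation is not None:
        profiles = [p for p in profiles if p.formulation == config.formulation]
    if not profiles:
        raise StageError("load", "no profiles match the requested formulation")

    groups = _group_by_sav(profiles)
    holdout = {s: g for s, g in groups.items() if any(abs(s - h) < 1e-9 for h in config.holdout_sav)}
    calibration = {s: g for s, g in groups.items() if s not in holdout}
    if len(calibration) < 2:
        raise StageError(
            "correlation",
            f"need >= 2 SA/V levels for correlation, got {len(calibration)}",
        )

    # --- per-level fits and MDTs -------------------------------------------
    means = {s: mean_profile(g) for s, g in sorted(calibration.items())}
    mdt_by_sav = {s: mdt(p) for s, p in means.items()}

    try:
        if config.family in ("peppas_sahlin", "korsmeyer_peppas"):
            n_bar, fit_list = shared_exponent_fit(
                list(means.values()), family=config.family, fit_cap=config.fit_cap
            )
            fits_by_sav = {
                s: f for s, f in zip(means, fit_list) if f is not None
            }
        else:
            n_bar = None
            fits_by_sav = {
                s: fit_release(p, config.family, fit_cap=config.fit_cap)
                for s, p in means.items()
            }
    except Exception as exc:
        raise StageError("fit", str(exc)) from exc

    # --- correlations -------------------------------------------------------
    try:
        mdt_law = fit_power_law(sorted(mdt_by_sav.items()))
        correlations = build_constant_correlations(fits_by_sav, n_bar=n_bar)
    except Exception as exc:
        raise StageError("correlation", str(exc)) from exc

    # --- predictions --------------------------------------------------------
    targets = sorted(set(config.predict_sav) | {s for s in holdout})
    reports: list[PredictionReport] = []
    for sav in targets:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # extrapolation flagged in manifest
            held = holdout.get(round(sav, 9))
            times = (
                mean_profile(held).times
                if held
                else means[min(means)].times  # longest calibration run
            )
            profile = predict_profile(correlations, sav, times)
            pred_mdt = predict_scalar(mdt_law, sav)
        err = score = None
        if held:
            observed = mean_profile(held)
            err = rmsep(profile.releases, observed.releases)
            score = f2_score(observed, profile)
        reports.append(
            PredictionReport(
                sav=sav, predicted_mdt=pred_mdt, profile=profile,
                rmsep_pct=err, f2=score,
            )
        )

    # --- artifacts ----------------------------------------------------------
    fits_frame = pd.DataFrame(
        [
            {
                "sav_mm_inv": s,
                "family": f.family,
                **{k: v for k, v in dataclasses.asdict(f.model).items()},
                "r_squared": f.r_squared,
                "fit_cap": f.fit_cap,
                "n_points": f.n_points_used,
                "mdt_min": mdt_by_sav[s],
            }
            for s, f in sorted(fits_by_sav.items())
        ]
    )
    fits_frame.to_csv(outdir / "fits.csv", index=False, float_format="%.10g")

    corr_payload = {
        "family": correlations.family,
        "n_bar": correlations.n_bar,
        "mdt_law": dataclasses.asdict(mdt_law),
        "constant_laws": {k: dataclasses.asdict(v) for k, v in correlations.laws.items()},
    }
    (outdir / "correlations.json").write_text(json.dumps(corr_payload, indent=2))

    pred_rows = []
    for r in reports:
        for t, c in zip(r.profile.times, r.profile.releases):
            pred_rows.append(
                {"sav_mm_inv": r.sav, "time_min": t, "released_pct": c}
            )
    pd.DataFrame(pred_rows).to_csv(
        outdir / "predictions.csv", index=False, float_format="%.10g"
    )

    manifest = {
        "package": "savrelease",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_profiles": len(profiles),
        "calibration_sav": sorted(calibration),
        "holdout_sav": sorted(holdout),
        "reports": [
            {
                "sav": r.sav,
                "predicted_mdt_min": r.predicted_mdt,
                "rmsep_pct": r.rmsep_pct,
                "f2": r.f2,
                "extrapolated": not (mdt_law.domain[0] <= r.sav <= mdt_law.domain[1]),
            }
            for r in reports
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        mdt_law=mdt_law,
        correlations=correlations,
        n_bar=n_bar,
        fits_by_sav=fits_by_sav,
        mdt_by_sav=mdt_by_sav,
        reports=reports,
        manifest=manifest,
    )
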