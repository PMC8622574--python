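"""End-to-end orchestration: simulate -> segment -> fit -> classify.

A single configuration drives an all-synthetic run that mirrors the
workflow of a mastication/digestion study: a participant panel is
generated, each participant's bolus plate is rendered and segmented,
particle-size distributions are fitted per colour class, digestion time
courses are generated (with kinetic parameters linked to chewing
duration, so that slower chewers digest more) and fitted, starch
fractions are computed, participants are classified into chewer groups,
and cross-metric correlations are reported.  Every intermediate table is
persisted as CSV and a summary report is written as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, imaging, kinetics, psd, synth
from .datasets import INTESTINAL_TIMEPOINTS_MIN

__all__ = ["DEFAULT_CONFIG", "PipelineStageError", "load_config", "run_pipeline"]

logger = logging.getLogger("beanbolus.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "panel": {
        "n_fast": 3,
        "n_slow": 2,
        "n_inconsistent": 1,
        "target_r": 0.88,
    },
    "plate": {
        "n_white": 14,
        "n_black": 10,
        "image_size_px": 900,
        "min_area_mm2": 2.0,
        "n_reflections": 2,
    },
    "imaging": {
        "min_equivalent_diameter_mm": 1.0,
    },
    "kinetics": {
        "noise_sd_mg": 4.0,
        "total_starch_mg": 400.0,
        "timepoints_min": list(INTESTINAL_TIMEPOINTS_MIN),
    },
}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage


def _deep_update(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge YAML config (optional) and overrides onto the defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        import yaml

        with open(path) as fh:
            cfg = _deep_update(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_update(cfg, overrides)
    return cfg


def _duration_linked_params(duration_s: float, rng: np.random.Generator) -> dict:
    """Per-participant latent parameters tied to chewing duration.

    Longer chewing gives smaller particles (lower x50, higher b), more
    released glucose/serine and only weakly-changed rate constants --
    the qualitative structure the cohort correlations probe.
    """
    x50_all = float(np.clip(7.8 - 0.055 * duration_s, 2.8, 9.0))
    b_all = float(np.clip(1.35 + 0.008 * duration_s, 1.3, 2.2))
    return {
        "x50_white": 0.65 * x50_all,
        "x50_black": 1.4 * x50_all,
        "b_white": b_all + 0.15,
        "b_black": b_all,
        "S0_mg": 45.0 + 1.6 * duration_s + rng.normal(0, 3),
        "Sf_mg": 130.0 + 3.0 * duration_s + rng.normal(0, 6),
        "ks_per_min": float(np.clip(0.02 + rng.normal(0, 0.004), 0.008, 0.035)),
        "P0_mg": 30.0 + 1.2 * duration_s + rng.normal(0, 3),
        "kp_mg_per_min": 0.2 + 0.012 * duration_s + rng.normal(0, 0.01),
    }


def run_pipeline(config: dict | None = None, out_dir="run") -> dict:
    """Execute the full synthetic pipeline and persist all outputs.

    Returns the summary report (also written to ``report.json``).  Any
    stage failure raises :class:`PipelineStageError` naming the stage;
    outputs produced up to that point remain on disk.
    """
    cfg = _deep_update(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ["panel", "plates", "kinetics"], ss.spawn(3)
        )
    }
    logger.info("run config: %s", json.dumps(cfg))
    logger.info("stage seeds: %s", stage_seeds)
    report: dict = {"seed": seed, "stages": {}}

    stage = "panel"
    try:
        panel = synth.generate_panel(
            synth.PanelSpec(seed=stage_seeds["panel"], **cfg["panel"])
        )
        panel.table.to_csv(out / "panel.csv", index=False)
        panel.design_medians.rename("median_s").to_csv(out / "design_medians.csv")
        report["stages"]["panel"] = {"n_participants": int(len(panel.table))}
        logger.info("panel: %d participants", len(panel.table))

        stage = "segment"
        rng = np.random.default_rng(stage_seeds["plates"])
        all_particles, fits_rows = [], []
        for i, row in panel.table.iterrows():
            params = _duration_linked_params(row["duration_s"], rng)
            spec = synth.PlateSpec(
                n_white=int(cfg["plate"]["n_white"]),
                n_black=int(cfg["plate"]["n_black"]),
                rr_white=(params["x50_white"], params["b_white"]),
                rr_black=(params["x50_black"], params["b_black"]),
                image_size_px=int(cfg["plate"]["image_size_px"]),
                min_area_mm2=float(cfg["plate"]["min_area_mm2"]),
                n_reflections=int(cfg["plate"]["n_reflections"]),
                seed=int(rng.integers(2**31)),
            )
            image, truth = synth.render_plate(spec)
            cal = imaging.calibrate(truth.marker_length_mm, truth.marker_length_px)
            particles = imaging.segment_image(
                image,
                cal,
                source_id=row["participant_id"],
                min_equivalent_diameter_mm=float(
                    cfg["imaging"]["min_equivalent_diameter_mm"]
                ),
            )
            particles.insert(0, "participant_id", row["participant_id"])
            all_particles.append(particles)
            logger.info(
                "segment %s: %d particles (truth %d)",
                row["participant_id"],
                len(particles),
                len(truth.particles),
            )
        particles_df = pd.concat(all_particles, ignore_index=True)
        particles_df.to_csv(out / "particles.csv", index=False)
        report["stages"]["segment"] = {"n_particles": int(len(particles_df))}

        stage = "psd"
        for pid, sub in particles_df.groupby("participant_id", sort=False):
            fits = psd.summarize_by_class(sub)
            fits.insert(0, "participant_id", pid)
            fits_rows.append(fits)
        fits_df = pd.concat(fits_rows, ignore_index=True)
        fits_df.to_csv(out / "psd_fits.csv", index=False)
        report["stages"]["psd"] = {
            "n_fits": int(fits_df["fitted"].sum()),
            "mean_x50_all_mm2": float(
                fits_df.loc[fits_df["class_scope"] == "all", "x50_mm2"].mean()
            ),
        }

        stage = "kinetics"
        krng = np.random.default_rng(stage_seeds["kinetics"])
        kin_rows, frac_rows, digesta_frames = [], [], []
        tpts = tuple(float(t) for t in cfg["kinetics"]["timepoints_min"])
        noise = float(cfg["kinetics"]["noise_sd_mg"])
        ts_mg = float(cfg["kinetics"]["total_starch_mg"])
        for _, row in panel.table.iterrows():
            params = _duration_linked_params(row["duration_s"], krng)
            scurve = synth.generate_curve(
                synth.CurveSpec(
                    model="fractional_conversion",
                    params=(params["S0_mg"], params["Sf_mg"], params["ks_per_min"]),
                    timepoints=tpts,
                    noise_sd=noise,
                    seed=int(krng.integers(2**31)),
                )
            )
            pcurve = synth.generate_curve(
                synth.CurveSpec(
                    model="zero_order",
                    params=(params["P0_mg"], params["kp_mg_per_min"]),
                    timepoints=tpts,
                    noise_sd=noise,
                    seed=int(krng.integers(2**31)),
                )
            )
            sfit = kinetics.fit_fractional_conversion(scurve)
            pfit = kinetics.fit_zero_order(pcurve)
            g20 = float(sfit.predict(20.0))
            g120 = float(sfit.predict(120.0))
            frac = kinetics.starch_fractions(g20, g120, ts_mg)
            kin_rows.append(
                dict(
                    participant_id=row["participant_id"],
                    S0_mg=sfit.S0,
                    Sf_mg=sfit.Sf,
                    ks_per_min=sfit.ks,
                    starch_adj_r2=sfit.adj_r2,
                    starch_converged=sfit.converged,
                    P0_mg=pfit.P0,
                    kp_mg_per_min=pfit.kp,
                    protein_adj_r2=pfit.adj_r2,
                )
            )
            frac_rows.append(
                dict(
                    participant_id=row["participant_id"],
                    G20_mg=frac.G20,
                    G120_mg=frac.G120,
                    total_starch_mg=frac.total_starch,
                    RDS=frac.RDS,
                    SDS=frac.SDS,
                    RS=frac.RS,
                )
            )
            dig = synth.digesta_frame([scurve, pcurve])
            dig.insert(0, "participant_id", row["participant_id"])
            digesta_frames.append(dig)
        kin_df = pd.DataFrame(kin_rows)
        frac_df = pd.DataFrame(frac_rows)
        kin_df.to_csv(out / "kinetics.csv", index=False)
        frac_df.to_csv(out / "fractions.csv", index=False)
        pd.concat(digesta_frames, ignore_index=True).to_csv(
            out / "digesta.csv", index=False
        )
        report["stages"]["kinetics"] = {
            "n_fits": int(len(kin_df)),
            "all_converged": bool(kin_df["starch_converged"].all()),
        }

        stage = "cohort"
        dur_cols = [c for c in panel.table.columns if c.startswith("duration_") and c != "duration_s"]
        durations = panel.table.set_index("participant_id")[dur_cols]
        labels, medians = cohort.classify_chewers(
            durations, medians=panel.design_medians
        )
        labels.to_csv(out / "labels.csv")
        metrics = (
            panel.table.set_index("participant_id")[["duration_s", "amylase_cu_per_ml"]]
            .join(
                fits_df[fits_df["class_scope"] == "all"]
                .set_index("participant_id")[["x50_mm2", "b"]]
            )
            .join(kin_df.set_index("participant_id")[["ks_per_min", "kp_mg_per_min"]])
            .join(frac_df.set_index("participant_id")[["RDS", "SDS", "RS"]])
        )
        corr = cohort.correlation_report(metrics)
        corr.to_csv(out / "correlations.csv")
        report["stages"]["cohort"] = {
            "counts": labels.value_counts().to_dict(),
            "r_duration_amylase": float(corr.loc["duration_s", "amylase_cu_per_ml"]),
            "r_duration_x50": float(corr.loc["duration_s", "x50_mm2"]),
        }
    except Exception as exc:  # noqa: BLE001 - stage name is the useful context
        logger.exception("stage %s failed", stage)
        logger.removeHandler(handler)
        handler.close()
        raise PipelineStageError(stage, exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("pipeline complete")
    logger.removeHandler(handler)
    handler.close()
    return report
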