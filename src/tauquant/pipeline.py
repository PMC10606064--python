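"""End-to-end study pipeline: generate (or load) every assay, fit, report.

The report mirrors the study's summary tables: per-compound binding
parameters (f_a, K_D), assembly-inhibition IC50s, viability IC50s per
compound x cell line, a migration group summary, and the microtubule
surface fraction, plus a provenance block (config hash, seed, package
version) so any numeric cell can be traced to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .binding import TitrationSeries, fit_modified_stern_volmer
from .config import RunConfig
from .errors import TauquantError, ValidationError
from .imaging import microtubule_surface_ratio
from .kinetics import (
    AggregationTimeCourse,
    estimate_ic50,
    fit_exp_plateau,
    inhibition_percent,
)
from .migration import population_summary
from .synthetic import (
    AggregationTruth,
    ImageTruth,
    MotilityTruth,
    QuenchTruth,
    simulate_cell_image,
    simulate_ths_timecourse,
    simulate_titration,
    simulate_tracks,
    simulate_viability,
)
from .viability import fit_median_effect
from . import io as tio

__all__ = ["StudyReport", "run_pipeline", "bracketing_concentrations",
           "analyze_ths_panel"]

log = logging.getLogger("tauquant")

#: concentration multipliers used to bracket a suspected half-maximal
#: point when designing an IC50 panel (all sub-saturating, straddling
#: 50% inhibition; see the methods note on the log-linear readout).
BRACKET_RATIOS = (0.80, 0.88, 0.96, 1.04, 1.12, 1.20)


def bracketing_concentrations(half_inhibition: float,
                              ratios: Sequence[float] = BRACKET_RATIOS) -> np.ndarray:
    """Dose panel tightly bracketing a suspected half-maximal value."""
    return half_inhibition * np.asarray(ratios, dtype=float)


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


@dataclass
class StudyReport:
    binding: pd.DataFrame
    assembly: pd.DataFrame
    viability: pd.DataFrame
    migration_groups: pd.DataFrame
    migration_comparisons: pd.DataFrame
    imaging: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.binding.to_csv(outdir / "binding.csv", index=False)
        self.assembly.to_csv(outdir / "assembly_ic50.csv", index=False)
        self.viability.to_csv(outdir / "viability_ic50.csv", index=False)
        self.migration_groups.to_csv(outdir / "migration_groups.csv")
        self.migration_comparisons.to_csv(outdir / "migration_comparisons.csv", index=False)
        self.imaging.to_csv(outdir / "imaging.csv", index=False)
        records = {
            "binding": self.binding.to_dict(orient="records"),
            "assembly": self.assembly.to_dict(orient="records"),
            "viability": self.viability.to_dict(orient="records"),
            "imaging": self.imaging.to_dict(orient="records"),
            "provenance": self.provenance,
        }
        (outdir / "report.json").write_text(json.dumps(records, indent=2, default=str))


def analyze_ths_panel(timecourses: Sequence[AggregationTimeCourse]):
    """Plateau-fit a ThS panel and estimate one IC50 per compound.

    Wells at zero compound concentration are the untreated controls;
    the baseline is the control fit's time-zero intercept.  Wells whose
    plateau fit fails to converge are skipped with a log record.
    """
    curves = []
    df = pd.DataFrame(
        {
            "compound": [tc.compound_id for tc in timecourses],
            "conc": [tc.compound_conc for tc in timecourses],
            "idx": range(len(timecourses)),
        }
    )
    for cid, grp in df.groupby("compound", sort=False):
        controls = grp[grp["conc"] == 0.0]
        if controls.empty:
            raise ValidationError(f"{cid}: no untreated control well in panel")
        control_fit = fit_exp_plateau(timecourses[int(controls["idx"].iloc[0])])
        if not control_fit.converged:
            raise ValidationError(f"{cid}: control plateau fit did not converge")
        baseline = control_fit.time_zero
        concs, inhibitions = [], []
        for _, row in grp[grp["conc"] > 0.0].iterrows():
            fit = fit_exp_plateau(timecourses[int(row["idx"])])
            if not fit.converged:
                log.debug("%s: skipping well %s (no convergence)", cid, row["idx"])
                continue
            concs.append(row["conc"])
            inhibitions.append(
                inhibition_percent(fit.plateau, control_fit.plateau, baseline)
            )
        curves.append(estimate_ic50(np.array(concs), np.array(inhibitions), str(cid)))
    return curves


def _binding_stage(cfg: RunConfig) -> pd.DataFrame:
    if cfg.synthetic:
        series = []
        for i, bt in enumerate(cfg.binding_truths):
            truth = QuenchTruth(
                f_a=bt.f_a,
                K=1.0 / bt.K_D_M,
                eps_ex_compound=1.5e4 if cfg.inner_filter else 0.0,
                eps_em_compound=2.0e3 if cfg.inner_filter else 0.0,
                noise_cv=cfg.noise_cv,
                seed=_stage_seed(cfg.seed, 10 + i),
            )
            series.append(simulate_titration(truth, compound_id=bt.compound))
    else:
        if cfg.titrations_csv is None:
            raise ValidationError("titrations_csv required when synthetic is false")
        series = tio.titrations_from_frame(tio.read_table(cfg.titrations_csv, "titration"))
    rows = []
    for s in series:
        fit = fit_modified_stern_volmer(s, r2_flag=cfg.r2_flag)
        rows.append(
            {
                "compound": fit.compound_id,
                "f_a": fit.f_a,
                "K_D_M": fit.K_D,
                "K_M^-1": fit.K,
                "intercept": fit.intercept,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "flags": ";".join(fit.flags),
            }
        )
    return pd.DataFrame(rows)


def _assembly_stage(cfg: RunConfig) -> pd.DataFrame:
    if cfg.synthetic:
        tcs = []
        for i, at in enumerate(cfg.assembly_truths):
            truth = AggregationTruth(
                half_inhibition_conc=at.half_inhibition_uM,
                noise_cv=cfg.noise_cv,
                seed=_stage_seed(cfg.seed, 20 + i),
            )
            concs = [0.0, *bracketing_concentrations(at.half_inhibition_uM)]
            for j, c in enumerate(concs):
                tcs.append(
                    simulate_ths_timecourse(
                        truth, c, well_id=f"{at.compound}-w{j}", compound_id=at.compound
                    )
                )
    else:
        if cfg.timecourses_csv is None:
            raise ValidationError("timecourses_csv required when synthetic is false")
        tcs = tio.timecourses_from_frame(tio.read_table(cfg.timecourses_csv, "timecourse"))
    curves = analyze_ths_panel(tcs)
    return pd.DataFrame(
        [
            {
                "compound": c.compound_id,
                "ic50_uM": c.ic50 if cfg.ic50_rule == "interpolated" else c.ic50_literal,
                "slope_pct_per_decade": c.slope,
                "r_squared": c.r_squared,
                "n_points": c.n_points,
                "n_saturated": c.n_saturated,
                "flags": ";".join(c.flags),
            }
            for c in curves
        ]
    )


def _viability_stage(cfg: RunConfig) -> pd.DataFrame:
    if cfg.synthetic:
        doses = 0.2 * 2.0 ** np.arange(7)  # 0.2-12.8 µM, 2-fold series
        drs = [
            simulate_viability(
                vt.m,
                vt.Dm_uM,
                doses * (vt.Dm_uM / 1.6),  # keep the series straddling Dm
                noise_cv=cfg.noise_cv,
                seed=_stage_seed(cfg.seed, 30 + i),
                compound_id=vt.compound,
                cell_line=vt.cell_line,
            )
            for i, vt in enumerate(cfg.viability_truths)
        ]
    else:
        if cfg.plates_csv is None:
            raise ValidationError("plates_csv required when synthetic is false")
        drs = tio.dose_responses_from_frame(tio.read_table(cfg.plates_csv, "plate"))
    rows = []
    for dr in drs:
        fit = fit_median_effect(dr)
        rows.append(
            {
                "compound": fit.compound_id,
                "cell_line": fit.cell_line,
                "ic50_uM": fit.Dm,
                "ic50_se_uM": fit.Dm_se,
                "m": fit.m,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "n_excluded": fit.n_excluded,
                "flags": ";".join(fit.flags),
            }
        )
    return pd.DataFrame(rows)


def _migration_stage(cfg: RunConfig):
    mcfg = cfg.migration
    if cfg.synthetic:
        groups = {}
        for k, (name, speed) in enumerate(
            [
                (mcfg.reference_group, mcfg.reference_speed_um_min),
                (mcfg.treated_group, mcfg.reference_speed_um_min * mcfg.speed_ratio),
            ]
        ):
            truth = MotilityTruth(
                mean_speed=speed,
                persistence_time=mcfg.persistence_time_min,
                n_frames=mcfg.n_frames,
                total_time=mcfg.total_time_min,
                step_cv=mcfg.step_cv,
                seed=_stage_seed(cfg.seed, 40 + k),
            )
            groups[name] = simulate_tracks(truth, mcfg.n_cells)
    else:
        if cfg.tracks_csv is None:
            raise ValidationError("tracks_csv required when synthetic is false")
        groups = tio.grouped_tracks_from_frame(
            tio.read_table(cfg.tracks_csv, "tracks"), cfg.tracks_group_col
        )
    summary = population_summary(groups, reference=mcfg.reference_group,
                                 total_time=mcfg.total_time_min)
    return summary.per_group, summary.comparisons


def _imaging_stage(cfg: RunConfig) -> pd.DataFrame:
    ic = cfg.imaging
    contrast = 160.0
    truth = ImageTruth(
        width=ic.width,
        height=ic.height,
        cell_mask_fraction=ic.cell_mask_fraction,
        mt_coverage_of_cell=ic.coverage,
        fg_intensity=40.0 + contrast,
        bg_intensity=40.0,
        noise_sd=ic.noise_sd_rel_contrast * contrast,
        seed=_stage_seed(cfg.seed, 50),
    )
    sci = simulate_cell_image(truth)
    ratio = microtubule_surface_ratio(sci.image)
    return pd.DataFrame(
        [
            {
                "image": "synthetic_cell",
                "cell_area_px": ratio.cell_area,
                "mt_area_px": ratio.mt_area,
                "mt_surface_pct": ratio.ratio_pct,
                "truth_coverage_pct": 100.0 * ic.coverage,
            }
        ]
    )


def run_pipeline(cfg: RunConfig) -> StudyReport:
    """Execute all stages in dependency order and write the report.

    Idempotent for a given (config, seed): rerunning produces
    numerically identical outputs.
    """
    if not cfg.synthetic:
        missing = [
            name
            for name, p in [
                ("titrations_csv", cfg.titrations_csv),
                ("timecourses_csv", cfg.timecourses_csv),
                ("plates_csv", cfg.plates_csv),
                ("tracks_csv", cfg.tracks_csv),
            ]
            if p is None or not Path(p).exists()
        ]
        if missing:
            raise ValidationError(f"missing input files: {', '.join(missing)}")
    stages = [
        ("binding", _binding_stage),
        ("assembly", _assembly_stage),
        ("viability", _viability_stage),
    ]
    results: dict[str, pd.DataFrame] = {}
    for name, fn in stages:
        log.info("stage %s: start", name)
        try:
            results[name] = fn(cfg)
        except TauquantError as exc:
            raise type(exc)(f"stage {name}: {exc}") from exc
        log.info("stage %s: done", name)
    log.info("stage migration: start")
    mig_groups, mig_comp = _migration_stage(cfg)
    log.info("stage migration: done")
    log.info("stage imaging: start")
    imaging = _imaging_stage(cfg)
    log.info("stage imaging: done")

    # hash of everything that influences the numbers (not where they land)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg.model_dump(exclude={"output_dir"}), default=str,
                   sort_keys=True).encode("utf-8")
    ).hexdigest()
    report = StudyReport(
        binding=results["binding"],
        assembly=results["assembly"],
        viability=results["viability"],
        migration_groups=mig_groups,
        migration_comparisons=mig_comp,
        imaging=imaging,
        provenance={
            "config_sha256": cfg_hash,
            "seed": cfg.seed,
            "version": __version__,
        },
    )
    report.write(cfg.output_dir)
    return report
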