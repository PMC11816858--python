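"""End-to-end orchestration: dose table and the full synthetic experiment.

``run_dose_table`` reproduces the planning table of the experiment — one
row per (cell line, reactor power) with boron concentration, thermal flux,
total and boron-free dose and both uncertainty terms — from a dose-rate
constant table and an irradiation-plan table (bundled fixtures by default).

``run_full`` runs the whole synthetic pipeline under one seed: generated
uptake, ICP-MS quantification, comet populations with group comparisons,
spheroid growth morphometry and Ki67 gating, written as a reproducible
CSV/JSON/Markdown bundle.  No timestamps are written anywhere, so a bundle
is byte-identical across re-runs with the same seed and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import anchors, comet_stats, dosimetry, flow_ki67, icpms, morphometry, synthetic
from .comet_stats import ExperimentalGroup
from .errors import StageError

__all__ = ["RunConfig", "run_dose_table", "run_full"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"

#: Surfaced in every report: the printed 2D rows of the planning table are
#: not reproduced by the mean 2D dose-rate constants (ratio ~0.7); only the
#: spheroid rows are asserted by the bundled verification fixtures.
TWO_D_DISCREPANCY_NOTE = (
    "Note: doses recomputed from the mean 2D dose-rate constants exceed the "
    "published 2D planning-table values by a systematic factor of ~1.4; the "
    "origin (per-flask rates or a table inconsistency) is unresolved. "
    "Spheroid rows reproduce within ~1%."
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic run."""

    seed: int = 0
    out_dir: str = "bnct_run"
    rates_path: str | None = None  # None -> bundled constants
    plans_path: str | None = None  # None -> bundled plans
    t_irr: float = 600.0
    P_max: float = 250.0
    comet_n_cells: int = 150
    comet_replicates: int = 3
    n_spheroids: int = 3
    flow_events: int = 4000
    flow_replicates: int = 3
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_plans(path: str | None) -> pd.DataFrame:
    if path is None:
        ref = resources.files("bnctkit.data") / "irradiation_plans.csv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def run_dose_table(
    rates_path: str | None = None,
    plans_path: str | None = None,
    t_irr: float = 600.0,
    P_max: float = 250.0,
) -> pd.DataFrame:
    """Planning-table report: one row per (cell line, reactor power)."""
    rates = dosimetry.load_dose_rate_table(rates_path)
    plans = _load_plans(plans_path)
    rows = []
    for _, row in plans.iterrows():
        ct = dosimetry.CultureType(row["culture_type"])
        if ct not in rates:
            logger.error("no dose-rate constants for %s; row skipped", ct)
            continue
        if pd.isna(row["C_B_ppm"]):
            logger.error("missing C_B for %s; row skipped", row["cell_line"])
            continue
        boron = dosimetry.BoronMeasurement(
            C_B=float(row["C_B_ppm"]), sigma_C_B=float(row["sigma_C_B_ppm"])
        )
        plan = dosimetry.IrradiationPlan(P=float(row["P_kW"]), P_max=P_max, t_irr=t_irr)
        res = dosimetry.total_dose(
            rates[ct], boron, plan, sigma_sys=float(row.get("sigma_sys_Dtot_Gy", 0.0))
        )
        rows.append(
            {
                "cell_line": row["cell_line"],
                "culture_type": ct.value,
                "power_kW": plan.P,
                "flux_cm2s": dosimetry.flux_at_power(plan),
                "C_B_ppm": boron.C_B,
                "sigma_C_B_ppm": boron.sigma_C_B,
                "D_tot_Gy": res.D_tot,
                "sigma_stat_Gy": res.sigma_stat,
                "sigma_sys_Gy": res.sigma_sys,
                "D_0_Gy": res.D_0,
                "dose_group": dosimetry.classify_dose_group(res.D_tot).value,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ stage runs

def _stage_uptake(cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for i, profile in enumerate(sorted(anchors.UPTAKE_4H)):
        tc = synthetic.gen_uptake_timecourse(profile, seed=cfg.seed + 101 + i)
        summ = icpms.uptake_summary(tc)
        for t, m, s in zip(summ.times_h, summ.means, summ.sds):
            rows.append(
                {"profile": profile, "time_h": t, "mean_ug_per_1e6": m,
                 "sd": s, "peak_time_h": summ.peak_time_h}
            )
    return pd.DataFrame(rows)


def _stage_icpms(cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for i, (profile, (ppm, _)) in enumerate(sorted(anchors.C_B_PPM.items())):
        syn = synthetic.gen_icpms_run(ppm, seed=cfg.seed + 211 + i)
        curve = icpms.fit_calibration(syn.run.standard_points)
        quant = icpms.quantify_b10(syn.run, curve)
        ug = quant.b10_ug_per_l * syn.digest_volume_l
        rows.append(
            {
                "profile": profile,
                "true_ppm": ppm,
                "measured_ppm": icpms.concentration_ppm(ug, syn.pellet),
                "ug_per_1e6_cells": icpms.concentration_per_million_cells(ug, syn.pellet),
                "below_detection": quant.below_detection,
                "r_squared": curve.r_squared,
            }
        )
    return pd.DataFrame(rows)


def _stage_comet(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    samples = []
    seed = cfg.seed + 307
    for i, ((profile, dose_group), (mean, se)) in enumerate(sorted(anchors.COMET_1H.items())):
        # IR_B at the published mean; IR and C at lower damage levels with
        # the same spread, giving the published IR_B > IR significance
        # structure by construction.
        for j, (group, m) in enumerate(
            [(ExperimentalGroup.IR_B, mean),
             (ExperimentalGroup.IR, 10.0),
             (ExperimentalGroup.C, 8.0)]
        ):
            samples.extend(
                synthetic.gen_comet_population(
                    m, se, n_cells=cfg.comet_n_cells,
                    replicates=cfg.comet_replicates,
                    seed=seed + 10 * i + j, group=group,
                    cell_line=profile, dose_group=dose_group,
                )
            )
    summaries = pd.DataFrame(
        [
            {
                "cell_line": s.cell_line,
                "dose_group": s.dose_group,
                "group": s.group.value,
                "time_h": s.time_h,
                "mean_tail_dna_pct": comet_stats.summarize(s.values).mean,
                "delta": comet_stats.summarize(s.values).delta,
                "n_cells": s.n,
            }
            for s in samples
        ]
    )
    tests = comet_stats.compare_conditions(samples)
    return summaries, tests


def _stage_growth(cfg: RunConfig) -> pd.DataFrame:
    conditions = [
        ("C", 0.0, False), ("C_B", 0.0, True),
        ("IR_2Gy", 2.0, False), ("IR_B_2Gy", 2.0, True),
        ("IR_6Gy", 6.0, False), ("IR_B_6Gy", 6.0, True),
    ]
    frames = []
    for i, (name, dose, boron) in enumerate(conditions):
        series = synthetic.gen_spheroid_experiment(
            dose, boron, seed=cfg.seed + 401 + i, n_spheroids=cfg.n_spheroids
        )
        records = []
        for s in series:
            for t, mask in zip(s.times_h, s.masks):
                sm = morphometry.shape_metrics(
                    morphometry.SpheroidMask(mask, pixel_size=s.pixel_size,
                                             spheroid_id=s.spheroid_id,
                                             time_h=t, group=name)
                )
                records.append({"spheroid_id": s.spheroid_id, "time_h": t,
                                "feret": sm.feret,
                                "circularity": sm.circularity})
        growth = morphometry.normalized_growth(pd.DataFrame(records))
        growth.insert(0, "group", name)
        growth["mean_circularity"] = float(
            np.mean([r["circularity"] for r in records])
        )
        frames.append(growth)
    return pd.concat(frames, ignore_index=True)


def _stage_ki67(cfg: RunConfig) -> pd.DataFrame:
    # Positive-fraction design: the boron-loaded high-dose arm loses
    # proliferative cells at 24/48 h but not yet at 1 h, mirroring the
    # published effect structure.
    design = {
        ("C", "none"): {1: 0.60, 24: 0.60, 48: 0.60},
        ("IR", "lower"): {1: 0.55, 24: 0.55, 48: 0.55},
        ("IR_B", "lower"): {1: 0.55, 24: 0.45, 48: 0.40},
        ("IR_B", "higher"): {1: 0.52, 24: 0.30, 48: 0.25},
    }
    control = synthetic.gen_flow_events(
        0.0, n_events=max(cfg.flow_events, flow_ki67.MIN_EVENTS),
        seed=cfg.seed + 503, group="unstained",
    )
    gate = flow_ki67.derive_gate(control)
    samples = []
    i = 0
    for (group, dg), per_time in design.items():
        for t, frac in per_time.items():
            for rep in range(cfg.flow_replicates):
                samples.append(
                    synthetic.gen_flow_events(
                        frac, n_events=cfg.flow_events,
                        seed=cfg.seed + 601 + 7 * i + rep,
                        group=group, dose_group=dg, time_h=float(t),
                        sample_id=f"{group}_{dg}_{t}h_r{rep}",
                    )
                )
            i += 1
    return flow_ki67.ki67_summary(samples, gate)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_full(config: RunConfig) -> Path:
    """Run every synthetic stage and write the report bundle.

    Returns the output directory.  A stage failure raises
    :class:`StageError` after writing whatever completed (partial bundle).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash(),
             "config": asdict(config)}
    (out / "run.json").write_text(json.dumps(stamp, indent=2, sort_keys=True) + "\n")

    stages = [
        ("dose_table", lambda: run_dose_table(
            config.rates_path, config.plans_path, config.t_irr, config.P_max)),
        ("uptake", lambda: _stage_uptake(config)),
        ("icpms", lambda: _stage_icpms(config)),
        ("comet", lambda: _stage_comet(config)),
        ("growth", lambda: _stage_growth(config)),
        ("ki67", lambda: _stage_ki67(config)),
    ]
    done = []
    for name, fn in stages:
        try:
            result = fn()
        except Exception as exc:  # pragma: no cover - exercised via CLI test
            _write_report(out, config, done, failed=name)
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        if name == "comet":
            _write(result[0], out / "comet_summary.csv")
            _write(result[1], out / "comet_tests.csv")
        elif name == "dose_table":
            _write(result, out / "dose_table.csv")
            result.to_json(out / "dose_table.json", orient="records", indent=2)
        else:
            _write(result, out / f"{name}.csv")
        done.append(name)
    _write_report(out, config, done)
    return out


def _write_report(out: Path, config: RunConfig, done: list[str],
                  failed: str | None = None) -> None:
    lines = [
        "# BNCT synthetic pipeline report",
        "",
        f"- seed: {config.seed}",
        f"- config hash: {config.config_hash()}",
        f"- completed stages: {', '.join(done) if done else 'none'}",
    ]
    if failed:
        lines.append(f"- FAILED stage: {failed}")
    lines += ["", TWO_D_DISCREPANCY_NOTE, ""]
    (out / "report.md").write_text("\n".join(lines))
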