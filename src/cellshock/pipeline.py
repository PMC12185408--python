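"""End-to-end orchestration: simulate -> (measure) -> group -> fit -> report.

Each stage reads/writes plain files under the run directory so any
stage can be re-run from its persisted inputs; all stochastic stages
derive their seed deterministically from the one global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import eos, imaging, inference, synthdata

__all__ = ["RunConfig", "validate_config", "run_pipeline", "measure_records",
           "stage_seed"]

log = logging.getLogger("cellshock.pipeline")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted configuration of one pipeline run."""

    dataset: synthdata.DatasetConfig = synthdata.DatasetConfig()
    outdir: str = "results/run"
    seed: int = 0
    do_measure: bool = False
    fit_family: str = "tait"
    fit_starts: int = 16
    cv_max: float = 0.05
    min_size: int = 4
    log_level: str = "INFO"


def _err(errors, path, message):
    errors.append({"path": path, "message": message})


def validate_config(config: dict | None):
    """Normalise a raw config dict into a RunConfig, or report errors.

    Returns (RunConfig | None, errors).  An empty/None config yields the
    full defaults; on any error the config is rejected outright (no
    partially-defaulted result).
    """
    cfg = dict(config or {})
    errors: list[dict] = []

    seed = int(cfg.get("seed", 0))
    model_cfg = dict(cfg.get("model", {}))
    family = model_cfg.pop("family", "tait")
    try:
        model = eos.StateEquationParams(family=family, **model_cfg)
    except (TypeError, ValueError) as e:
        _err(errors, "model", str(e))
        model = None

    try:
        population = synthdata.PopulationSpec(**cfg.get("population", {}))
    except (TypeError, ValueError) as e:
        _err(errors, "population", str(e))
        population = None
    try:
        noise = synthdata.NoiseSpec(**cfg.get("noise", {}))
    except (TypeError, ValueError) as e:
        _err(errors, "noise", str(e))
        noise = None
    coupling_cfg = cfg.get("coupling", {})
    coupling = None
    if coupling_cfg is not None:
        try:
            coupling = synthdata.SizeCouplingSpec(**coupling_cfg)
        except (TypeError, ValueError) as e:
            _err(errors, "coupling", str(e))

    groups = cfg.get("groups")
    if groups is None:
        centers = synthdata.STUDY_GROUP_CENTERS_KPA
        sds = synthdata.STUDY_GROUP_SDS_KPA
        sizes = synthdata.STUDY_GROUP_SIZES
    else:
        labels = [g.get("label") for g in groups]
        if len(set(labels)) != len(labels):
            _err(errors, "groups", "duplicate group labels")
        centers = tuple(float(g["center"]) for g in groups)
        sds = tuple(float(g.get("sd", 0.0)) for g in groups)
        sizes = tuple(int(g["n"]) for g in groups)
    if model is not None:
        for i, c in enumerate(centers):
            if c <= model.p0:
                _err(errors, f"groups[{i}].center",
                     f"peak pressure {c} kPa is not above the baseline model.p0={model.p0} kPa")

    span = tuple(cfg.get("pressure_span", synthdata.PRESSURE_SPAN_KPA))

    dataset = None
    if not errors:
        try:
            dataset = synthdata.DatasetConfig(
                population=population,
                model=model,
                noise=noise,
                coupling=coupling,
                group_centers=centers,
                group_sds=sds,
                group_sizes=sizes,
                cv_compliant=bool(cfg.get("cv_compliant", True)),
                pressure_span=span,
                detach_prob=float(cfg.get("detach_prob", 0.05)),
                seed=stage_seed(seed, "simulate"),
            )
        except (TypeError, ValueError) as e:
            _err(errors, "dataset", str(e))

    if errors:
        return None, errors

    fit_cfg = cfg.get("fit", {})
    grouping_cfg = cfg.get("grouping", {})
    run = RunConfig(
        dataset=dataset,
        outdir=str(cfg.get("outdir", "results/run")),
        seed=seed,
        do_measure=bool(cfg.get("stages", {}).get("measure", False)),
        fit_family=str(fit_cfg.get("family", family)),
        fit_starts=int(fit_cfg.get("n_starts", 16)),
        cv_max=float(grouping_cfg.get("cv_max", 0.05)),
        min_size=int(grouping_cfg.get("min_size", 4)),
        log_level=str(cfg.get("log_level", "INFO")),
    )
    return run, []


# ---------------------------------------------------------------------------

def measure_records(records: pd.DataFrame, dataset: synthdata.DatasetConfig,
                    seed: int, image_spec: synthdata.ImageSpec | None = None
                    ) -> pd.DataFrame:
    """Re-derive records through the imaging path.

    Each record is re-rendered as a frame stack (its waveform rebuilt
    from the recorded peak pressure), segmented, measured, and replaced
    by the image-derived areas/ζ.  Records whose final outline does not
    fit the canvas are dropped (counted in the log).
    """
    spec = image_spec or synthdata.ImageSpec()
    out_rows = []
    dropped = 0
    for _, row in records.iterrows():
        rng = np.random.default_rng((seed + 7919 * int(row["cell_id"])) % (2**31))
        cell = synthdata.CellSeed(int(row["cell_id"]), float(row["A_initial_um2"]),
                                  float(row["perimeter_um"]), float(row["angle_deg"]))
        wf = synthdata.generate_waveform(float(row["p0_kPa"]), float(row["pmax_kPa"]),
                                         dataset.ramp_duration_ms, dataset.fps,
                                         baseline_frames=dataset.baseline_frames)
        rec = synthdata.DeformationRecord(
            cell_id=cell.cell_id, A_initial=cell.area,
            A_final=float(row["A_final_um2"]), zeta=float(row["zeta"]),
            p_max=float(row["pmax_kPa"]), p0=float(row["p0_kPa"]),
            detached=bool(row["detached"]),
        )
        try:
            frames, _, _ = synthdata.render_frames(cell, rec, wf, spec, rng)
        except ValueError:
            dropped += 1
            continue
        sel = imaging.select_frames(frames, wf, pixel_size=spec.pixel_size)
        seg0 = imaging.segment_cell(frames[sel.initial_index], spec.pixel_size)
        seg1 = imaging.segment_cell(frames[sel.final_index], spec.pixel_size)
        if seg0 is None or seg1 is None:
            dropped += 1
            continue
        s0 = imaging.measure_shape(seg0.contour)
        s1 = imaging.measure_shape(seg1.contour)
        out_rows.append({
            "cell_id": cell.cell_id,
            "group_label": row["group_label"],
            "p0_kPa": row["p0_kPa"],
            "pmax_kPa": sel.p_at_final,
            "A_initial_um2": s0.area,
            "A_final_um2": s1.area,
            "zeta": imaging.compute_zeta(s0, s1),
            "perimeter_um": s0.perimeter,
            "angle_deg": s0.angle,
            "detached": bool(row["detached"]) or sel.detached,
        })
    if dropped:
        log.warning("measure stage dropped %d record(s) (render/segment failure)", dropped)
    return pd.DataFrame(out_rows, columns=synthdata.RECORD_COLUMNS)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig | dict | None = None) -> dict:
    """Execute the enabled stages in order and write all artefacts.

    Returns a run report dict (also persisted as manifest.json).
    Stage failures abort with a stage-tagged error; artefacts written
    before the failure are preserved.
    """
    if not isinstance(config, RunConfig):
        config, errors = validate_config(config)
        if errors:
            raise ValueError(f"invalid config: {errors}")
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "outdir": str(outdir), "stages": {}}
    written: list[Path] = []

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as e:
                report["stages"][name] = {"status": "failed", "error": str(e)}
                _write_manifest()
                raise RuntimeError(f"stage '{name}' failed: {e}") from e
            report["stages"][name] = {"status": "ok", **(result or {})}
            log.info("stage %-8s ok: %s", name, result or {})
            return result
        return deco

    def _write_manifest():
        report["files"] = {str(p.relative_to(outdir)): _sha256(p) for p in written}
        report["versions"] = {"numpy": np.__version__, "pandas": pd.__version__}
        (outdir / "manifest.json").write_text(json.dumps(report, indent=2, default=str))

    # --- simulate -----------------------------------------------------
    records = truth = None

    @stage("simulate")
    def _simulate():
        nonlocal records, truth
        records, truth = synthdata.generate_dataset(config.dataset)
        p = outdir / "records.csv"
        records.to_csv(p, index=False)
        written.append(p)
        p2 = outdir / "ground_truth.json"
        p2.write_text(json.dumps(truth, indent=2))
        written.append(p2)
        return {"n_records": len(records)}

    # --- measure (optional) -------------------------------------------
    if config.do_measure:
        @stage("measure")
        def _measure():
            nonlocal records
            records = measure_records(records, config.dataset,
                                      stage_seed(config.seed, "measure"))
            p = outdir / "measured_records.csv"
            records.to_csv(p, index=False)
            written.append(p)
            return {"n_records": len(records)}

    # --- distributions + grouping -------------------------------------
    groups = lines = grouped_records = None

    @stage("group")
    def _group():
        nonlocal groups, lines, grouped_records
        dist = inference.test_distributions(records)
        (outdir / "distributions.json").write_text(
            json.dumps([dataclasses.asdict(d) for d in dist], indent=2))
        written.append(outdir / "distributions.json")
        # detached records carry a censored peak pressure (re-read at the
        # pre-detachment frame), so they are left out of the pressure groups
        adhered = records[~records["detached"].astype(bool)].reset_index(drop=True)
        grouped_records = adhered
        groups, ungrouped = inference.group_by_pressure(
            adhered, cv_max=config.cv_max, min_size=config.min_size)
        gdf = pd.DataFrame([{"label": g.label, "mean_pmax_kPa": g.mean_pmax,
                             "sd_pmax_kPa": g.sd_pmax, "n": g.n} for g in groups])
        p = outdir / "groups.csv"
        gdf.to_csv(p, index=False)
        written.append(p)
        lines = inference.fit_group_lines(adhered, groups)
        p2 = outdir / "group_lines.csv"
        lines.to_csv(p2, index=False)
        written.append(p2)
        return {"n_groups": len(groups), "n_ungrouped": len(ungrouped)}

    # --- fit ----------------------------------------------------------
    fit = None

    @stage("fit")
    def _fit():
        nonlocal fit
        fit = inference.fit_state_equation(
            records, config.fit_family, base=config.dataset.model,
            coupling=config.dataset.coupling,
            seed=stage_seed(config.seed, "fit"), n_starts=config.fit_starts)
        p = outdir / "fits.json"
        p.write_text(json.dumps(dataclasses.asdict(fit), indent=2))
        written.append(p)
        return {"converged": fit.converged, "params": fit.params}

    # --- report -------------------------------------------------------
    @stage("report")
    def _report():
        n_shrink, frac = inference.count_shrinking(records)
        _figure_zeta_vs_area(grouped_records, groups, lines, outdir / "zeta_vs_area.png")
        _figure_state_equation(config, fit, outdir / "state_equation.png")
        _figure_trajectory(config, outdir / "trajectory.png")
        written.extend([outdir / "zeta_vs_area.png", outdir / "state_equation.png",
                        outdir / "trajectory.png"])
        return {"n_shrinking": n_shrink, "frac_shrinking": round(frac, 4)}

    _write_manifest()
    return report


def _figure_zeta_vs_area(records, groups, lines, path: Path):
    fig, ax = plt.subplots(figsize=(7, 4.5))
    cmap = plt.get_cmap("viridis")
    for i, g in enumerate(groups):
        sub = records.iloc[g.indices]
        color = cmap(i / max(len(groups) - 1, 1))
        ax.scatter(sub["A_initial_um2"], sub["zeta"], s=12, color=color,
                   label=f"{g.label} ({g.mean_pmax:.0f} kPa)")
        row = lines.iloc[i]
        if row["error"] is None and np.isfinite(row["slope"]):
            x = np.linspace(sub["A_initial_um2"].min(), sub["A_initial_um2"].max(), 20)
            ax.plot(x, row["intercept"] + row["slope"] * x, color=color, lw=0.8)
    ax.set_xlabel("initial area $A_{initial}$ (µm²)")
    ax.set_ylabel(r"$\zeta = A_{final}/A_{initial}$")
    ax.legend(fontsize=5, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _figure_state_equation(config: RunConfig, fit, path: Path):
    fig, ax = plt.subplots(figsize=(6, 4))
    model = config.dataset.model
    if fit is not None and fit.converged:
        model = model.with_(family=fit.family, **fit.params)
    p0 = model.p0
    p = np.linspace(p0 * 1.05, 3400, 300)
    try:
        A = eos.area_model(p, model)
        ax.plot(p, A, label=f"fitted {model.family}")
    except eos.DomainError:
        pass
    # reference curve with an interior inflection, for the curvature marker
    ref = model.with_(family="exponential", B0=1.0, Bprime=-0.25)
    pr = np.linspace(p0 * 1.01, p0 + ref.pref * 3.8, 250)
    ax.plot(pr, eos.area_exponential(pr, ref), "--", lw=1,
            label="exponential reference (B' = -0.25)")
    infl = eos.find_inflection("exponential", ref, (pr[0], pr[-1]))
    if infl.exists:
        ax.plot([infl.p_k], [infl.A_k], "r*", ms=12, label="max deformation rate")
    ax.set_xlabel("pressure p (kPa)")
    ax.set_ylabel("projected area A (µm²)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _figure_trajectory(config: RunConfig, path: Path):
    model = config.dataset.model
    traj = eos.isobaric_trajectory(model.family, model,
                                   model.p0 * 1.2, 3000.0, 24)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(traj.pressures[1:], traj.step_ratios, where="mid")
    ax.set_xlabel("pressure p (kPa)")
    ax.set_ylabel(r"step ratio $\zeta_i = A_{i+1}/A_i$")
    ax.set_title("discrete isobaric loading path")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
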