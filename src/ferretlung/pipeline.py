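"""Run configuration and pipeline orchestration.

A run is described by one declarative YAML (or dict) config with a
``stages`` list and one section per stage.  Unknown keys are rejected
with a nearest-match suggestion, every run writes the fully resolved
config as a JSON sidecar, and deterministic stages reproduce their
outputs bit-for-bit when rerun with the same config and inputs.
"""

from __future__ import annotations

import difflib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import synthetic, qct, pft, stats, io
from .errors import InputError

log = logging.getLogger("ferretlung")

#: stage name -> (allowed keys, dependencies)
STAGE_SCHEMA: dict[str, set] = {
    "simulate_ct": {
        "shape", "spacing", "emphysema_fraction", "seed", "out_volume",
        "out_masks_prefix", "airway_depth", "emphysema_mode",
    },
    "qct": {
        "volume", "lung_threshold", "grow_threshold", "leak_factor",
        "close_radius_mm", "thresholds", "subject", "out_csv", "out_mask",
    },
    "simulate_traces": {"n_controls", "fvc_ml", "tau_s", "t_onset_s", "dt_s",
                        "duration_s", "noise_sd_ml_s", "seed", "out_dir"},
    "spirometry": {"trace", "traces_dir", "x_seconds", "body_length_cm", "out_csv"},
    "calibrate_fevx": {"traces_dir", "floor", "quantile", "out_csv"},
    "pvloop": {"loop", "p_ref_cmh2o", "out_json"},
    "simulate_cohort": {"preset", "seed", "out_csv"},
    "cohort_fit": {"cohort", "response", "out_json"},
    "ne_auc": {"curve", "out_json"},
}

RUN_KEYS = {"stages", "out_dir", "seed"}

#: execution order respecting data dependencies
STAGE_ORDER = [
    "simulate_ct", "qct", "simulate_traces", "spirometry", "calibrate_fevx",
    "pvloop", "simulate_cohort", "cohort_fit", "ne_auc",
]


def _reject_unknown(given: set, allowed: set, context: str) -> None:
    unknown = given - allowed
    if unknown:
        key = sorted(unknown)[0]
        hint = difflib.get_close_matches(key, allowed, n=1)
        suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
        raise InputError(f"unknown config key {key!r} in {context}{suggestion}")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list
    out_dir: str = "runs/latest"
    seed: int = 0
    sections: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _reject_unknown(set(raw) - set(STAGE_SCHEMA), RUN_KEYS, "run config")
        stages = raw.get("stages")
        if not stages:
            raise InputError("config must list at least one stage under 'stages'")
        for st in stages:
            if st not in STAGE_SCHEMA:
                hint = difflib.get_close_matches(st, STAGE_SCHEMA, n=1)
                suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
                raise InputError(f"unknown stage {st!r}{suggestion}")
        sections = {}
        for st in stages:
            section = raw.get(st, {}) or {}
            _reject_unknown(set(section), STAGE_SCHEMA[st], f"stage {st!r}")
            sections[st] = dict(section)
        return cls(
            stages=list(stages),
            out_dir=str(raw.get("out_dir", "runs/latest")),
            seed=int(raw.get("seed", 0)),
            sections=sections,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise InputError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def resolved(self) -> dict:
        return {
            "stages": self.stages,
            "out_dir": self.out_dir,
            "seed": self.seed,
            **{st: self.sections.get(st, {}) for st in self.stages},
            "version": _version(),
        }


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("ferretlung")
    except Exception:
        return "unknown"


def run_pipeline(config: RunConfig, base_dir=".") -> Path:
    """Execute the configured stages in dependency order.

    Returns the run directory, which contains each stage's outputs plus
    ``resolved_config.json``.  Stage context (e.g. the phantom volume
    produced by ``simulate_ct``) flows to downstream stages in-process,
    so a config with only ``qct`` must point at an input volume instead.
    """
    base = Path(base_dir)
    out = base / config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    ordered = [st for st in STAGE_ORDER if st in config.stages]
    for st in ordered:
        t0 = time.perf_counter()
        params = config.sections.get(st, {})
        _STAGE_FUNCS[st](params, ctx, out, config.seed)
        log.info("stage=%s params=%s elapsed=%.2fs", st, params, time.perf_counter() - t0)
    io.write_json_sidecar(config.resolved(), out / "resolved_config.json")
    return out


# --- stage implementations -------------------------------------------------


def _stage_simulate_ct(p, ctx, out, seed):
    spec = synthetic.PhantomSpec(
        shape=tuple(p.get("shape", (96, 96, 96))),
        spacing=tuple(p.get("spacing", (0.5, 0.5, 0.5))),
        emphysema_fraction=float(p.get("emphysema_fraction", 0.25)),
        airway_depth=int(p.get("airway_depth", 3)),
        emphysema_mode=p.get("emphysema_mode", "bernoulli"),
        seed=int(p.get("seed", seed)),
    )
    volume, truth = synthetic.make_ct_phantom(spec)
    ctx["volume"] = volume
    ctx["truth"] = truth
    if "out_volume" in p:
        io.write_volume(volume, out / p["out_volume"])
        io.write_json_sidecar(vars(spec), out / (str(p["out_volume"]) + ".params.json"))
    if "out_masks_prefix" in p:
        prefix = str(p["out_masks_prefix"])
        io.write_mask(truth.lung, out / f"{prefix}_lung.nii.gz")
        io.write_mask(truth.airway, out / f"{prefix}_airway.nii.gz")
        io.write_mask(truth.emphysema, out / f"{prefix}_emphysema.nii.gz")


def _stage_qct(p, ctx, out, seed):
    if "volume" in p:
        volume = io.read_volume(p["volume"])
    elif "volume" in ctx:
        volume = ctx["volume"]
    else:
        raise InputError("qct stage needs a 'volume' path or an upstream simulate_ct stage")
    refined, airway, profile = qct.qct_pipeline(
        volume,
        lung_threshold=float(p.get("lung_threshold", -320.0)),
        grow_threshold=float(p.get("grow_threshold", -950.0)),
        leak_factor=float(p.get("leak_factor", 2.0)),
        close_radius_mm=float(p.get("close_radius_mm", 2.0)),
        thresholds=tuple(p.get("thresholds", qct.DEFAULT_LAA_THRESHOLDS)),
        subject=p.get("subject"),
    )
    ctx["laa_profile"] = profile
    profile.to_frame().to_csv(out / p.get("out_csv", "laa.csv"), index=False)
    if "out_mask" in p:
        io.write_mask(refined, out / p["out_mask"])


def _stage_simulate_traces(p, ctx, out, seed):
    n = int(p.get("n_controls", 5))
    traces = []
    for i in range(n):
        preset = synthetic.TracePreset(
            fvc_ml=float(p.get("fvc_ml", 30.0)),
            taus_s=(float(p.get("tau_s", 0.2)),),
            t_onset_s=float(p.get("t_onset_s", 0.1)),
            dt_s=float(p.get("dt_s", 0.001)),
            duration_s=float(p.get("duration_s", 4.0)),
            noise_sd_ml_s=float(p.get("noise_sd_ml_s", 0.0)),
            seed=int(p.get("seed", seed)) + i,
        )
        traces.append(synthetic.make_expiration_trace(preset))
    ctx["traces"] = traces
    if "out_dir" in p:
        d = out / p["out_dir"]
        d.mkdir(exist_ok=True)
        for i, tr in enumerate(traces):
            io.write_flow_volume_csv(tr, d / f"trace_{i:02d}.csv")


def _load_traces(p, ctx):
    if "traces_dir" in p:
        d = Path(p["traces_dir"])
        return [io.read_flow_volume_csv(f) for f in sorted(d.glob("*.csv"))]
    if "trace" in p:
        return [io.read_flow_volume_csv(p["trace"])]
    if "traces" in ctx:
        return ctx["traces"]
    raise InputError("no trace input: give 'trace'/'traces_dir' or simulate first")


def _stage_spirometry(p, ctx, out, seed):
    import pandas as pd

    traces = _load_traces(p, ctx)
    rows = []
    for i, tr in enumerate(traces):
        res = pft.compute_spirometry(
            tr,
            x_seconds=float(p.get("x_seconds", 0.4)),
            body_length_cm=p.get("body_length_cm"),
        )
        rows.append({"trace": i, **vars(res)})
    pd.DataFrame(rows).to_csv(out / p.get("out_csv", "spirometry.csv"), index=False)
    ctx["spirometry"] = rows


def _stage_calibrate_fevx(p, ctx, out, seed):
    traces = _load_traces(p, ctx)
    res = pft.calibrate_fev_x(
        traces, floor=float(p.get("floor", 0.7)), quantile=p.get("quantile", "min")
    )
    res.table.to_csv(out / p.get("out_csv", "calibration.csv"), index=False)
    io.write_json_sidecar(
        {"x_star_s": res.x_star_s, "floor": res.floor, "quantile": res.quantile},
        out / "calibration.json",
    )
    ctx["x_star_s"] = res.x_star_s


def _stage_pvloop(p, ctx, out, seed):
    if "loop" not in p:
        raise InputError("pvloop stage needs a 'loop' CSV path")
    loop = io.read_pv_csv(p["loop"])
    fit = pft.fit_pv_compliance(loop, p_ref_cmh2o=float(p.get("p_ref_cmh2o", 5.0)))
    io.write_json_sidecar(vars(fit), out / p.get("out_json", "compliance.json"))
    ctx["compliance"] = fit


def _stage_simulate_cohort(p, ctx, out, seed):
    name = p.get("preset", "PiMM")
    if name not in synthetic.COHORT_PRESETS:
        raise InputError(f"unknown cohort preset {name!r} "
                         f"(available: {', '.join(synthetic.COHORT_PRESETS)})")
    cohort = synthetic.make_cohort(synthetic.COHORT_PRESETS[name], seed=int(p.get("seed", seed)))
    ctx["cohort"] = cohort
    cohort.to_csv(out / p.get("out_csv", "cohort.csv"), index=False)


def _stage_cohort_fit(p, ctx, out, seed):
    if "cohort" in p:
        cohort = io.read_cohort_csv(p["cohort"])
    elif "cohort" in ctx:
        cohort = ctx["cohort"]
    else:
        raise InputError("cohort_fit needs a 'cohort' CSV or an upstream simulate_cohort")
    fit = stats.fit_longitudinal(cohort, response=p.get("response", "ic_per_ln"))
    payload = {
        "slopes": fit.slopes,
        "slope_se": fit.slope_se,
        "sex_intercepts": fit.sex_intercepts,
        "random_intercept_sd": fit.random_intercept_sd,
        "residual_sd": fit.residual_sd,
        "n_animals": fit.n_animals,
        "n_obs": fit.n_obs,
    }
    io.write_json_sidecar(payload, out / p.get("out_json", "cohort_fit.json"))
    ctx["cohort_fit"] = fit


def _stage_ne_auc(p, ctx, out, seed):
    if "curve" not in p:
        raise InputError("ne_auc stage needs a 'curve' CSV path")
    curve = io.read_inhibition_csv(p["curve"])
    auc = stats.inhibition_auc(curve)
    io.write_json_sidecar({"auc_ul": auc}, out / p.get("out_json", "ne_auc.json"))
    ctx["ne_auc"] = auc


_STAGE_FUNCS = {
    "simulate_ct": _stage_simulate_ct,
    "qct": _stage_qct,
    "simulate_traces": _stage_simulate_traces,
    "spirometry": _stage_spirometry,
    "calibrate_fevx": _stage_calibrate_fevx,
    "pvloop": _stage_pvloop,
    "simulate_cohort": _stage_simulate_cohort,
    "cohort_fit": _stage_cohort_fit,
    "ne_auc": _stage_ne_auc,
}
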