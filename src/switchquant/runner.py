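"""Pipeline orchestration: configuration, validation, stages, CLI.

A run is a pure function of its configuration: every stage draws its
randomness from config seeds, outputs are written with a fixed CSV
dialect, and the run record lists each output with a SHA-256 checksum so
reruns can be verified byte for byte.

Stage names: ``simulate-umbrella``, ``pmf``, ``simulate-cyto``, ``gate``,
``simulate-qpcr``, ``qpcr``, ``simulate-image``, ``imaging``, ``all``.
Defaults mirror the measurement protocol: 13 bins on 3.75-10.25 A,
convergence tolerance 0.01 kcal/mol, 5 ns equilibration with 5 ns
blocks at 310 K, a 40% scatter gate, a 99.9th-percentile negative
threshold and 8 background regions.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import click
import numpy as np
import yaml

from . import __version__, cyto, imaging, io, pmf, qpcr, synth

STAGES = [
    "simulate-umbrella",
    "pmf",
    "simulate-cyto",
    "gate",
    "simulate-qpcr",
    "qpcr",
    "simulate-image",
    "imaging",
]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "outdir": "switchquant_out",
    "stages": ["all"],
    "umbrella": {
        "center_first": 4.0,
        "center_last": 10.0,
        "n_windows": 13,
        "spring_constant": 20.0,
        "diffusion_coefficient": 1.0,
        "timestep": 0.002,
        "n_steps": 15000,
        "sampling_interval": 1,
        "potential": "double_well",
    },
    "pmf": {
        "grid_lower": 3.75,
        "grid_upper": 10.25,
        "n_bins": 13,
        "temperature": 310.0,
        "tolerance": 0.01,
        "equilibration_ns": 5.0,
        "block_ns": 5.0,
        "windows_manifest": None,
    },
    "cyto": {
        "target_fraction": 0.40,
        "percentile": 99.9,
        "mad_cutoff": 5.0,
        "n_events": 10000,
        "on_fraction": 0.5,
        "channels": {"fsc": "FSC-H", "ssc": "SSC-H", "fl": "FL1-H"},
        "events_csv": None,
        "negative_csv": None,
    },
    "qpcr": {
        "true_fraction": 0.3,
        "noise_sd": 0.15,
        "replicates": 3,
        "calibration_csv": None,
        "samples_csv": None,
    },
    "imaging": {
        "n_regions": 8,
        "n_cells": 12,
        "noise_sd": 0.0,
        "image": None,
        "mask": None,
    },
}


@dataclass
class Finding:
    """One configuration problem: dotted field path, message, allowed domain."""

    field: str
    message: str
    allowed: str = ""

    def __str__(self) -> str:
        extra = f" (allowed: {self.allowed})" if self.allowed else ""
        return f"{self.field}: {self.message}{extra}"


@dataclass
class RunConfig:
    """Validated parameter tree for a pipeline run."""

    params: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_dict(cls, overrides: dict[str, Any]) -> "RunConfig":
        params = copy.deepcopy(DEFAULTS)
        _deep_merge(params, overrides)
        return cls(params=params)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def __getitem__(self, key: str):
        return self.params[key]


def _deep_merge(base: dict, overrides: dict) -> None:
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_merge(base[key], value)
        else:
            base[key] = value


def validate(config: RunConfig) -> list[Finding]:
    """Check every parameter against its documented domain.

    Returns an empty list iff the config is runnable; all problems are
    reported at once, each with its dotted field path.
    """
    p = config.params
    findings: list[Finding] = []

    def check(cond: bool, fld: str, msg: str, allowed: str = "") -> None:
        if not cond:
            findings.append(Finding(fld, msg, allowed))

    stages = p["stages"]
    known = set(STAGES) | {"all"}
    for s in stages:
        check(s in known, "stages", f"unknown stage {s!r}", ", ".join(sorted(known)))
    g = p["pmf"]
    check(g["n_bins"] >= 1, "pmf.n_bins", f"got {g['n_bins']}", ">= 1")
    check(g["grid_upper"] > g["grid_lower"], "pmf.grid_upper", "upper must exceed lower")
    check(g["temperature"] > 0, "pmf.temperature", f"got {g['temperature']}", "> 0 K")
    check(g["tolerance"] > 0, "pmf.tolerance", f"got {g['tolerance']}", "> 0 kcal/mol")
    check(g["block_ns"] > 0, "pmf.block_ns", f"got {g['block_ns']}", "> 0 ns")
    u = p["umbrella"]
    check(u["n_windows"] >= 1, "umbrella.n_windows", f"got {u['n_windows']}", ">= 1")
    check(u["spring_constant"] >= 0, "umbrella.spring_constant", "must be >= 0")
    check(u["timestep"] > 0, "umbrella.timestep", "must be > 0 ns")
    check(u["n_steps"] >= u["sampling_interval"], "umbrella.n_steps", "fewer steps than sampling interval")
    c = p["cyto"]
    check(0 < c["target_fraction"] < 1, "cyto.target_fraction", f"got {c['target_fraction']}", "(0, 1)")
    check(0 < c["percentile"] < 100, "cyto.percentile", f"got {c['percentile']}", "(0, 100)")
    check(c["mad_cutoff"] > 0, "cyto.mad_cutoff", "must be > 0")
    check(0 <= c["on_fraction"] <= 1, "cyto.on_fraction", f"got {c['on_fraction']}", "[0, 1]")
    q = p["qpcr"]
    check(0 <= q["true_fraction"] <= 1, "qpcr.true_fraction", f"got {q['true_fraction']}", "[0, 1]")
    check(q["replicates"] >= 1, "qpcr.replicates", "must be >= 1")
    im = p["imaging"]
    check(im["n_regions"] >= 1, "imaging.n_regions", "must be >= 1")
    # cross-stage requirement: gating needs a negative control
    wants = set(stages)
    if "gate" in wants and "all" not in wants and "simulate-cyto" not in wants:
        check(
            c["negative_csv"] is not None,
            "cyto.negative_csv",
            "gate stage without simulate-cyto needs a negative-control event file",
        )
        check(
            c["events_csv"] is not None,
            "cyto.events_csv",
            "gate stage without simulate-cyto needs an event file",
        )
    if "pmf" in wants and "all" not in wants and "simulate-umbrella" not in wants:
        check(
            g["windows_manifest"] is not None,
            "pmf.windows_manifest",
            "pmf stage without simulate-umbrella needs a windows manifest",
        )
    return findings


@dataclass
class RunRecord:
    config: dict
    version: str
    timings: dict[str, float]
    warnings: list[str]
    manifest: dict[str, str]  # path -> sha256


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> RunRecord:
    """Execute the requested stages in dependency order."""
    problems = validate(config)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(str(f) for f in problems))

    p = config.params
    outdir = Path(p["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    wants = set(p["stages"])
    if "all" in wants:
        wants = set(STAGES)

    timings: dict[str, float] = {}
    warnings_log: list[str] = []
    outputs: list[Path] = []
    seed = int(p["seed"])

    windows = None
    for stage in STAGES:  # fixed dependency order
        if stage not in wants:
            continue
        t0 = time.perf_counter()
        if stage == "simulate-umbrella":
            windows = _stage_simulate_umbrella(p, seed, outdir, outputs)
        elif stage == "pmf":
            _stage_pmf(p, outdir, outputs, windows)
        elif stage == "simulate-cyto":
            _stage_simulate_cyto(p, seed, outdir, outputs)
        elif stage == "gate":
            _stage_gate(p, outdir, outputs)
        elif stage == "simulate-qpcr":
            _stage_simulate_qpcr(p, seed, outdir, outputs)
        elif stage == "qpcr":
            _stage_qpcr(p, outdir, outputs)
        elif stage == "simulate-image":
            _stage_simulate_image(p, seed, outdir, outputs)
        elif stage == "imaging":
            _stage_imaging(p, seed, outdir, outputs)
        timings[stage] = time.perf_counter() - t0

    record = RunRecord(
        config=copy.deepcopy(p),
        version=__version__,
        timings=timings,
        warnings=warnings_log,
        manifest={str(path.relative_to(outdir)): _sha256(path) for path in outputs},
    )
    with open(outdir / "run_record.json", "w", encoding="utf-8") as fh:
        json.dump(record.__dict__, fh, indent=2, sort_keys=True, default=io._json_default)
        fh.write("\n")
    return record


# --- stage implementations -------------------------------------------------


def _thermo(p) -> pmf.Thermo:
    return pmf.Thermo(temperature=p["pmf"]["temperature"])


def _stage_simulate_umbrella(p, seed, outdir, outputs):
    u = p["umbrella"]
    potential = synth.double_well() if u["potential"] == "double_well" else synth.harmonic_potential(2.0, 7.0)
    centers = np.linspace(u["center_first"], u["center_last"], u["n_windows"])
    spec = synth.LangevinSpec(
        diffusion_coefficient=u["diffusion_coefficient"],
        timestep=u["timestep"],
        n_steps=u["n_steps"],
        sampling_interval=u["sampling_interval"],
        seed=seed,
    )
    windows = synth.simulate_umbrella(
        potential, [(float(c), u["spring_constant"]) for c in centers], spec, _thermo(p)
    )
    manifest = io.write_window_panel(windows, outdir / "umbrella")
    outputs.extend(sorted(manifest.parent.glob("*.csv")))
    p["pmf"]["windows_manifest"] = str(manifest)
    return windows


def _stage_pmf(p, outdir, outputs, windows):
    g = p["pmf"]
    if windows is None:
        windows = io.read_window_panel(g["windows_manifest"])
    grid = pmf.make_grid(g["grid_lower"], g["grid_upper"], g["n_bins"])
    profile, blocks = pmf.estimate_pmf(
        windows,
        grid,
        _thermo(p),
        equilibration_ns=g["equilibration_ns"],
        block_ns=g["block_ns"],
        tolerance=g["tolerance"],
        return_blocks=True,
    )
    io.write_pmf_csv(profile, outdir / "pmf.csv")
    io.write_run_summary(
        {
            "n_blocks": profile.n_blocks,
            "iterations_per_block": [b.n_iterations for b in blocks],
            "samples_outside_grid": [b.n_outside.tolist() for b in blocks],
        },
        outdir / "pmf_summary.json",
    )
    outputs.extend([outdir / "pmf.csv", outdir / "pmf_summary.json"])


def _stage_simulate_cyto(p, seed, outdir, outputs):
    c = p["cyto"]
    test = synth.simulate_cytometry(
        synth.CytometryPanelSpec(n_events=c["n_events"], on_fraction=c["on_fraction"], seed=seed),
        sample_id="test", role="test",
    )
    neg = synth.simulate_cytometry(
        synth.CytometryPanelSpec(n_events=c["n_events"], on_fraction=0.0, seed=seed + 1),
        sample_id="negative", role="negative_control",
    )
    io.write_events_csv(test, outdir / "events_test.csv")
    io.write_events_csv(neg, outdir / "events_negative.csv")
    c["events_csv"] = str(outdir / "events_test.csv")
    c["negative_csv"] = str(outdir / "events_negative.csv")
    outputs.extend([outdir / "events_test.csv", outdir / "events_negative.csv"])


def _stage_gate(p, outdir, outputs):
    import pandas as pd

    c = p["cyto"]
    test = cyto.read_events_csv(c["events_csv"], sample_id="test", channels=c["channels"])
    neg = cyto.read_events_csv(
        c["negative_csv"], sample_id="negative", role="negative_control", channels=c["channels"]
    )
    gate_t = cyto.kde_gate(test, target_fraction=c["target_fraction"])
    gate_n = cyto.kde_gate(neg, target_fraction=c["target_fraction"])
    thr = cyto.negative_threshold(neg, gate_n, percentile=c["percentile"])
    result = cyto.fraction_on(test, gate_t, thr)
    pd.DataFrame(
        [
            {
                "sample_id": result.sample_id,
                "threshold": result.threshold,
                "fraction_on": result.fraction_on,
                "n_gated": result.n_gated,
                "outlier_flag": result.outlier_flag,
            }
        ]
    ).to_csv(outdir / "switch_results.csv", index=False, float_format=io.FLOAT_FMT)
    outputs.append(outdir / "switch_results.csv")


def _stage_simulate_qpcr(p, seed, outdir, outputs):
    import pandas as pd

    q = p["qpcr"]
    lox_spec = synth.QpcrSimSpec(
        true_fraction=q["true_fraction"], noise_sd=q["noise_sd"], replicates=q["replicates"], seed=seed
    )
    total_spec = synth.QpcrSimSpec(
        true_fraction=1.0, noise_sd=q["noise_sd"], replicates=q["replicates"], seed=seed + 1
    )
    frames = []
    samples = []
    for assay, spec in (("lox", lox_spec), ("total", total_spec)):
        cal, cts = synth.simulate_qpcr(spec)
        cal.insert(0, "assay", assay)
        frames.append(cal)
        samples.extend({"sample_id": "sample", "assay": assay, "Ct": ct} for ct in cts)
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "qpcr_calibration.csv", index=False, float_format=io.FLOAT_FMT
    )
    pd.DataFrame(samples).to_csv(outdir / "qpcr_samples.csv", index=False, float_format=io.FLOAT_FMT)
    q["calibration_csv"] = str(outdir / "qpcr_calibration.csv")
    q["samples_csv"] = str(outdir / "qpcr_samples.csv")
    outputs.extend([outdir / "qpcr_calibration.csv", outdir / "qpcr_samples.csv"])


def _stage_qpcr(p, outdir, outputs):
    import pandas as pd

    q = p["qpcr"]
    cal = pd.read_csv(q["calibration_csv"])
    samples = pd.read_csv(q["samples_csv"])
    curves = {assay: qpcr.fit_standard_curve(sub) for assay, sub in cal.groupby("assay")}
    rows = []
    for sample_id, sub in samples.groupby("sample_id"):
        est = qpcr.excision_fraction(
            sub.loc[sub["assay"] == "lox", "Ct"].to_numpy(),
            curves["lox"],
            sub.loc[sub["assay"] == "total", "Ct"].to_numpy(),
            curves["total"],
        )
        rows.append(
            {
                "sample_id": sample_id,
                "n_lox": est.n_lox,
                "n_total": est.n_total,
                "fraction": est.fraction,
                "over_one": est.over_one,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "excision.csv", index=False, float_format=io.FLOAT_FMT)
    pd.DataFrame(
        [
            {"assay": a, "intercept": cv.intercept, "slope": cv.slope, "r_squared": cv.r_squared,
             "n_points": cv.n_points, "efficiency": cv.amplification_efficiency}
            for a, cv in curves.items()
        ]
    ).to_csv(outdir / "standard_curves.csv", index=False, float_format=io.FLOAT_FMT)
    outputs.extend([outdir / "excision.csv", outdir / "standard_curves.csv"])


def _stage_simulate_image(p, seed, outdir, outputs):
    im = p["imaging"]
    li = synth.simulate_microscopy(
        synth.ImageSimSpec(n_cells=im["n_cells"], noise_sd=im["noise_sd"], seed=seed)
    )
    io.write_image_pair(li, outdir / "image.tif", outdir / "mask.tif")
    im["image"] = str(outdir / "image.tif")
    im["mask"] = str(outdir / "mask.tif")
    outputs.extend([outdir / "image.tif", outdir / "mask.tif"])


def _stage_imaging(p, seed, outdir, outputs):
    import pandas as pd

    im = p["imaging"]
    li = imaging.read_labeled_image(im["image"], im["mask"])
    records = imaging.corrected_intensities(li, n_regions=im["n_regions"], seed=seed)
    pd.DataFrame(
        [
            {"label": r.label, "area": r.area, "mean_intensity": r.mean_intensity,
             "background": r.background, "corrected_intensity": r.corrected_intensity}
            for r in records
        ]
    ).to_csv(outdir / "cell_intensities.csv", index=False, float_format=io.FLOAT_FMT)
    outputs.append(outdir / "cell_intensities.csv")


# --- CLI -------------------------------------------------------------------


@click.group()
def cli() -> None:
    """Recombination-switch quantification pipeline."""


def _common_options(fn):
    fn = click.option("--config", "config_path", type=click.Path(exists=True), default=None,
                      help="YAML configuration file.")(fn)
    fn = click.option("--outdir", default=None, help="Output directory.")(fn)
    fn = click.option("--seed", default=None, type=int, help="Master seed.")(fn)
    return fn


def _build_config(config_path, outdir, seed, stages, **stage_overrides) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    if outdir is not None:
        cfg.params["outdir"] = outdir
    if seed is not None:
        cfg.params["seed"] = seed
    cfg.params["stages"] = stages
    for dotted, value in stage_overrides.items():
        if value is None:
            continue
        section, key = dotted.split("__")
        cfg.params[section][key] = value
    return cfg


def _execute(cfg: RunConfig) -> None:
    problems = validate(cfg)
    if problems:
        for f in problems:
            click.echo(f"error: {f}", err=True)
        raise SystemExit(2)
    record = run(cfg)
    for stage, dt in record.timings.items():
        click.echo(f"{stage}: {dt:.2f} s")
    click.echo(f"outputs: {len(record.manifest)} files in {cfg.params['outdir']}")


@cli.command("validate")
@_common_options
def cmd_validate(config_path, outdir, seed):
    """Validate a configuration and list every problem."""
    cfg = _build_config(config_path, outdir, seed, stages=["all"])
    problems = validate(cfg)
    if problems:
        for f in problems:
            click.echo(str(f))
        raise SystemExit(2)
    click.echo("configuration OK")


def _stage_command(name: str, stages: list[str], extra_options=()):
    @_common_options
    def command(config_path, outdir, seed, **kwargs):
        cfg = _build_config(config_path, outdir, seed, stages=stages, **kwargs)
        _execute(cfg)

    command.__name__ = name.replace("-", "_")
    for opt in extra_options:
        command = opt(command)
    return cli.command(name)(command)


_stage_command("simulate-umbrella", ["simulate-umbrella"])
_stage_command(
    "pmf", ["pmf"],
    extra_options=[
        click.option("--windows-manifest", "pmf__windows_manifest", default=None,
                     help="Manifest CSV of umbrella-window files."),
    ],
)
_stage_command(
    "simulate-cyto", ["simulate-cyto"],
    extra_options=[click.option("--on-fraction", "cyto__on_fraction", type=float, default=None)],
)
_stage_command(
    "gate", ["gate"],
    extra_options=[
        click.option("--events", "cyto__events_csv", default=None),
        click.option("--negative", "cyto__negative_csv", default=None),
        click.option("--target-fraction", "cyto__target_fraction", type=float, default=None),
    ],
)
_stage_command("simulate-qpcr", ["simulate-qpcr"])
_stage_command("qpcr", ["qpcr"], extra_options=[
    click.option("--calibration", "qpcr__calibration_csv", default=None),
    click.option("--samples", "qpcr__samples_csv", default=None),
])
_stage_command("simulate-image", ["simulate-image"])
_stage_command("imaging", ["imaging"], extra_options=[
    click.option("--image", "imaging__image", default=None),
    click.option("--mask", "imaging__mask", default=None),
])
_stage_command("all", ["all"])


if __name__ == "__main__":
    cli()
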