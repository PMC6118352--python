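"""End-to-end orchestration: simulate -> univariate / bivariate -> states ->
compare -> report, driven by one YAML run config.

A run config looks like::

    seed: 7
    output_dir: out
    stages: [simulate, univariate, states, report]
    analysis: {n_envelope: 200, r_max: 240}
    scenario:
      kind: clustered            # csr | clustered | bivariate
      sheets: 15
      condition: control
      n: 300                     # csr only
      cluster: {parents: 25, offspring: 6, sigma: 10}
      bivariate: {shared_fraction: 1.0, big: {...}, small: {...}}
    # or, instead of a scenario:
    input: coords.csv

Every stochastic step draws its generator from ``SeedSequence((seed, stage,
index))``, so re-running an identical config reproduces all numeric outputs
exactly.  The returned manifest records the config snapshot, input hashes,
seeds, package version and per-stage outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bivariate import bivariate_envelope, k_bivariate, l_biv_transform, lbi
from .config import AnalysisConfig
from .inference import anova_densities, bootstrap_compare, density, group_summary
from .io import read_coordinates, write_coordinates, write_curve, write_json
from .patterns import BivariatePattern, PointPattern, ValidationError
from .states import classify_pattern
from .synthetic import BivariateSpec, ClusterProcessSpec, gen_bivariate, gen_clustered, gen_csr
from .univariate import csr_envelope, k_univariate, l_transform, lmax, standardize

__all__ = ["PipelineError", "RunManifest", "run_pipeline"]

_STAGE_CODES = {
    "simulate": 1,
    "univariate": 2,
    "bivariate": 3,
    "states": 4,
    "compare": 5,
    "report": 6,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    stages: list[str]
    outputs: dict[str, list[str]] = field(default_factory=dict)
    input_hashes: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        write_json(asdict(self), path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(seed), _STAGE_CODES[stage], int(index)))


def _simulate(raw: dict, cfg: AnalysisConfig, seed: int):
    kind = raw.get("kind", "csr")
    sheets = int(raw.get("sheets", 15))
    condition = str(raw.get("condition", ""))
    region = cfg.region
    patterns = []
    for i in range(sheets):
        ss = _stage_seed(seed, "simulate", i)
        sid = f"{condition or 'sheet'}_{i:03d}"
        if kind == "csr":
            patterns.append(
                gen_csr(int(raw.get("n", 300)), region, ss, sheet_id=sid, condition=condition)
            )
        elif kind == "clustered":
            spec = ClusterProcessSpec(**raw.get("cluster", {}))
            patterns.append(
                gen_clustered(spec, region, ss, sheet_id=sid, condition=condition).pattern
            )
        elif kind == "bivariate":
            braw = dict(raw.get("bivariate", {}))
            spec = BivariateSpec(
                shared_fraction=float(braw.get("shared_fraction", 1.0)),
                big=ClusterProcessSpec(**braw.get("big", {})),
                small=ClusterProcessSpec(**braw.get("small", {})),
            )
            patterns.append(
                gen_bivariate(spec, region, ss, sheet_id=sid, condition=condition).pattern
            )
        else:
            raise PipelineError(f"simulate: unknown scenario kind {kind!r}")
    return patterns


def _univariate_stage(patterns, cfg: AnalysisConfig, seed: int, out: Path) -> list[str]:
    uni = [p for p in patterns if isinstance(p, PointPattern)]
    if not uni:
        raise PipelineError("univariate: input contains no single-channel sheets")
    outputs: list[str] = []
    env_cache: dict[int, object] = {}
    radii = cfg.radii
    summary = []
    for p in uni:
        k = k_univariate(p, radii, unbiased=cfg.unbiased_k)
        l_curve = l_transform(k)
        if p.n not in env_cache:
            env_cache[p.n] = csr_envelope(
                p.n,
                cfg.region,
                radii,
                level=cfg.univariate_level,
                n_sim=cfg.n_envelope,
                seed=_stage_seed(seed, "univariate", p.n),
                floor=cfg.envelope_floor,
                unbiased=cfg.unbiased_k,
            )
        env = env_cache[p.n]
        std = standardize(l_curve, env)
        peak = lmax(std)
        for suffix, curve in (("K", k), ("L", l_curve), ("std", std)):
            path = out / f"{p.sheet_id}_{suffix}.csv"
            write_curve(curve, path)
            outputs.append(str(path))
        summary.append(
            {
                "sheet_id": p.sheet_id,
                "condition": p.condition,
                "n": p.n,
                "density_per_um2": density(p),
                "l_max": peak.value,
                "l_max_radius_nm": peak.radius,
                "n_clamped_radii": int(env.clamped.sum()),
            }
        )
    path = out / "univariate_summary.json"
    write_json(summary, path)
    outputs.append(str(path))
    return outputs


def _bivariate_stage(patterns, cfg: AnalysisConfig, seed: int, out: Path) -> list[str]:
    biv = [p for p in patterns if isinstance(p, BivariatePattern)]
    if not biv:
        raise PipelineError(
            "bivariate: input has no two-channel sheets (missing 'big'/'small' channel)"
        )
    outputs: list[str] = []
    radii = cfg.radii
    summary = []
    for i, bp in enumerate(biv):
        curves = k_bivariate(bp, radii)
        l_curve = l_biv_transform(curves.k_biv)
        env = bivariate_envelope(
            bp,
            radii,
            level=cfg.bivariate_level,
            n_sim=cfg.n_envelope,
            seed=_stage_seed(seed, "bivariate", i),
            floor=cfg.envelope_floor,
            shift_channel=cfg.shift_channel,
        )
        std = standardize(l_curve, env)
        score = lbi(std, cfg.lbi_bounds, sheet_id=bp.sheet_id)
        for suffix, curve in (
            ("Kbs", curves.k_bs),
            ("Ksb", curves.k_sb),
            ("Kbiv", curves.k_biv),
            ("Lbiv", l_curve),
            ("std", std),
        ):
            path = out / f"{bp.sheet_id}_{suffix}.csv"
            write_curve(curve, path)
            outputs.append(str(path))
        summary.append(
            {
                "sheet_id": bp.sheet_id,
                "condition": bp.condition,
                "n_big": bp.n_big,
                "n_small": bp.n_small,
                "lbi": score.lbi,
                "co_localized": score.co_localized,
            }
        )
    gs = group_summary("all", [s["lbi"] for s in summary])
    path = out / "bivariate_summary.json"
    write_json({"sheets": summary, "lbi_mean": gs.mean, "lbi_sem": gs.sem}, path)
    outputs.append(str(path))
    return outputs


def _states_stage(patterns, cfg: AnalysisConfig, out: Path) -> list[str]:
    uni = [p for p in patterns if isinstance(p, PointPattern)]
    if not uni:
        raise PipelineError("states: input contains no single-channel sheets")
    rows = []
    for p in uni:
        d = classify_pattern(p, cfg.linkage_nm, cfg.oligomer_min_size)
        rows.append(
            {
                "sheet_id": d.sheet_id,
                "condition": p.condition,
                "monomer": d.monomer,
                "dimer": d.dimer,
                "oligomer": d.oligomer,
                "unassigned": d.unassigned,
                "size_histogram": {str(k): v for k, v in sorted(d.size_histogram.items())},
            }
        )
    path = out / "states.json"
    write_json(rows, path)
    return [str(path)]


def _compare_stage(patterns, cfg: AnalysisConfig, seed: int, out: Path) -> list[str]:
    uni = [p for p in patterns if isinstance(p, PointPattern)]
    conditions = sorted({p.condition for p in uni})
    if len(conditions) != 2:
        raise PipelineError(
            f"compare: need exactly 2 conditions among single-channel sheets, got {conditions}"
        )
    radii = cfg.radii
    groups = {c: [p for p in uni if p.condition == c] for c in conditions}
    curves = {
        c: [l_transform(k_univariate(p, radii, unbiased=cfg.unbiased_k)) for p in groups[c]]
        for c in conditions
    }
    counts = {c: [p.n for p in groups[c]] for c in conditions}
    a, b = conditions
    res = bootstrap_compare(
        curves[a],
        counts[a],
        curves[b],
        counts[b],
        n_boot=cfg.n_bootstrap,
        seed=_stage_seed(seed, "compare"),
        weighting=cfg.weighting,
    )
    dens = {c: [density(p) for p in groups[c]] for c in conditions}
    an = anova_densities([dens[a], dens[b]])
    payload = {
        "group_a": a,
        "group_b": b,
        "t_obs": res.t_obs,
        "p_value": res.p_value,
        "n_boot": res.n_boot,
        "weighting": res.weighting,
        "r_range_nm": list(res.r_range),
        "anova_f": an.f_statistic,
        "anova_p": an.p_value,
        "density_mean": {c: float(np.mean(dens[c])) for c in conditions},
    }
    path = out / "compare.json"
    write_json(payload, path)
    return [str(path)]


def _report_stage(out: Path) -> list[str]:
    from .io import read_curve
    from .plotting import plot_group_bars, plot_standardized
    import json as _json
    import matplotlib.pyplot as plt

    outputs: list[str] = []
    std_paths = sorted(out.glob("*_std.csv"))
    if std_paths:
        curves = [read_curve(p) for p in std_paths[:12]]
        ax = plot_standardized(curves, labels=[p.stem[:-4] for p in std_paths[:12]])
        fig_path = out / "standardized_curves.png"
        ax.figure.savefig(fig_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        outputs.append(str(fig_path))
    biv = out / "bivariate_summary.json"
    if biv.exists():
        data = _json.loads(biv.read_text())
        gs = group_summary("all sheets", [s["lbi"] for s in data["sheets"]])
        ax = plot_group_bars([gs], ylabel="LBI", reference=100.0)
        fig_path = out / "lbi_summary.png"
        ax.figure.savefig(fig_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        outputs.append(str(fig_path))
    return outputs


def run_pipeline(config_path: str | Path, output_dir: str | Path | None = None) -> RunManifest:
    """Execute the stages requested in a YAML run config; see module docstring."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = AnalysisConfig.from_dict(raw.get("analysis", {}))
    seed = int(raw.get("seed", cfg.seed))
    out = Path(output_dir or raw.get("output_dir", "nanospat_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(raw.get("stages", []))
    if not stages:
        raise PipelineError("run: config lists no stages")
    unknown = set(stages) - set(_STAGE_CODES)
    if unknown:
        raise PipelineError(f"run: unknown stages {sorted(unknown)}")

    manifest = RunManifest(
        version=__version__, seed=seed, config={**raw, "analysis": cfg.to_dict()}, stages=stages
    )

    patterns = None
    if "simulate" in stages:
        scenario = raw.get("scenario")
        if scenario is None:
            raise PipelineError("simulate: config has no scenario block")
        try:
            patterns = _simulate(scenario, cfg, seed)
        except (ValidationError, TypeError) as exc:
            raise PipelineError(f"simulate: {exc}") from exc
        coords = out / "coords.csv"
        write_coordinates(patterns, coords)
        manifest.outputs["simulate"] = [str(coords)]
    if patterns is None:
        input_path = raw.get("input")
        if input_path is None:
            raise PipelineError("run: config needs either a scenario or an input file")
        input_path = Path(input_path)
        if not input_path.is_absolute():
            input_path = config_path.parent / input_path
        patterns = read_coordinates(input_path, cfg)
        manifest.input_hashes[str(input_path)] = _sha256(input_path)

    for stage in stages:
        if stage == "simulate":
            continue
        try:
            if stage == "univariate":
                manifest.outputs[stage] = _univariate_stage(patterns, cfg, seed, out)
            elif stage == "bivariate":
                manifest.outputs[stage] = _bivariate_stage(patterns, cfg, seed, out)
            elif stage == "states":
                manifest.outputs[stage] = _states_stage(patterns, cfg, out)
            elif stage == "compare":
                manifest.outputs[stage] = _compare_stage(patterns, cfg, seed, out)
            elif stage == "report":
                manifest.outputs[stage] = _report_stage(out)
        except PipelineError:
            raise
        except (ValidationError, ValueError) as exc:
            raise PipelineError(f"{stage}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest.save(manifest_path)
    return manifest
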