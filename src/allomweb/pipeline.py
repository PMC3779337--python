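"""End-to-end experiment orchestration with reproducible seeding.

An experiment is: obtain communities (from files or the synthetic
generator), preprocess them, fit the free parameters from Sobol starts,
optionally refit under within-category rate shuffles, optionally score
every visited parameter point on a second community, and write all stage
outputs plus a manifest (config hash, stage seeds, content hashes,
versions).  Stage seeds are derived from the master seed by hashing the
stage name, so adding a stage never perturbs the seeds of the others.
"""

from __future__ import annotations

import hashlib
import json
import platform
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import Community, read_community, remove_unconsumed_producers, write_community
from .dynamics import SimulationSettings, simulate_to_stationary
from .fitting import (
    FitResult,
    ParameterSpace,
    best_fit,
    cross_community_scores,
    run_fit,
)
from .model import FREE_PARAMETER_NAMES, FixedAllometry
from .randomize import RandomizationPlan, run_randomization_study
from .scoring import model_score, summarize_patterns
from .synth import SyntheticSpec, generate_community


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence keyed on the master seed
    and a CRC32 of the stage name, reduced below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun an experiment bit-identically."""

    master_seed: int
    out_dir: str
    nodes_path: str | None = None
    links_path: str | None = None
    synthetic_spec: SyntheticSpec | None = None
    nodes2_path: str | None = None
    links2_path: str | None = None
    synthetic_spec2: SyntheticSpec | None = None
    n_starts: int = 32
    max_evaluations: int = 400
    randomization_targets: tuple[str, ...] = ()
    n_randomization_replicates: int = 3
    randomization_n_starts: int | None = None
    cross_score: bool = False
    constants_path: str | None = None
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    space: ParameterSpace = field(default_factory=ParameterSpace.default)

    def fixed(self) -> FixedAllometry:
        if self.constants_path:
            return FixedAllometry.from_yaml(self.constants_path)
        return FixedAllometry.default()


def _config_digest(config: ExperimentConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)

    blob = json.dumps(asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _load_community(config: ExperimentConfig, which: int, seed: int
                    ) -> Community | None:
    if which == 1:
        nodes, links, spec = (config.nodes_path, config.links_path,
                              config.synthetic_spec)
    else:
        nodes, links, spec = (config.nodes2_path, config.links2_path,
                              config.synthetic_spec2)
    if nodes and links:
        return read_community(nodes, links)
    if spec is not None:
        return generate_community(spec, seed)
    return None


def _fits_frame(fits: list[FitResult]) -> pd.DataFrame:
    rows = []
    for i, f in enumerate(fits):
        row = {"run": i, "score_start": f.score_start, "score_end": f.score_end,
               "n_evaluations": f.n_evaluations, "converged": f.converged}
        for name in FREE_PARAMETER_NAMES:
            row[f"start_{name}"] = getattr(f.start, name)
            row[f"end_{name}"] = getattr(f.end, name)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_json(path: Path, payload) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=default) + "\n", encoding="utf-8")


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the configured experiment; returns the report dict.

    All floating-point outputs are serialized through repr/JSON at full
    precision, so a rerun with the same config and seed is byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixed = config.fixed()
    manifest: dict = {
        "config_sha256": _config_digest(config),
        "allomweb_version": __version__,
        "python": platform.python_version(),
        "master_seed": config.master_seed,
        "stage_seeds": {},
        "outputs": {},
        "status": "running",
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }

    report: dict = {}
    try:
        seed_c1 = stage_seed(config.master_seed, "community-1")
        seed_c2 = stage_seed(config.master_seed, "community-2")
        manifest["stage_seeds"]["community-1"] = seed_c1
        manifest["stage_seeds"]["community-2"] = seed_c2
        c1 = _load_community(config, 1, seed_c1)
        if c1 is None:
            raise ValueError("no community source configured")
        c1, removed = remove_unconsumed_producers(c1)
        report["removed_unconsumed_producers"] = removed
        write_community(c1, out / "community_nodes.csv", out / "community_links.csv")
        record("community_nodes", out / "community_nodes.csv")
        record("community_links", out / "community_links.csv")

        c2 = _load_community(config, 2, seed_c2)
        if c2 is not None:
            c2, removed2 = remove_unconsumed_producers(c2)
            report["removed_unconsumed_producers_2"] = removed2

        fit_seed = stage_seed(config.master_seed, "fit")
        manifest["stage_seeds"]["fit"] = fit_seed
        communities = c1 if c2 is None else [c1, c2]
        fits = run_fit(communities, config.space, config.n_starts, fit_seed,
                       fixed, config.settings,
                       max_evaluations=config.max_evaluations)
        fits_frame = _fits_frame(fits)
        fits_frame.to_csv(out / "fits.csv", index=False,
                          float_format="%.17g")
        record("fits", out / "fits.csv")

        best = best_fit(fits)
        sim = simulate_to_stationary(c1, fixed, best.end, config.settings)
        score = model_score(sim, c1)
        patterns = summarize_patterns(c1, sim)
        report["best_parameters"] = best.end.to_dict()
        report["best_score"] = score.to_dict()
        report["stationary_kind"] = sim.stationary_kind
        report["sse_model_vs_regression"] = {
            "sse_model": score.sse_model,
            "sse_regression": score.sse_regression,
            "model_beats_regression": bool(score.sse_model < score.sse_regression),
        }
        report["regression_slopes_data"] = {
            k: v.slope for k, v in patterns.regressions_data.items()}
        report["regression_slopes_sim"] = {
            k: v.slope for k, v in patterns.regressions_sim.items()}
        _write_json(out / "best_endpoint.json", {
            "parameters": best.end.to_dict(),
            "score": score.to_dict(),
            "B_sim": sim.B_sim,
            "N_sim": sim.N_sim,
            "persisting": sim.persisting,
            "stationary_kind": sim.stationary_kind,
        })
        record("best_endpoint", out / "best_endpoint.json")

        if config.randomization_targets:
            rand_frames = []
            n_rand = config.randomization_n_starts or config.n_starts
            for target in config.randomization_targets:
                rand_seed = stage_seed(config.master_seed, f"randomize-{target}")
                manifest["stage_seeds"][f"randomize-{target}"] = rand_seed
                plan = RandomizationPlan(
                    target=target,
                    n_replicates=config.n_randomization_replicates,
                    seed=rand_seed,
                )
                rep = run_randomization_study(
                    c1, plan, config.space, n_rand, fixed, config.settings,
                    baseline=fits if c2 is None else None,
                    max_evaluations=config.max_evaluations,
                )
                rand_frames.append(rep.to_frame())
                report.setdefault("randomization", {})[target] = {
                    "baseline_best_score": rep.baseline_best.score_end,
                    "replicate_best_scores": [f.score_end
                                              for f in rep.replicate_fits],
                    "n_below_baseline": rep.n_below_baseline,
                }
            pd.concat(rand_frames, ignore_index=True).to_csv(
                out / "randomization.csv", index=False, float_format="%.17g")
            record("randomization", out / "randomization.csv")

        if config.cross_score and c2 is not None:
            points = [f.start for f in fits] + [f.end for f in fits]
            s1, s2, r = cross_community_scores(points, c1, c2, fixed,
                                               config.settings)
            pd.DataFrame({"score_c1": s1, "score_c2": s2}).to_csv(
                out / "cross_scores.csv", index=False, float_format="%.17g")
            record("cross_scores", out / "cross_scores.csv")
            report["cross_community_pearson_r"] = r

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        raise
    finally:
        _write_json(out / "report.json", report)
        record("report", out / "report.json")
        _write_json(out / "manifest.json", manifest)
    return report
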