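"""Pipeline orchestration: simulate -> fit -> compare -> summarize.

A run is driven by a configuration mapping (YAML or JSON on disk).  Every
stochastic stage receives a seed derived deterministically from the global
seed and a stage tag, so a rerun with the same configuration reproduces
every artifact byte for byte; the manifest lists each output with its
SHA-256 hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from .agents import AgentSpec, efficiency_ratios, generate_session, planner_session_for
from .choice import ChoiceModelParams, SessionData
from .fitting import (
    FitResult,
    compare_lookaheads,
    compare_submodels,
    fit_session,
)
from .movement import default_movement_model, fit_movement_time, harvest_movement_records
from .session_io import read_session, write_session
from .summaries import (
    distance_distribution,
    path_ranking,
    selection_diagnostics,
    selection_proportions,
)

log = logging.getLogger("foragekit")


def seed_for(global_seed: int, tag: str) -> int:
    """Deterministic per-stage seed derived from the global seed and a tag."""
    digest = hashlib.sha256(f"{global_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:8], "little")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def params_from_config(obj: dict) -> ChoiceModelParams:
    lambdas = tuple(obj.get("lambdas", ()))
    return ChoiceModelParams(
        beta=float(obj.get("beta", 0.05)),
        w1=float(obj.get("w1", 500.0)),
        gamma=float(obj.get("gamma", 1.0)),
        w2=float(obj.get("w2", 1000.0)),
        lambdas=lambdas,
        lookahead_n=int(obj.get("lookahead_n", len(lambdas) + 1)),
        include_reward_rate=bool(obj.get("include_reward_rate", True)),
        include_distance=bool(obj.get("include_distance", True)),
        include_size=bool(obj.get("include_size", True)),
    )


def fit_result_to_json(fit: FitResult) -> dict:
    return {
        "params": dataclasses.asdict(fit.params),
        "log_likelihood": fit.log_likelihood,
        "n_params": fit.n_params,
        "n_choices": fit.n_choices,
        "bic": fit.bic,
        "n_restarts": fit.n_restarts,
        "converged": fit.converged,
        "seed": fit.seed,
        "submodel": fit.submodel,
        "lookahead_n": fit.lookahead_n,
    }


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    try:
        import yaml

        return yaml.safe_load(text)
    except ImportError:  # pragma: no cover
        return json.loads(text)


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the requested stages and return the artifact manifest."""
    out = Path(out_dir or config.get("out_dir", "foragekit_out"))
    out.mkdir(parents=True, exist_ok=True)
    global_seed = int(config.get("seed", 0))
    stages = config.get("stages", ["simulate", "fit", "summarize"])
    artifacts: dict[str, str] = {}

    def register(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = file_sha256(path)

    session: SessionData | None = None
    fit: FitResult | None = None

    if "simulate" in stages:
        sim = config.get("simulate", {})
        agent_cfg = sim.get("agent", {})
        params = params_from_config(sim.get("params", {}))
        agent = AgentSpec(
            kind=agent_cfg.get("kind", "model"),
            params=params,
            effector=agent_cfg.get("effector", "hand"),
            time_budget=float(agent_cfg.get("time_budget", 3.25)),
            time_noise_sd=float(agent_cfg.get("time_noise_sd", 0.0)),
            constrained=bool(agent_cfg.get("constrained", False)),
        )
        mm = default_movement_model(agent.effector)
        session = generate_session(
            agent,
            mm,
            trials_per_condition=int(sim.get("trials_per_condition", 50)),
            seed=seed_for(global_seed, "simulate"),
        )
        spath = out / "session.jsonl"
        write_session(session, spath)
        register(spath)
        log.info("simulate: wrote %s (%d trials)", spath, session.n_trials())
    elif "session" in config:
        session = read_session(config["session"])

    if session is None:
        raise ValueError("no session available: add a 'simulate' stage or 'session' path")

    if "fit_mt" in stages:
        records = harvest_movement_records(session)
        mt = fit_movement_time(records, session.effector)
        mpath = out / "movement_time.json"
        mpath.write_text(
            json.dumps(
                {
                    "effector": mt.effector,
                    "slope_s_per_m": {f"{r*1000:g}": v for r, v in mt.slope_by_radius.items()},
                    "intercept_s": {f"{r*1000:g}": v for r, v in mt.intercept_by_radius.items()},
                },
                indent=2,
            )
        )
        register(mpath)

    if "fit" in stages:
        fcfg = config.get("fit", {})
        fit = fit_session(
            session,
            lookahead_n=int(fcfg.get("lookahead_n", 1)),
            submodel=fcfg.get("submodel", "full"),
            n_restarts=int(fcfg.get("n_restarts", 10)),
            seed=seed_for(global_seed, "fit"),
            maxfev=int(fcfg.get("maxfev", 5000)),
            min_choices=int(fcfg.get("min_choices", 50)),
        )
        fpath = out / "fit.json"
        fpath.write_text(json.dumps(fit_result_to_json(fit), indent=2))
        register(fpath)
        log.info("fit: logL=%.2f bic=%.2f", fit.log_likelihood, fit.bic)

    if "compare" in stages:
        ccfg = config.get("compare", {})
        if ccfg.get("submodels", True):
            table = compare_submodels(
                session,
                lookahead_n=int(ccfg.get("lookahead_n", 1)),
                n_restarts=int(ccfg.get("n_restarts", 10)),
                seed=seed_for(global_seed, "compare_submodels"),
                maxfev=int(ccfg.get("maxfev", 5000)),
                min_choices=int(ccfg.get("min_choices", 50)),
            )
            cpath = out / "compare_submodels.csv"
            table.to_frame().to_csv(cpath, index=False)
            register(cpath)
        depths = ccfg.get("lookaheads")
        if depths:
            table = compare_lookaheads(
                session,
                n_range=[int(d) for d in depths],
                n_restarts=int(ccfg.get("n_restarts", 10)),
                seed=seed_for(global_seed, "compare_lookaheads"),
                maxfev=int(ccfg.get("maxfev", 5000)),
                min_choices=int(ccfg.get("min_choices", 50)),
            )
            cpath = out / "compare_lookaheads.csv"
            table.to_frame().to_csv(cpath, index=False)
            register(cpath)

    if "plan" in stages:
        planner = planner_session_for(session)
        ppath = out / "planner_session.jsonl"
        write_session(planner, ppath)
        register(ppath)
        pts, cts, excluded = efficiency_ratios(session, planner)
        epath = out / "efficiency.json"
        epath.write_text(
            json.dumps(
                {"points_ratio": pts, "count_ratio": cts,
                 "excluded_trials": excluded},
                indent=2,
            )
        )
        register(epath)

    if "summarize" in stages:
        scfg = config.get("summarize", {})
        if fit is not None:
            diag = selection_diagnostics(session, fit)
            dpath = out / "selection_diagnostics.csv"
            diag.to_csv(dpath, index=False)
            register(dpath)
        props = selection_proportions(session)
        ppath = out / "selection_proportions.csv"
        props.to_csv(ppath, index=False)
        register(ppath)
        hist = distance_distribution(
            session, bin_width=float(scfg.get("bin_width", 0.015))
        )
        hpath = out / "distance_histogram.csv"
        import pandas as pd

        pd.DataFrame(
            {"bin_left_m": hist.bin_edges[:-1], "count": hist.counts}
        ).to_csv(hpath, index=False)
        register(hpath)
        if session.constrained:
            ranking = path_ranking(session)
            rpath = out / "path_ranking.csv"
            ranking.to_frame().to_csv(rpath, index=False)
            register(rpath)

    from importlib.metadata import version

    try:
        pkg_version = version("foragekit")
    except Exception:  # pragma: no cover
        pkg_version = "unknown"
    manifest = {
        "config": config,
        "seed": global_seed,
        "package_version": pkg_version,
        "artifacts": artifacts,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
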