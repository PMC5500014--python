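"""Maximum-likelihood fitting, BIC, and model-comparison grids.

Fitting uses derivative-free Nelder-Mead simplex search with multiple
random restarts.  ``beta`` and ``gamma`` are optimized on a log scale
(keeping them positive); ``w1``, ``w2`` and the look-ahead weights are
unconstrained.  In the submodel without the reward-rate term, ``beta`` is
fixed at 1 because only the products ``beta*w1`` and ``beta*w2`` would be
identified; the free-parameter count k reflects this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .choice import (
    ChoiceModelParams,
    SessionData,
    SessionLikelihood,
)
from .exceptions import DegenerateWeightsError, FitError

SUBMODELS = ("full", "no_reward_rate", "no_distance", "no_size")

#: Initial-point sampling ranges for random restarts.
INIT_RANGES = {
    "log10_beta": (-2.5, -0.5),
    "log_gamma": (math.log(0.3), math.log(3.0)),
    "w1": (-200.0, 1000.0),
    "w2": (-1000.0, 3000.0),
    "lambda": (0.0, 1.0),
}

#: Reference synthetic-data generator used in recovery studies.
REFERENCE_GENERATOR = ChoiceModelParams(
    beta=0.05, w1=500.0, gamma=1.0, w2=1000.0, lookahead_n=1
)


def free_parameter_count(params: ChoiceModelParams) -> int:
    """Number of free parameters: beta (unless the reward-rate term is
    removed), w1+gamma (distance), w2 (size), plus one lambda per
    look-ahead step beyond the first."""
    k = params.lookahead_n - 1
    if params.include_reward_rate:
        k += 1  # beta
    if params.include_distance:
        k += 2  # w1, gamma
    if params.include_size:
        k += 1  # w2
    return k


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, ``-2*logL + k*ln(N)`` (lower is better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * log_likelihood + k * math.log(n)


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params: ChoiceModelParams
    log_likelihood: float
    n_params: int
    n_choices: int
    bic: float
    n_restarts: int
    converged: bool
    seed: int | None

    @property
    def submodel(self) -> str:
        return self.params.submodel

    @property
    def lookahead_n(self) -> int:
        return self.params.lookahead_n


@dataclass
class ComparisonRow:
    lookahead_n: int
    submodel: str
    fit: FitResult | None
    delta_bic: float | None
    error: str | None = None


@dataclass
class ComparisonTable:
    rows: list[ComparisonRow]

    def best(self) -> ComparisonRow:
        ok = [r for r in self.rows if r.fit is not None]
        if not ok:
            raise FitError("no successful fits in comparison table")
        return min(ok, key=lambda r: r.fit.bic)

    def to_frame(self):
        import pandas as pd

        recs = []
        for r in self.rows:
            rec = {
                "lookahead_n": r.lookahead_n,
                "submodel": r.submodel,
                "delta_bic": r.delta_bic,
                "error": r.error,
            }
            if r.fit is not None:
                rec.update(
                    log_likelihood=r.fit.log_likelihood,
                    k=r.fit.n_params,
                    n_choices=r.fit.n_choices,
                    bic=r.fit.bic,
                    converged=r.fit.converged,
                    beta=r.fit.params.beta,
                    w1=r.fit.params.w1,
                    gamma=r.fit.params.gamma,
                    w2=r.fit.params.w2,
                    lambdas=";".join(f"{l:g}" for l in r.fit.params.lambdas),
                )
            recs.append(rec)
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------


def _template(lookahead_n: int, submodel: str) -> ChoiceModelParams:
    if submodel not in SUBMODELS:
        raise ValueError(f"unknown submodel {submodel!r}; expected {SUBMODELS}")
    return ChoiceModelParams(
        beta=1.0,
        w1=0.0,
        gamma=1.0,
        w2=0.0,
        lambdas=(0.0,) * (lookahead_n - 1),
        lookahead_n=lookahead_n,
        include_reward_rate=submodel != "no_reward_rate",
        include_distance=submodel != "no_distance",
        include_size=submodel != "no_size",
    )


def _pack(params: ChoiceModelParams) -> np.ndarray:
    x = []
    if params.include_reward_rate:
        x.append(math.log(max(params.beta, 1e-12)))
    if params.include_distance:
        x.append(params.w1)
        x.append(math.log(params.gamma))
    if params.include_size:
        x.append(params.w2)
    x.extend(params.lambdas)
    return np.asarray(x, dtype=float)


def _unpack(x: np.ndarray, template: ChoiceModelParams) -> ChoiceModelParams:
    i = 0
    beta = 1.0
    if template.include_reward_rate:
        beta = math.exp(x[i])
        i += 1
    w1, gamma = 0.0, 1.0
    if template.include_distance:
        w1 = float(x[i])
        gamma = math.exp(x[i + 1])
        i += 2
    w2 = 0.0
    if template.include_size:
        w2 = float(x[i])
        i += 1
    lambdas = tuple(float(v) for v in x[i:])
    return replace(
        template, beta=beta, w1=w1, gamma=gamma, w2=w2, lambdas=lambdas
    )


def _draw_initial(template: ChoiceModelParams, rng: np.random.Generator) -> np.ndarray:
    x = []
    if template.include_reward_rate:
        lo, hi = INIT_RANGES["log10_beta"]
        x.append(rng.uniform(lo, hi) * math.log(10.0))
    if template.include_distance:
        x.append(rng.uniform(*INIT_RANGES["w1"]))
        x.append(rng.uniform(*INIT_RANGES["log_gamma"]))
    if template.include_size:
        x.append(rng.uniform(*INIT_RANGES["w2"]))
    x.extend(
        rng.uniform(*INIT_RANGES["lambda"]) for _ in range(template.lookahead_n - 1)
    )
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_session(
    session: SessionData,
    lookahead_n: int = 1,
    submodel: str = "full",
    n_restarts: int = 10,
    seed: int | None = None,
    maxfev: int = 5000,
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    min_choices: int = 50,
    extra_inits: list[ChoiceModelParams] | None = None,
) -> FitResult:
    """Maximize the session log-likelihood over the free parameters.

    Runs ``n_restarts`` Nelder-Mead searches from random initial points
    (plus any ``extra_inits``) and returns the best.  Deterministic for a
    fixed ``seed``.
    """
    template = _template(lookahead_n, submodel)
    lik = SessionLikelihood(session, lookahead_n)
    if lik.n_choices < min_choices:
        raise ValueError(
            f"session has {lik.n_choices} scored choices; "
            f"floor is {min_choices} (set min_choices to override)"
        )

    def negll(x: np.ndarray) -> float:
        try:
            return -lik(_unpack(x, template))
        except (OverflowError, FloatingPointError):
            return np.inf

    rng = np.random.default_rng(seed)
    starts = [_draw_initial(template, rng) for _ in range(n_restarts)]
    for p in extra_inits or []:
        starts.append(_pack(replace(
            p,
            lambdas=tuple(p.lambdas) + (0.0,) * (lookahead_n - 1 - len(p.lambdas)),
            lookahead_n=lookahead_n,
            include_reward_rate=template.include_reward_rate,
            include_distance=template.include_distance,
            include_size=template.include_size,
        )))

    best = None
    best_success = False
    failures = []
    for x0 in starts:
        try:
            res = optimize.minimize(
                negll,
                x0,
                method="Nelder-Mead",
                options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol},
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective at optimum")
            continue
        if best is None or res.fun < best.fun:
            best = res
            best_success = bool(res.success)
    if best is None:
        raise FitError(
            f"all {len(starts)} restarts failed: {failures[:3]}"
        )

    params = _unpack(best.x, template)
    ll = -float(best.fun)
    k = free_parameter_count(params)
    return FitResult(
        params=params,
        log_likelihood=ll,
        n_params=k,
        n_choices=lik.n_choices,
        bic=bic(ll, k, lik.n_choices),
        n_restarts=len(starts),
        converged=best_success,
        seed=seed,
    )


def _as_full_init(fit: FitResult) -> ChoiceModelParams:
    """Map a submodel optimum into the full parameter space (removed
    components zeroed), so the full fit can start from it."""
    p = fit.params
    return ChoiceModelParams(
        beta=p.beta if p.include_reward_rate else 1.0,
        w1=p.w1 if p.include_distance else 0.0,
        gamma=p.gamma if p.include_distance else 1.0,
        w2=p.w2 if p.include_size else 0.0,
        lambdas=p.lambdas,
        lookahead_n=p.lookahead_n,
    )


def compare_submodels(
    session: SessionData,
    lookahead_n: int = 1,
    n_restarts: int = 10,
    seed: int | None = None,
    **fit_kwargs,
) -> ComparisonTable:
    """Fit the full model and the three single-factor-removed submodels.

    The full fit additionally starts from each submodel's optimum (with
    the removed component zeroed), which guarantees the nesting property
    logL(full) >= logL(submodel) up to optimizer tolerance.  ``delta_bic``
    is reported relative to the full model.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(4)]
    rows: list[ComparisonRow] = []
    sub_fits: list[FitResult] = []
    for label, s in zip(SUBMODELS[1:], seeds[1:]):
        try:
            fit = fit_session(
                session, lookahead_n, label, n_restarts, s, **fit_kwargs
            )
            sub_fits.append(fit)
            rows.append(ComparisonRow(lookahead_n, label, fit, None))
        except FitError as exc:
            rows.append(ComparisonRow(lookahead_n, label, None, None, str(exc)))
    full = fit_session(
        session,
        lookahead_n,
        "full",
        n_restarts,
        seeds[0],
        extra_inits=[_as_full_init(f) for f in sub_fits],
        **fit_kwargs,
    )
    rows.insert(0, ComparisonRow(lookahead_n, "full", full, 0.0))
    for r in rows[1:]:
        if r.fit is not None:
            r.delta_bic = r.fit.bic - full.bic
    return ComparisonTable(rows)


def compare_lookaheads(
    session: SessionData,
    n_range=range(1, 6),
    n_restarts: int = 10,
    seed: int | None = None,
    **fit_kwargs,
) -> ComparisonTable:
    """Fit the full model at each look-ahead depth.

    Each depth beyond the smallest also starts from the previous depth's
    optimum with the new look-ahead weight at zero.  ``delta_bic`` is
    relative to the shallowest depth in ``n_range``.
    """
    depths = sorted(n_range)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(len(depths))]
    rows: list[ComparisonRow] = []
    prev: FitResult | None = None
    for depth, s in zip(depths, seeds):
        extra = [prev.params] if prev is not None else []
        try:
            fit = fit_session(
                session, depth, "full", n_restarts, s, extra_inits=extra,
                **fit_kwargs,
            )
            rows.append(ComparisonRow(depth, "full", fit, None))
            prev = fit
        except FitError as exc:
            rows.append(ComparisonRow(depth, "full", None, None, str(exc)))
    ref = next((r.fit.bic for r in rows if r.fit is not None), None)
    for r in rows:
        if r.fit is not None and ref is not None:
            r.delta_bic = r.fit.bic - ref
    return ComparisonTable(rows)


def normalized_lookahead_weights(fit: FitResult | ChoiceModelParams) -> np.ndarray:
    """Step weights ``(1, lambda_1, ...)`` normalized to sum to one."""
    params = fit.params if isinstance(fit, FitResult) else fit
    w = params.step_weights()
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightsError(
            f"look-ahead weights sum to {total}; cannot normalize"
        )
    return w / total
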