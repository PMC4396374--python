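"""Sequential Monte Carlo ABC over pathway parameters.

The inference asks which kinetic parameters let a pathway variant
reproduce the stereotyped neural-tube behaviour: strong induction,
sensitivity to the two Shh ramps, and adaptation, as encoded by the
integer distance of :mod:`shhadapt.adaptation_metrics`.  Parameters are
drawn from independent log-uniform priors (four orders of magnitude by
default), and populations of weighted particles are filtered through a
strictly decreasing ladder of distance thresholds (epsilon) until the
zero-distance population is filled or the simulation budget runs out.

Weights follow the standard SMC-ABC importance scheme: uniform at
generation zero, then prior density over the kernel mixture of the
previous population.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adaptation_metrics import (
    AdaptationMetrics,
    compute_metrics,
    required_readouts,
    total_distance,
)
from .pathway_models import ModelVariant, ParameterSet, load_fig7_parameters
from .stimulation_protocols import (
    InputSignal,
    SolverError,
    build_ramp_inputs,
    pre_equilibrate,
    run_protocol,
)

__all__ = [
    "PriorSpec",
    "Particle",
    "Population",
    "default_prior",
    "sample_prior",
    "evaluate_particle",
    "run_abc_smc",
    "posterior_summaries",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent log-uniform priors plus clamped (fixed) parameters.

    ``log_uniform`` maps free parameter names to (lo, hi) bounds with
    lo > 0; ``fixed`` holds every remaining model parameter at a constant.
    The sampling dimension is ``len(log_uniform)``.
    """

    log_uniform: dict[str, tuple[float, float]]
    fixed: dict[str, float]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.log_uniform.items():
            if not (0 < lo < hi):
                raise ValueError(f"prior for {name}: need 0 < lo < hi, got [{lo}, {hi}]")

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(self.log_uniform)

    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.log10([self.log_uniform[n][0] for n in self.free_names])
        hi = np.log10([self.log_uniform[n][1] for n in self.free_names])
        return lo, hi

    def to_dict(self) -> dict:
        return {
            "log_uniform": {k: list(v) for k, v in self.log_uniform.items()},
            "fixed": dict(self.fixed),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PriorSpec":
        return cls(
            log_uniform={k: (float(v[0]), float(v[1])) for k, v in d["log_uniform"].items()},
            fixed={k: float(v) for k, v in d["fixed"].items()},
        )

    @classmethod
    def from_json(cls, path) -> "PriorSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# Parameters that remain kinetically meaningful in each variant.  X-related
# rates are clamped where X is removed; Gli-isoform degradation rates are
# tied where the variant shares them; the ptch1 Gli-affinity is clamped
# where ptch1 transcription is constant.
_COMMON_FREE = (
    "tr_ptc",
    "tr_gliFL",
    "tl_Ptc",
    "tl_GliFL",
    "deg_ptc",
    "deg_gliFL",
    "deg_Ptc",
    "deg_GliFL",
    "conv_GliA",
    "conv_GliR",
    "act_Ptc",
    "k_ShhPtc",
    "Km_Ptch1",
    "K_Pol_ptc",
    "K_Pol_gli",
    "K_Pol_gfp",
    "K_Gli_gfp",
    "c_GliA",
)
_X_FREE = ("tr_x", "tl_X", "deg_x", "deg_X", "K_X_gli", "K_Gli_x", "K_Pol_x")


def default_prior(
    variant: ModelVariant, span: float = 100.0
) -> PriorSpec:
    """Log-uniform priors spanning four orders of magnitude per parameter.

    Ranges are centred (in log space) on the published reference set where
    a value exists, [1e-2, 1e2] otherwise; the activator cooperativity is
    bounded below by 1 so Gli-bound polymerase recruitment is never
    repressive.  In the neural-tube screen X acts as a repressor, so c_X
    is clamped at 0.
    """
    if not isinstance(variant, ModelVariant):
        variant = ModelVariant(variant)
    ref = load_fig7_parameters().to_dict()

    free = list(_COMMON_FREE)
    if variant.has_x:
        free += list(_X_FREE)
    if variant.ptc_regulated:
        free.append("K_Gli_ptc")
    if not variant.shared_gli_degradation:
        free += ["deg_GliA", "deg_GliR"]

    log_uniform: dict[str, tuple[float, float]] = {}
    for name in free:
        v = ref.get(name)
        if v is None or v <= 0:
            lo, hi = 1.0 / span, span
        else:
            lo, hi = v / span, v * span
        if name == "c_GliA":
            lo = max(lo, 1.0)
            hi = max(hi, lo * span * span)
        log_uniform[name] = (lo, hi)

    fixed = {k: v for k, v in ref.items() if k not in log_uniform}
    fixed["c_X"] = 0.0
    fixed["Pol"] = 1.0
    fixed["c_GliR"] = 0.0
    if not variant.has_x:
        fixed["tr_x"] = 0.0
        fixed["tl_X"] = 0.0
    return PriorSpec(log_uniform=log_uniform, fixed=fixed)


def _params_from_vector(
    log10_vec: np.ndarray, prior: PriorSpec, variant: ModelVariant
) -> ParameterSet:
    d = dict(prior.fixed)
    d.update({n: 10.0 ** v for n, v in zip(prior.free_names, log10_vec)})
    return ParameterSet.from_dict(d).for_variant(variant)


def sample_prior(prior: PriorSpec, rng: np.random.Generator) -> ParameterSet:
    """One independent draw: uniform in log10 space over each free range,
    fixed entries passed through unchanged."""
    lo, hi = prior.log_bounds()
    vec = rng.uniform(lo, hi)
    d = dict(prior.fixed)
    d.update({n: 10.0 ** v for n, v in zip(prior.free_names, vec)})
    return ParameterSet.from_dict(d)


@dataclass
class Particle:
    params: ParameterSet
    distance: float  # integer-valued, inf on solver failure
    weight: float
    log10_free: np.ndarray  # free-parameter vector in log10 space
    metrics: dict[str, AdaptationMetrics] | None = None

    def to_record(self, prior: PriorSpec) -> dict:
        return {
            "parameters": self.params.to_dict(),
            "distance": None if math.isinf(self.distance) else int(self.distance),
            "weight": float(self.weight),
            "metrics": {k: m.to_dict() for k, m in self.metrics.items()}
            if self.metrics
            else None,
        }


@dataclass
class Population:
    particles: list[Particle]
    epsilon: float
    generation: int
    seed: int
    n_simulations: int = 0
    acceptance_rate: float = 1.0
    complete: bool = True
    diagnostic: str = ""

    @property
    def distances(self) -> np.ndarray:
        return np.array([p.distance for p in self.particles])

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.particles])

    def best(self) -> Particle:
        return min(self.particles, key=lambda p: p.distance)


def evaluate_particle(
    params: ParameterSet,
    variant: ModelVariant,
    signal1: InputSignal,
    signal2: InputSignal,
    t_pre: float = 300.0,
    t_stim: float = 70.0,
    grid_dt: float = 0.5,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    glia_requirements: Mapping[str, float] | None = None,
) -> tuple[float, dict[str, AdaptationMetrics] | None]:
    """Simulate both ramps for one parameter set and score the distance.

    Pre-equilibration (no ligand) is shared between the two stimulations.
    A solver failure yields an infinite distance rather than an exception,
    so the SMC loop can simply discard the particle.
    """
    try:
        pre, _ = pre_equilibrate(params, variant, t_pre, rtol, atol)
        res1 = run_protocol(
            params, variant, signal1, t_pre, t_stim, grid_dt, rtol, atol, pre_state=pre
        )
        res2 = run_protocol(
            params, variant, signal2, t_pre, t_stim, grid_dt, rtol, atol, pre_state=pre
        )
    except (SolverError, FloatingPointError, OverflowError):
        return math.inf, None
    metrics: dict[str, AdaptationMetrics] = {}
    for readout in required_readouts(variant):
        metrics[readout] = compute_metrics(
            (res1.times, res1.series(readout)),
            (res2.times, res2.series(readout)),
            basal=res1.basal(readout),
        )
    score = total_distance(metrics, variant, glia_requirements)
    return float(score.total), metrics


def _kernel_scales(pop: Population, n_dim: int) -> np.ndarray:
    """Component-wise uniform-kernel half-widths: half the population range
    of each free parameter in log10 space (floored to keep the kernel
    proper when a dimension has collapsed)."""
    vecs = np.array([p.log10_free for p in pop.particles])
    span = vecs.max(axis=0) - vecs.min(axis=0)
    return np.maximum(0.5 * span, 1e-3)


def run_abc_smc(
    variant: ModelVariant,
    prior: PriorSpec | None = None,
    n_particles: int = 128,
    epsilon_schedule: Sequence[float] | str = "auto",
    max_generations: int = 30,
    seed: int = 0,
    max_simulations: int = 60_000,
    signal1: InputSignal | None = None,
    signal2: InputSignal | None = None,
    t_pre: float = 300.0,
    glia_requirements: Mapping[str, float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    verbose: bool = False,
) -> list[Population]:
    """SMC-ABC against the adaptation distance; returns one Population per
    generation (epsilon strictly decreasing, ending at 0 when reached).

    Generation 0 is plain rejection sampling at the initial epsilon
    (infinite under the automatic schedule, so it equals the prior).
    Later generations resample the previous population by weight, perturb
    component-wise with a uniform log10 kernel, and accept at the current
    epsilon.  The automatic schedule sets the next epsilon to the floor of
    the current population's median distance (at least one less than the
    current epsilon).  If the simulation budget is exhausted or acceptance
    stalls, the last, possibly partial, population is returned with its
    ``complete`` flag cleared and a diagnostic message.
    """
    if not isinstance(variant, ModelVariant):
        variant = ModelVariant(variant)
    if n_particles < 2:
        raise ValueError("n_particles must be >= 2")
    if prior is None:
        prior = default_prior(variant)
    if signal1 is None or signal2 is None:
        signal1, signal2 = build_ramp_inputs(1.0, 1.0)

    rng = np.random.default_rng(seed)
    lo, hi = prior.log_bounds()
    n_dim = len(prior.free_names)
    eval_kw = dict(
        t_pre=t_pre, rtol=rtol, atol=atol, glia_requirements=glia_requirements
    )

    if epsilon_schedule == "auto":
        schedule = None
        eps = math.inf
    else:
        schedule = list(epsilon_schedule)
        eps = schedule.pop(0)

    populations: list[Population] = []
    n_sims = 0
    generation = 0
    while generation < max_generations:
        particles: list[Particle] = []
        attempts = 0
        prev = populations[-1] if populations else None
        if prev is not None:
            scales = _kernel_scales(prev, n_dim)
            prev_vecs = np.array([p.log10_free for p in prev.particles])
            prev_w = prev.weights
        budget_hit = False
        # cap attempts so a hopeless epsilon cannot spin forever
        max_attempts = max(200 * n_particles, 2000)
        while len(particles) < n_particles:
            if n_sims >= max_simulations or attempts >= max_attempts:
                budget_hit = True
                break
            if prev is None:
                vec = rng.uniform(lo, hi)
            else:
                j = rng.choice(len(prev_vecs), p=prev_w)
                for _ in range(100):
                    vec = prev_vecs[j] + rng.uniform(-scales, scales)
                    if np.all(vec >= lo) and np.all(vec <= hi):
                        break
                else:  # pathological corner: fall back to the source particle
                    vec = prev_vecs[j].copy()
            params = _params_from_vector(vec, prior, variant)
            attempts += 1
            n_sims += 1
            dist, metrics = evaluate_particle(
                params, variant, signal1, signal2, **eval_kw
            )
            if dist <= eps:
                particles.append(
                    Particle(params, dist, 0.0, vec.copy(), metrics)
                )
        if not particles:
            populations.append(
                Population(
                    [], eps, generation, seed, n_sims, 0.0, False,
                    "no particle accepted before budget exhaustion",
                )
            )
            break

        # importance weights (uniform log-prior => constant numerator)
        if prev is None:
            w = np.full(len(particles), 1.0 / len(particles))
        else:
            w = np.empty(len(particles))
            inv_vol = 1.0 / np.prod(2.0 * scales)
            for i, p in enumerate(particles):
                diff = np.abs(prev_vecs - p.log10_free)
                inside = np.all(diff <= scales, axis=1)
                denom = float(np.sum(prev_w[inside])) * inv_vol
                w[i] = 1.0 / denom if denom > 0 else 0.0
            if w.sum() == 0:
                w[:] = 1.0
            w /= w.sum()
        for p, wi in zip(particles, w):
            p.weight = float(wi)

        pop = Population(
            particles,
            eps,
            generation,
            seed,
            n_sims,
            acceptance_rate=len(particles) / max(attempts, 1),
            complete=not budget_hit,
            diagnostic="simulation budget exhausted" if budget_hit else "",
        )
        populations.append(pop)
        if verbose:
            d = pop.distances
            print(
                f"gen {generation}: eps={eps} accepted={len(particles)} "
                f"acc_rate={pop.acceptance_rate:.3g} sims={n_sims} "
                f"min={d.min():.0f} median={np.median(d):.0f}"
            )
        if budget_hit or eps == 0:
            break
        # next epsilon
        if schedule is None:
            med = float(np.median(pop.distances[np.isfinite(pop.distances)]))
            nxt = math.floor(med)
            if math.isfinite(eps):
                nxt = min(nxt, int(eps) - 1)
            eps = max(nxt, 0)
        else:
            if not schedule:
                break
            nxt = schedule.pop(0)
            if math.isfinite(eps) and nxt >= eps:
                raise ValueError("epsilon schedule must be strictly decreasing")
            eps = nxt
        generation += 1
    return populations


def _weighted_quantile(
    values: np.ndarray, weights: np.ndarray, qs: Sequence[float]
) -> np.ndarray:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(qs, cw, v)


def posterior_summaries(
    population: Population, prior: PriorSpec
) -> pd.DataFrame:
    """Weighted marginal quantiles (2.5/25/50/75/97.5%) per free parameter,
    computed on the log10 scale, alongside the prior bounds."""
    if not population.particles:
        raise ValueError("empty population")
    w = population.weights
    if w.sum() <= 0:
        raise ValueError("population has zero total weight")
    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    vecs = np.array([p.log10_free for p in population.particles])
    rows = []
    lo, hi = prior.log_bounds()
    for d, name in enumerate(prior.free_names):
        quant = _weighted_quantile(vecs[:, d], w, qs)
        row = {"parameter": name, "prior_log10_lo": lo[d], "prior_log10_hi": hi[d]}
        row.update({f"q{q*100:g}_log10": float(x) for q, x in zip(qs, quant)})
        row["median"] = float(10.0 ** quant[2])
        rows.append(row)
    return pd.DataFrame(rows)


def write_population_jsonl(population: Population, prior: PriorSpec, path) -> None:
    with open(path, "w") as fh:
        for p in population.particles:
            fh.write(json.dumps(p.to_record(prior)) + "\n")
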