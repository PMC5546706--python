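"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator forward-simulates the same protein balance the analysis
inverts, dP/dt = R(t) S_g(t) - (d + gamma(t)) P(t), with known ground truth:
a dose condition fixes the growth and global-synthesis shapes, cluster
templates fix staggered pulse windows and signs, per-gene turnover and
baseline levels are drawn from documented distributions, and measurement
noise is multiplicative log-normal on P(t).

Conditions emulated
-------------------
shmoo (high pheromone): growth rate drops smoothly to half its pre-stimulus
value within 60 min; global synthesis rises transiently (~1.2x within 2 h)
then declines to ~60% of baseline.

elongation (intermediate pheromone): growth slows hyperbolically
(gamma = gamma0 * t0 / (t0 + t), the dilution law of linear mass
accumulation); global synthesis fluctuates around baseline with a mild
prolonged increase.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import (DegradationTable, ExpressionSeries, GrowthProfile, TimeGrid,
                   ValidationError)
from .kinetics import GlobalSynthesisProfile, rescale_global, simulate_protein
from .psda import PulseRegulation, regulation_value


@dataclass(frozen=True)
class ClusterTemplate:
    """One temporal regulation mode: a window, a direction, a fold range."""

    name: str
    fraction: float           # fraction of the cohort drawn from this mode
    sign: str                 # "activated" | "inhibited"
    t_on: float               # nominal event start, minutes
    t_off: float              # nominal event end, minutes
    fold_range: tuple[float, float]   # |log2 fold| sampled uniformly in between
    jitter: float = 8.0       # sd of per-gene window jitter, minutes


#: Default templates, staggered like the six temporal modes seen in shmooing
#: cells: translation machinery repressed early then recovering (T1), stress
#: genes transiently induced (T2), MAPK components next (T3), mating/fusion
#: genes later and prolonged (T4), cell-cycle genes repressed with a ~2 h lag
#: (T5), chromatin remodellers very late (T6).
DEFAULT_SHMOO_TEMPLATES: tuple[ClusterTemplate, ...] = (
    ClusterTemplate("T1", 0.12, "inhibited", 5.0, 130.0, (1.0, 2.0)),
    ClusterTemplate("T2", 0.10, "activated", 30.0, 110.0, (1.0, 2.0)),
    ClusterTemplate("T3", 0.10, "activated", 65.0, 170.0, (1.0, 2.0)),
    ClusterTemplate("T4", 0.12, "activated", 105.0, 310.0, (1.0, 2.0)),
    ClusterTemplate("T5", 0.10, "inhibited", 150.0, 340.0, (1.0, 2.0)),
    ClusterTemplate("T6", 0.18, "activated", 210.0, 360.0, (1.0, 2.0)),
)


@dataclass
class GeneratorConfig:
    """Study-scale defaults: 195 genes on a 5-min grid over 6 hours."""

    n_genes: int = 195
    t_start: float = 0.0
    t_end: float = 360.0
    step: float = 5.0
    condition: str = "shmoo"
    templates: tuple[ClusterTemplate, ...] = DEFAULT_SHMOO_TEMPLATES
    gamma0: float = 0.006           # pre-stimulus dilution rate, 1/min
    t0_elongation: float = 120.0    # hyperbolic slowdown timescale, minutes
    noise_cv: float = 0.05          # log-normal multiplicative noise CV
    half_life_median: float = 43.0  # minutes
    half_life_sigma: float = 0.5    # log-sd of the half-life distribution
    p0_median: float = 100.0        # a.u.
    p0_sigma: float = 0.5
    edge_width: float = 10.0        # minutes, pulse ramp width
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(t.fraction for t in self.templates) > 1.0 + 1e-9:
            raise ValidationError("template fractions must sum to <= 1")
        if self.noise_cv < 0 or self.gamma0 < 0:
            raise ValidationError("rates and noise CV must be >= 0")
        if self.condition not in ("shmoo", "elongation"):
            raise ValidationError(f"unknown condition {self.condition!r}")

    def grid(self) -> TimeGrid:
        n = int(round((self.t_end - self.t_start) / self.step)) + 1
        return TimeGrid(self.t_start + self.step * np.arange(n))


@dataclass
class GeneTruth:
    pulse: PulseRegulation | None   # None for unregulated genes
    template: str | None
    d: float
    p0: float


@dataclass
class SyntheticDataset:
    expression: list[ExpressionSeries]
    growth: GrowthProfile
    degradation: DegradationTable
    global_profile: GlobalSynthesisProfile
    truth: dict[str, GeneTruth]
    config: GeneratorConfig

    def truth_json(self) -> str:
        payload = {}
        for g, t in self.truth.items():
            payload[g] = {
                "template": t.template, "d": t.d, "p0": t.p0,
                "pulse": None if t.pulse is None else {
                    "t_on": t.pulse.t_on, "t_off": t.pulse.t_off,
                    "fold": t.pulse.fold, "edge_width": t.pulse.edge_width},
            }
        return json.dumps({"config": {"n_genes": self.config.n_genes,
                                      "condition": self.config.condition,
                                      "seed": self.config.seed},
                           "genes": payload}, indent=1)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_growth(condition: str, grid: TimeGrid, gamma0: float = 0.006,
                t0: float = 120.0) -> GrowthProfile:
    """Condition-specific dilution-rate profile (deterministic).

    shmoo: gamma0 * (0.5 + 0.5 * sigma((30 - t)/8)) -- a smooth arrest that
    reaches half the pre-stimulus rate by 60 min and stays there.
    elongation: gamma0 * t0 / (t0 + t) -- hyperbolic decay, the dilution rate
    of a linearly accumulating cell mass.
    """
    t = np.maximum(grid.times, 0.0)
    if condition == "shmoo":
        gamma = gamma0 * (0.5 + 0.5 * _logistic((30.0 - t) / 8.0))
    elif condition == "elongation":
        gamma = gamma0 * t0 / (t0 + t)
    else:
        raise ValidationError(f"unknown condition {condition!r}")
    return GrowthProfile(grid, gamma)


def make_global_synthesis(condition: str, grid: TimeGrid,
                          peak: float = 1.2, floor: float = 0.6
                          ) -> GlobalSynthesisProfile:
    """Condition-specific normalized global synthesis rate (deterministic).

    shmoo: a Gaussian bump (peak ~1.2x near 50 min) riding on a logistic
    decline to ~``floor`` of baseline after two hours.
    elongation: unit mean with smooth sinusoidal fluctuation and a mild
    prolonged ramp.
    """
    t = np.maximum(grid.times, 0.0)
    if condition == "shmoo":
        # the final division by s(0) rescales the nominal floor and peak, so
        # solve for effective parameters by fixed-point iteration (converges
        # in a couple of steps; floor and peak enter nearly linearly)
        floor_eff, peak_eff = floor, peak
        for _ in range(4):
            decline = floor_eff + (1.0 - floor_eff) * _logistic((160.0 - t) / 30.0)
            target_peak = peak_eff / (floor_eff + (1.0 - floor_eff) *
                                      _logistic((160.0 - 50.0) / 30.0))
            bump = 1.0 + (target_peak - 1.0) * np.exp(-((t - 50.0) / 40.0) ** 2)
            s = bump * decline
            s0 = s[grid.baseline_index]
            floor_eff *= (floor * s0) / s[-1] if s[-1] > 0 else 1.0
            peak_eff *= (peak * s0) / s.max()
    elif condition == "elongation":
        s = 1.0 + 0.08 * np.sin(2.0 * math.pi * t / 200.0) + 0.0004 * t
    else:
        raise ValidationError(f"unknown condition {condition!r}")
    s = s / s[grid.baseline_index]
    return GlobalSynthesisProfile(grid, s, provenance=f"synthetic:{condition}")


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a full cohort; bit-identical for a given config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    growth = make_growth(config.condition, grid, config.gamma0, config.t0_elongation)
    global_profile = make_global_synthesis(config.condition, grid)

    # deterministic template allocation by rounded counts, remainder unregulated
    counts = [int(round(t.fraction * config.n_genes)) for t in config.templates]
    assignments: list[ClusterTemplate | None] = []
    for tmpl, c in zip(config.templates, counts):
        assignments.extend([tmpl] * c)
    assignments.extend([None] * (config.n_genes - len(assignments)))
    if len(assignments) != config.n_genes:
        raise ValidationError("template fractions produce more genes than n_genes")

    # log-normal noise with the requested CV on the natural scale
    noise_sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))

    expression: list[ExpressionSeries] = []
    truth: dict[str, GeneTruth] = {}
    rates: dict[str, float] = {}
    for i, tmpl in enumerate(assignments):
        gene = f"G{i:04d}"
        half_life = config.half_life_median * rng.lognormal(0.0, config.half_life_sigma)
        d = math.log(2.0) / half_life
        p0 = config.p0_median * rng.lognormal(0.0, config.p0_sigma)
        pulse = None
        if tmpl is not None:
            t_on = tmpl.t_on + rng.normal(0.0, tmpl.jitter)
            t_off = tmpl.t_off + rng.normal(0.0, tmpl.jitter)
            t_on = float(np.clip(t_on, grid.times[0], grid.times[-1] - config.step))
            t_off = float(np.clip(t_off, t_on + config.step, grid.times[-1] + config.step))
            mag = rng.uniform(*tmpl.fold_range)
            fold = 2.0 ** (-mag if tmpl.sign == "inhibited" else mag)
            pulse = PulseRegulation(t_on, t_off, fold, config.edge_width)
        s_g = rescale_global(global_profile, p0, d, growth.baseline)
        alpha = s_g.copy()
        if pulse is not None:
            alpha = alpha * regulation_value(pulse, grid.times)
        clean = simulate_protein(alpha, growth, d, p0, gene_id=gene)
        values = clean.values
        if config.noise_cv > 0:
            values = values * rng.lognormal(-0.5 * noise_sigma ** 2, noise_sigma,
                                            size=len(grid))
        expression.append(ExpressionSeries(gene, grid, values))
        truth[gene] = GeneTruth(pulse, tmpl.name if tmpl else None, d, p0)
        rates[gene] = d
    degradation = DegradationTable(rates)
    return SyntheticDataset(expression, growth, degradation, global_profile,
                            truth, config)
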