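"""Protein life-cycle kinetics: synthesis-rate inversion and the global null.

The model is the mass-action protein balance

    dP/dt = alpha(t) - (d + gamma(t)) * P(t)

solved discretely on the measurement grid, so that the forward update

    P(t_{k+1}) = P(t_k) + dt_k * [alpha(t_k) - (d + gamma(t_k)) P(t_k)]

and the inversion

    alpha(t_k) = (P(t_{k+1}) - P(t_k)) / dt_k + (d + gamma(t_k)) P(t_k)

are exact mutual inverses. The "global null" replaces alpha(t) by a rescaled
condition-wide synthesis profile S_g(t) = p0 * (d + gamma0) * s_norm(t),
which makes the pre-stimulus level a steady state; the discrepancy between
this null and the observation is what the pulse-decoupling fit explains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import (DegradationTable, ExpressionSeries, GrowthProfile, TimeGrid,
                   ValidationError)

logger = logging.getLogger(__name__)

#: Relative floor applied to non-positive synthesis values when they are used
#: as a rate in forward simulation (raw negatives are kept for averaging).
SYNTHESIS_FLOOR_REL = 1e-6


@dataclass(frozen=True)
class SynthesisSeries:
    """Estimated synthesis rate alpha(t) on the first n-1 grid points."""

    gene_id: str
    grid: TimeGrid
    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "alpha", a)
        if a.shape != (len(self.grid) - 1,):
            raise ValidationError("alpha must live on the first n-1 grid points")
        if not np.all(np.isfinite(a)):
            raise ValidationError("non-finite synthesis values")

    @property
    def baseline(self) -> float:
        k = min(self.grid.baseline_index, self.alpha.size - 1)
        return float(self.alpha[k])


@dataclass(frozen=True)
class GlobalSynthesisProfile:
    """Normalized global synthesis rate s_norm(t); s_norm(baseline) = 1."""

    grid: TimeGrid
    s_norm: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        s = np.asarray(self.s_norm, dtype=float)
        object.__setattr__(self, "s_norm", s)
        if s.shape != (len(self.grid),):
            raise ValidationError("s_norm length != grid length")
        if not np.all(np.isfinite(s)) or np.any(s <= 0):
            raise ValidationError("s_norm must be finite and > 0")
        if abs(s[self.grid.baseline_index] - 1.0) > 1e-9:
            raise ValidationError("s_norm at baseline must equal 1")


def estimate_synthesis_rates(series: ExpressionSeries, growth: GrowthProfile,
                             d: float) -> SynthesisSeries:
    """Invert the discrete balance for alpha(t) by forward difference.

    Negative estimates are kept (they carry estimation noise that averaging
    must see) but a debug log flags them.
    """
    if series.grid != growth.grid:
        raise ValidationError("series and growth must share a grid")
    if d < 0:
        raise ValidationError("degradation rate must be >= 0")
    P = series.values
    dt = series.grid.dt
    alpha = np.diff(P) / dt + (d + growth.gamma[:-1]) * P[:-1]
    n_neg = int(np.sum(alpha < 0))
    if n_neg:
        logger.debug("gene %s: %d negative alpha estimates retained",
                     series.gene_id, n_neg)
    return SynthesisSeries(series.gene_id, series.grid, alpha)


def simulate_protein(alpha, growth: GrowthProfile, d: float, p0: float,
                     gene_id: str = "simulated") -> ExpressionSeries:
    """Forward-Euler integration of the protein balance on the grid.

    ``alpha`` may be length n-1 (interval rates) or length n (the last value
    is unused). Output is clamped at zero with a warning rather than going
    negative; a grid too coarse for the decay rate (dt*(d+gamma) >= 1) is a
    hard error since Euler is unstable there.
    """
    grid = growth.grid
    a = np.asarray(alpha, dtype=float)
    if a.shape == (len(grid),):
        a = a[:-1]
    if a.shape != (len(grid) - 1,):
        raise ValidationError("alpha length must be n or n-1 for an n-point grid")
    if p0 < 0:
        raise ValidationError("p0 must be >= 0")
    dt = grid.dt
    decay = dt * (d + growth.gamma[:-1])
    if np.any(decay >= 1.0):
        raise ValidationError("grid too coarse: dt*(d+gamma) >= 1 (Euler unstable)")
    P = np.empty(len(grid))
    P[0] = p0
    clamped = False
    for k in range(len(grid) - 1):
        nxt = P[k] + dt[k] * a[k] - decay[k] * P[k]
        if nxt < 0:
            nxt = 0.0
            clamped = True
        P[k + 1] = nxt
    if clamped:
        warnings.warn(f"{gene_id}: simulated trajectory clamped at 0", stacklevel=2)
    return ExpressionSeries(gene_id, grid, P)


def build_global_synthesis(all_series: list[SynthesisSeries],
                           mode: str = "reference_genes",
                           refs: list[str] | None = None,
                           baseline_window: int = 4) -> GlobalSynthesisProfile:
    """Average per-gene synthesis traces into one condition-wide profile.

    Each contributing alpha-trace is first divided by its own baseline
    (so highly expressed genes do not dominate), then genes are combined by
    mean (``reference_genes`` / ``all_mean``) or median (``median``); the
    result is renormalized so s_norm(baseline) = 1. The last grid point
    (where alpha is undefined) repeats the final value.

    Because the forward-difference inversion amplifies measurement noise,
    the per-gene baseline is the mean of alpha over the first few samples
    (through the pre-stimulus index, at least ``baseline_window`` points)
    rather than a single point; a one-point baseline makes the normalized
    traces heavy-tailed.
    """
    if mode == "reference_genes":
        if not refs:
            raise ValidationError("reference_genes mode requires a non-empty ref list")
        by_id = {s.gene_id: s for s in all_series}
        missing = [g for g in refs if g not in by_id]
        if missing:
            raise ValidationError(f"reference genes not available: {missing}")
        contributing = [by_id[g] for g in refs]
    elif mode in ("all_mean", "median"):
        contributing = list(all_series)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if not contributing:
        raise ValidationError("no synthesis series to average")
    grid = contributing[0].grid
    nb = max(grid.baseline_index + 1, baseline_window)
    normed = []
    for s in contributing:
        b = float(np.mean(s.alpha[:nb]))
        if b <= 0:
            logger.warning("gene %s: non-positive baseline synthesis, excluded from global",
                           s.gene_id)
            continue
        normed.append(s.alpha / b)
    if not normed:
        raise ValidationError("all candidate genes had zero baseline synthesis")
    stack = np.vstack(normed)
    prof = np.median(stack, axis=0) if mode == "median" else np.mean(stack, axis=0)
    prof = np.append(prof, prof[-1])  # extend to the full grid
    floor = SYNTHESIS_FLOOR_REL * max(abs(prof[grid.baseline_index]), 1.0)
    prof = np.maximum(prof, floor)
    prof = prof / prof[grid.baseline_index]
    provenance = ",".join(refs) if mode == "reference_genes" else f"{mode} of {len(normed)} genes"
    return GlobalSynthesisProfile(grid, prof, provenance)


def rescale_global(global_profile: GlobalSynthesisProfile, p0: float, d: float,
                   gamma0: float) -> np.ndarray:
    """Per-gene synthesis trace S_g(t) = p0*(d+gamma0)*s_norm(t).

    The factor makes the pre-stimulus protein level a steady state of the
    physiology-only model.
    """
    if p0 <= 0:
        raise ValidationError("p0 must be > 0 for global rescaling")
    return p0 * (d + gamma0) * global_profile.s_norm


def global_null_prediction(expr: list[ExpressionSeries], growth: GrowthProfile,
                           deg: DegradationTable,
                           global_profile: GlobalSynthesisProfile) -> list[ExpressionSeries]:
    """Simulate every gene under the physiology-only (no gene-specific) model."""
    out = []
    for s in expr:
        p0 = s.baseline
        if p0 == 0:
            logger.warning("gene %s: zero baseline, excluded from global-null analysis",
                           s.gene_id)
            continue
        d = deg.lookup(s.gene_id)
        s_g = rescale_global(global_profile, p0, d, growth.baseline)
        out.append(simulate_protein(s_g, growth, d, p0, gene_id=s.gene_id))
    return out


def peak_log2_fold_change(series: ExpressionSeries) -> float:
    """Signed peak |log2(P(t)/P(baseline))| over the time course.

    The default fold-change summary: robust to when the extremum occurs and
    symmetric for induction vs repression. Zero values are floored at a tiny
    fraction of baseline so the log is defined.
    """
    p0 = series.baseline
    if p0 <= 0:
        raise ValidationError(f"{series.gene_id}: non-positive baseline")
    v = np.maximum(series.values, 1e-9 * p0)
    lfc = np.log2(v / p0)
    return float(lfc[np.argmax(np.abs(lfc))])


def endpoint_log2_fold_change(series: ExpressionSeries) -> float:
    """log2 fold change at the final time point (alternative summary)."""
    p0 = series.baseline
    if p0 <= 0:
        raise ValidationError(f"{series.gene_id}: non-positive baseline")
    return float(np.log2(max(series.values[-1], 1e-9 * p0) / p0))


_FOLD_CHANGE = {"peak": peak_log2_fold_change, "endpoint": endpoint_log2_fold_change}


def fold_change_correlation(observed: list[ExpressionSeries],
                            predicted: list[ExpressionSeries],
                            definition: str = "peak") -> dict:
    """Pearson correlation of predicted vs observed per-gene fold changes.

    Returns {r, p, r2, n_genes, fold_change_definition}; r**2 is the variance
    in the observed fold changes explained by the physiology-only null.
    """
    pred_by_id = {s.gene_id: s for s in predicted}
    pairs = [(o, pred_by_id[o.gene_id]) for o in observed if o.gene_id in pred_by_id]
    if len(pairs) < 3:
        raise ValidationError("fold-change correlation needs >= 3 paired genes")
    fc = _FOLD_CHANGE[definition]
    obs = np.array([fc(o) for o, _ in pairs])
    prd = np.array([fc(p) for _, p in pairs])
    r, p = stats.pearsonr(prd, obs)
    return {"r": float(r), "p": float(p), "r2": float(r) ** 2,
            "n_genes": len(pairs), "fold_change_definition": definition}


class GlobalNullModel:
    """Physiology-only model of a cohort: shared S(t), per-gene turnover.

    Fitting builds the global synthesis profile from the cohort (or a
    reference-gene panel), predicts every gene under the null, and scores how
    much of the observed fold-change variance the null explains.
    """

    def __init__(self, expression: list[ExpressionSeries], growth: GrowthProfile,
                 degradation: DegradationTable,
                 mode: str = "all_mean", refs: list[str] | None = None):
        self.expression = list(expression)
        self.growth = growth
        self.degradation = degradation
        self.mode = mode
        self.refs = refs

    def fit(self, fold_change_definition: str = "peak") -> "GlobalNullResults":
        synth = [estimate_synthesis_rates(s, self.growth,
                                          self.degradation.lookup(s.gene_id))
                 for s in self.expression]
        profile = build_global_synthesis(synth, self.mode, self.refs)
        predicted = global_null_prediction(self.expression, self.growth,
                                           self.degradation, profile)
        report = fold_change_correlation(self.expression, predicted,
                                         fold_change_definition)
        return GlobalNullResults(self, profile, predicted, report)


class GlobalNullResults:
    def __init__(self, model: GlobalNullModel, profile: GlobalSynthesisProfile,
                 predicted: list[ExpressionSeries], correlation: dict):
        self.model = model
        self.global_profile = profile
        self.predicted = predicted
        self.correlation = correlation

    @property
    def r(self) -> float:
        return self.correlation["r"]

    @property
    def r2(self) -> float:
        return self.correlation["r2"]

    def summary(self) -> str:
        c = self.correlation
        lines = [
            "Global-null (physiology-only) model",
            "===================================",
            f"genes paired:            {c['n_genes']}",
            f"global profile:          {self.global_profile.provenance}",
            f"fold-change definition:  {c['fold_change_definition']}",
            f"Pearson r:               {c['r']:.4f}",
            f"p-value:                 {c['p']:.3g}",
            f"variance explained r^2:  {c['r2']:.4f}",
        ]
        return "\n".join(lines)
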