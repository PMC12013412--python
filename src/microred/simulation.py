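"""Dirichlet synthetic communities and the unclassified-species experiment.

Each iteration draws a share vector and an abundance vector independently from
a symmetric Dirichlet whose concentration is coin-flipped between an uneven
(alpha=1) and a more even (alpha=5) regime.  Species are then reclassified as
"unknown" in cumulative batches; the redundancy measures are recomputed on the
renormalised, shortened vectors, while the reference measure keeps its
denominator fixed at the full community size.  The recorded quantity is the
bias observed-minus-true per measure, iteration and unknown count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError, kl_divergence, shannon_entropy

MEASURES = ("sample_fr", "reference_fr", "abundance_fr")


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 100
    n_iterations: int = 1000
    alpha_options: tuple[float, float] = (1.0, 5.0)
    alpha_probability: float = 0.5
    unknown_step: int = 10
    max_unknown: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValidationError("need at least two species")
        if self.n_iterations < 1:
            raise ValidationError("need at least one iteration")
        if any(a <= 0 for a in self.alpha_options):
            raise ValidationError("Dirichlet concentrations must be positive")
        if not 0.0 <= self.alpha_probability <= 1.0:
            raise ValidationError("alpha_probability must be in [0, 1]")
        if self.max_unknown >= self.n_species:
            raise ValidationError("max_unknown must be smaller than n_species")
        if self.unknown_step < 1 or self.max_unknown % self.unknown_step != 0:
            raise ValidationError("unknown_step must divide max_unknown")

    @property
    def unknown_counts(self) -> tuple[int, ...]:
        return tuple(range(0, self.max_unknown + 1, self.unknown_step))


@dataclass(frozen=True)
class SimulationResult:
    """Long-form record: one row per iteration x unknown count x measure."""

    frame: pd.DataFrame
    config: SimulationConfig


def draw_community(
    n: int, alpha: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a (shares, abundances) pair from independent symmetric Dirichlets."""
    if n < 2:
        raise ValidationError("need at least two species")
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    shares = rng.dirichlet(np.full(n, float(alpha)))
    abundances = rng.dirichlet(np.full(n, float(alpha)))
    return shares, abundances


def reclassify_unknown(
    shares: np.ndarray,
    abundances: np.ndarray,
    k_unknown: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Remove ``k_unknown`` random species and renormalise both vectors.

    Returns ``None`` when the surviving species carry no share at all (the
    iteration should then be recorded as missing).
    """
    n = shares.size
    if abundances.size != n:
        raise ValidationError("shares and abundances must have equal length")
    if not 0 <= k_unknown < n:
        raise ValidationError("k_unknown must be in [0, n)")
    if k_unknown == 0:
        return shares.copy(), abundances.copy()
    removed = rng.choice(n, size=k_unknown, replace=False)
    keep = np.setdiff1d(np.arange(n), removed)
    f = shares[keep]
    a = abundances[keep]
    if f.sum() <= 0.0 or a.sum() <= 0.0:
        return None
    return f / f.sum(), a / a.sum()


def _measures(shares: np.ndarray, abundances: np.ndarray, m_reference: int) -> dict:
    entropy = shannon_entropy(shares)
    return {
        "sample_fr": entropy - math.log(shares.size),
        "reference_fr": entropy - math.log(m_reference),
        "abundance_fr": -kl_divergence(shares, abundances),
    }


def run_experiment(config: SimulationConfig) -> SimulationResult:
    """Run the full unknown-species experiment.

    Per iteration: flip the concentration parameter, draw shares and
    abundances, then remove species cumulatively in steps of
    ``unknown_step`` up to ``max_unknown``, recomputing all measures on the
    renormalised remainder.  The reference denominator stays at ``n_species``
    throughout, which is what makes the reference measure biased.  At unknown
    count 0 the bias is exactly zero by construction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    rows: list[dict] = []
    for iteration in range(config.n_iterations):
        alpha = (
            config.alpha_options[0]
            if rng.random() < config.alpha_probability
            else config.alpha_options[1]
        )
        shares, abundances = draw_community(n, alpha, rng)
        truth = _measures(shares, abundances, n)
        # one removal order per iteration; prefixes give cumulative batches
        order = rng.permutation(n)
        for k_unknown in config.unknown_counts:
            if k_unknown == 0:
                # no removal: observed is the truth, bias exactly zero
                for measure in MEASURES:
                    rows.append(
                        {
                            "iteration": iteration,
                            "alpha": alpha,
                            "n_unknown": 0,
                            "measure": measure,
                            "true": truth[measure],
                            "observed": truth[measure],
                            "bias": 0.0,
                        }
                    )
                continue
            keep = np.sort(order[k_unknown:])
            f = shares[keep]
            a = abundances[keep]
            f_total = f.sum()
            if f_total <= 0.0:
                for measure in MEASURES:
                    rows.append(
                        {
                            "iteration": iteration,
                            "alpha": alpha,
                            "n_unknown": k_unknown,
                            "measure": measure,
                            "true": truth[measure],
                            "observed": np.nan,
                            "bias": np.nan,
                        }
                    )
                continue
            observed = _measures(f / f_total, a / a.sum(), n)
            for measure in MEASURES:
                rows.append(
                    {
                        "iteration": iteration,
                        "alpha": alpha,
                        "n_unknown": k_unknown,
                        "measure": measure,
                        "true": truth[measure],
                        "observed": observed[measure],
                        "bias": observed[measure] - truth[measure],
                    }
                )
    return SimulationResult(pd.DataFrame(rows), config)


def summarise(result: SimulationResult) -> pd.DataFrame:
    """Aggregate bias by (measure, alpha, unknown count).

    Columns: mean bias, its standard deviation and Monte-Carlo standard error,
    quantiles (5/25/50/75/95 %), inter-quartile range and the number of
    non-missing iterations.
    """
    if result.frame.empty:
        raise ValidationError("empty simulation result")
    records = []
    for (measure, alpha, n_unknown), group in result.frame.groupby(
        ["measure", "alpha", "n_unknown"], sort=True
    ):
        bias = group["bias"].dropna().to_numpy()
        if bias.size == 0:
            continue
        q05, q25, q50, q75, q95 = np.quantile(bias, [0.05, 0.25, 0.5, 0.75, 0.95])
        sd = float(bias.std(ddof=1)) if bias.size > 1 else 0.0
        records.append(
            {
                "measure": measure,
                "alpha": alpha,
                "n_unknown": n_unknown,
                "n": int(bias.size),
                "mean_bias": float(bias.mean()),
                "sd": sd,
                "se": sd / math.sqrt(bias.size) if bias.size else float("nan"),
                "q05": q05,
                "q25": q25,
                "median": q50,
                "q75": q75,
                "q95": q95,
                "iqr": q75 - q25,
            }
        )
    return pd.DataFrame(records)
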