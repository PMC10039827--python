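"""Synthetic site tables with known structural coefficients.

The generator draws data from the structural equations a path diagram
encodes: exogenous land-cover gradients are standard normal, each
endogenous Gaussian node is a linear (plus optional quadratic) combination
of its parents with Gaussian noise, and richness counts are Poisson with a
log-linear rate in the node's parents.  By default the residual variance of
every endogenous Gaussian node is solved analytically so that all
land-cover variables have unit variance — the structural coefficients are
then directly comparable to the standardised-scale path estimates the
analysis produces.

This emulates the statistical structure the analysis assumes (correlated
agriculture–forest gradients, Poisson richness); it does not emulate
bounded proportions, survey noise, or spatial dependence (see the raster
pathway in :mod:`agrisem.landscape` for bounded compositions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dag import DagSpec, topological_order, validate_dag

__all__ = ["GeneratorConfig", "SyntheticSiteTable", "generate_site_table", "sign_based_truth"]

ETA_LIMIT = 20.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic data set.

    ``coefficients`` maps (source, target) links to structural slopes;
    ``quad_coefficients`` adds the x² slope for quadratic links;
    ``intercepts`` gives the log-scale intercept of each Poisson richness
    node.  ``noise_sd`` overrides the automatic unit-variance residual for
    named Gaussian nodes.  The defaults mirror the study design the
    analysis targets: 127 survey sites on an agriculture–forest gradient.
    """

    spec: DagSpec
    coefficients: dict[tuple[str, str], float]
    quad_coefficients: dict[tuple[str, str], float] = field(default_factory=dict)
    intercepts: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] | None = None
    n_sites: int = 127
    seed: int = 0
    spatial_layout: str = "random"
    extent_m: float = 40_000.0

    def __post_init__(self) -> None:
        if self.n_sites < 10:
            raise ValueError("n_sites must be at least 10")
        if self.spatial_layout not in ("random", "grid"):
            raise ValueError("spatial_layout must be 'random' or 'grid'")


@dataclass(frozen=True)
class SyntheticSiteTable:
    """Generated site table plus the truth that produced it."""

    table: pd.DataFrame
    config: GeneratorConfig
    residual_sd: dict[str, float]

    def truth_dict(self) -> dict:
        return {
            "coefficients": {f"{s}->{t}": v for (s, t), v in self.config.coefficients.items()},
            "quad_coefficients": {
                f"{s}->{t}": v for (s, t), v in self.config.quad_coefficients.items()
            },
            "intercepts": dict(self.config.intercepts),
            "residual_sd": dict(self.residual_sd),
            "n_sites": self.config.n_sites,
            "seed": self.config.seed,
        }


def sign_based_truth(
    spec: DagSpec,
    positive: float = 0.35,
    negative: float = -0.4,
    added: float = 0.3,
    peaked: tuple[float, float] = (0.3, -0.25),
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """Default structural coefficients from a diagram's predicted signs.

    Moderate effect sizes (|β| ≈ 0.3–0.4) with the hypothesised directions;
    links without a predicted sign (added links) get a positive slope of
    ``added``.  Returns (coefficients, quad_coefficients).
    """
    coefs: dict[tuple[str, str], float] = {}
    quads: dict[tuple[str, str], float] = {}
    for l in spec.links:
        if l.form == "quadratic" or l.predicted_sign == "peaked":
            coefs[l.pair] = peaked[0]
            quads[l.pair] = peaked[1]
        elif l.predicted_sign == "+":
            coefs[l.pair] = positive
        elif l.predicted_sign == "-":
            coefs[l.pair] = negative
        else:
            coefs[l.pair] = added
    return coefs, quads


def _auto_residual_sd(
    spec: DagSpec,
    order: list[str],
    coefs: dict[tuple[str, str], float],
    quads: dict[tuple[str, str], float],
) -> dict[str, float]:
    """Residual SDs giving every Gaussian node unit marginal variance.

    Covariances propagate through the linear part of the structural
    equations; a quadratic parent term contributes variance 2β² and (for
    centred jointly Gaussian parents) zero covariance with linear terms.
    """
    cov: dict[tuple[str, str], float] = {}
    sds: dict[str, float] = {}
    gaussian = [n for n in order if spec.family(n) == "gaussian"]
    for i, node in enumerate(gaussian):
        parents = spec.parents(node)
        if not parents:
            cov[(node, node)] = 1.0
            for prev in gaussian[:i]:
                cov[(node, prev)] = cov[(prev, node)] = 0.0
            continue
        betas = {p: coefs[(p, node)] for p in parents}
        explained = 0.0
        for p in parents:
            for q in parents:
                explained += betas[p] * betas[q] * cov[(p, q)]
        for p in parents:
            bq = quads.get((p, node), 0.0)
            explained += 2.0 * bq * bq
        if explained >= 1.0:
            raise ValueError(
                f"node {node!r}: explained variance {explained:.3f} >= 1; "
                "reduce the structural coefficients or supply noise_sd"
            )
        sds[node] = math.sqrt(1.0 - explained)
        for prev in gaussian[: i + 1]:
            c = sum(betas[p] * cov[(p, prev)] for p in parents)
            if prev == node:
                c = 1.0
            cov[(node, prev)] = cov[(prev, node)] = c
    return sds


def _coordinates(config: GeneratorConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_sites
    if config.spatial_layout == "grid":
        side = math.ceil(math.sqrt(n))
        spacing = config.extent_m / side
        xs, ys = np.meshgrid(np.arange(side), np.arange(side))
        return (xs.ravel()[:n] * spacing, ys.ravel()[:n] * spacing)
    return (rng.uniform(0, config.extent_m, n), rng.uniform(0, config.extent_m, n))


def generate_site_table(config: GeneratorConfig) -> SyntheticSiteTable:
    """Draw one site table from the structural model.

    Reproducible per seed.  Raises if a Poisson linear predictor exceeds
    ±20 (the rate would overflow any realistic richness scale).
    """
    spec = validate_dag(config.spec)
    order = topological_order(spec)
    for l in spec.links:
        if l.pair not in config.coefficients:
            raise ValueError(f"no structural coefficient for link {l.source}->{l.target}")
        if l.form == "quadratic" and l.pair not in config.quad_coefficients:
            raise ValueError(f"no quadratic coefficient for link {l.source}->{l.target}")
    rng = np.random.default_rng(config.seed)
    n = config.n_sites

    if config.noise_sd is None:
        residual_sd = _auto_residual_sd(spec, order, config.coefficients, config.quad_coefficients)
    else:
        residual_sd = dict(config.noise_sd)

    values: dict[str, np.ndarray] = {}
    for node in order:
        family = spec.family(node)
        parents = spec.parents(node)
        if family == "gaussian":
            if not parents:
                values[node] = rng.standard_normal(n)
                continue
            sd = residual_sd.get(node)
            if sd is None or sd <= 0:
                raise ValueError(f"endogenous gaussian node {node!r} needs noise sd > 0")
            eta = np.zeros(n)
            for p in parents:
                eta += config.coefficients[(p, node)] * values[p]
                bq = config.quad_coefficients.get((p, node))
                if bq is not None:
                    eta += bq * values[p] ** 2
            values[node] = eta + sd * rng.standard_normal(n)
        else:  # poisson richness
            eta = np.full(n, float(config.intercepts.get(node, 0.0)))
            for p in parents:
                eta += config.coefficients[(p, node)] * values[p]
                bq = config.quad_coefficients.get((p, node))
                if bq is not None:
                    eta += bq * values[p] ** 2
            if np.max(np.abs(eta)) > ETA_LIMIT:
                raise ValueError(
                    f"linear predictor of {node!r} exceeds ±{ETA_LIMIT:g}; "
                    "use smaller structural coefficients"
                )
            values[node] = rng.poisson(np.exp(eta)).astype(float)

    x, y = _coordinates(config, rng)
    data = {"site": np.arange(1, n + 1), "x": x, "y": y}
    data.update({node: values[node] for node in order})
    return SyntheticSiteTable(table=pd.DataFrame(data), config=config, residual_sd=residual_sd)
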