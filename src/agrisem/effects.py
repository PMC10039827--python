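"""Direct, indirect and total effects of agriculture on guild richness.

A direct effect is the coefficient of the link from an agriculture variable
straight to richness.  Each indirect pathway contributes the product of its
link coefficients, and the indirect effect is the sum over all such
pathways; the total effect is direct + indirect.  The proportional change
|total|/|direct| (1 decimal) summarises how much the indirect pathways
amplify ("more") or dampen ("less") the direct response, tagged with the
sign of the total effect.

Richness links carry log-scale Poisson coefficients while upstream
land-cover links are identity-scale; pathway products deliberately mix the
two scales — the decomposition is a path-diagram summary, not a marginal
effect on the count scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .dag import DagSpec, directed_paths

__all__ = [
    "PathContribution",
    "EffectDecomposition",
    "quadratic_link_effect",
    "decompose",
    "proportional_change",
]

LinkCoefficients = Mapping[tuple[str, str], float]


@dataclass(frozen=True)
class PathContribution:
    """One directed pathway and the product of its link coefficients."""

    path: tuple[str, ...]
    link_coefficients: tuple[float, ...]
    product: float

    def to_dict(self) -> dict:
        return {
            "path": list(self.path),
            "link_coefficients": list(self.link_coefficients),
            "product": self.product,
        }


@dataclass(frozen=True)
class EffectDecomposition:
    """Direct/indirect/total effect of one agriculture variable on one guild."""

    source: str
    response: str
    direct: float
    indirect_paths: tuple[PathContribution, ...]
    indirect: float
    total: float
    n_indirect_paths: int
    proportional_change: float | None
    direction_label: str | None

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "response": self.response,
            "direct": self.direct,
            "indirect": self.indirect,
            "total": self.total,
            "n_indirect_paths": self.n_indirect_paths,
            "proportional_change": self.proportional_change,
            "direction_label": self.direction_label,
            "indirect_paths": [p.to_dict() for p in self.indirect_paths],
        }


def quadratic_link_effect(linear_coef: float, quadratic_coef: float) -> float:
    """Single path coefficient for a peaked link: linear + quadratic estimate."""
    return linear_coef + quadratic_coef


def _round_half_up(x: float, decimals: int) -> float:
    scale = 10.0 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def proportional_change(direct: float, total: float) -> tuple[float | None, str | None]:
    """Ratio |total|/|direct| (1 decimal) and its more/less ± label.

    ``more`` when the ratio is at least 1 (indirect pathways amplified the
    direct effect), ``less`` otherwise; the sign is the total effect's.
    A zero direct effect leaves the ratio undefined (None, None).
    """
    if direct == 0:
        return None, None
    ratio = _round_half_up(abs(total) / abs(direct), 1)
    word = "more" if ratio >= 1.0 else "less"
    sign = "+" if total >= 0 else "-"
    return ratio, f"{word} {sign}"


def decompose(
    spec: DagSpec,
    coefficients: LinkCoefficients,
    source: str,
    response: str,
) -> EffectDecomposition:
    """Decompose the effect of ``source`` on ``response`` over all pathways.

    ``coefficients`` maps each (source, target) link to its path coefficient
    (for a quadratic link, supply the summed linear + quadratic estimate).
    Links absent from the mapping must not lie on any pathway.  When the
    response is unreachable the decomposition is all-zero with no pathways.
    """
    paths = directed_paths(spec, source, response)
    direct = 0.0
    contributions: list[PathContribution] = []
    for path in paths:
        links = list(zip(path[:-1], path[1:]))
        try:
            coefs = tuple(float(coefficients[l]) for l in links)
        except KeyError as err:
            raise KeyError(f"no coefficient for link {err.args[0]} on path {path}") from None
        product = math.prod(coefs)
        if len(path) == 2:
            direct = product
        else:
            contributions.append(
                PathContribution(path=tuple(path), link_coefficients=coefs, product=product)
            )
    indirect = float(sum(c.product for c in contributions))
    total = direct + indirect
    ratio, label = proportional_change(direct, total)
    return EffectDecomposition(
        source=source,
        response=response,
        direct=direct,
        indirect_paths=tuple(contributions),
        indirect=indirect,
        total=total,
        n_indirect_paths=len(contributions),
        proportional_change=ratio,
        direction_label=label,
    )
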