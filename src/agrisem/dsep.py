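"""Directional-separation test of a path diagram against site data.

Each independence claim in the diagram's basis set is tested by regressing
the causally later member on its conditioning set plus the earlier member
(family chosen by the response node), taking the two-sided Wald p-value of
the earlier member's coefficient.  The k p-values combine into Fisher's
C = −2 Σ ln p_i, referred to a χ² distribution with 2k degrees of freedom:
a small upper-tail p rejects the diagram.  Failed claims (p < α) earn an
added link from the earlier to the later member, after which the test is
re-run on the revised diagram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dag import DagSpec, IndependenceClaim, LinkSpec, basis_set, validate_dag
from .regression import design_matrix, fit_glm

__all__ = ["ClaimTest", "DSepResult", "claim_pvalue", "fishers_c", "dsep_test", "revise_dag"]


@dataclass(frozen=True)
class ClaimTest:
    """One tested independence claim."""

    claim: IndependenceClaim
    p_value: float
    test_family: str
    coefficient: float

    def to_dict(self) -> dict:
        return {
            "earlier": self.claim.earlier,
            "later": self.claim.later,
            "conditioning_set": list(self.claim.conditioning_set),
            "test_family": self.test_family,
            "coefficient": self.coefficient,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class DSepResult:
    """Fisher's C summary over a basis set."""

    claim_tests: tuple[ClaimTest, ...]
    C: float
    df: int
    p_value: float

    @property
    def k(self) -> int:
        return len(self.claim_tests)

    def to_dict(self) -> dict:
        return {
            "claims": [ct.to_dict() for ct in self.claim_tests],
            "k": self.k,
            "C": self.C,
            "df": self.df,
            "p_value": self.p_value,
        }


def claim_pvalue(claim: IndependenceClaim, table: pd.DataFrame, spec: DagSpec) -> ClaimTest:
    """Test one claim: later ~ conditioning set + earlier.

    The regression family is the later node's family; the p-value is the
    two-sided Wald test on the earlier node's coefficient (exact t for
    Gaussian responses, normal for Poisson).
    """
    family = spec.family(claim.later)
    terms = tuple(claim.conditioning_set) + (claim.earlier,)
    X = design_matrix(table, terms)
    fit = fit_glm(np.asarray(table[claim.later], dtype=float), X, family, terms, claim.later)
    return ClaimTest(
        claim=claim,
        p_value=fit.wald_p(claim.earlier),
        test_family=family,
        coefficient=fit.coef(claim.earlier),
    )


def fishers_c(p_values: Sequence[float], floor: float | None = None) -> tuple[float, int, float]:
    """Fisher's C = −2 Σ ln p_i with df = 2k and its upper-tail χ² p-value.

    An empty list is the saturated diagram: C = 0, df = 0, p = 1.  A
    p-value of 0 raises unless ``floor`` is given (it then replaces any
    p below it).
    """
    ps = [float(p) for p in p_values]
    for p in ps:
        if not np.isfinite(p) or p > 1:
            raise ValueError(f"invalid p-value {p}")
        if p <= 0:
            if floor is None:
                raise ValueError("p-value of 0: Fisher's C is infinite (set a floor to override)")
    if floor is not None:
        ps = [max(p, floor) for p in ps]
    k = len(ps)
    if k == 0:
        return 0.0, 0, 1.0
    C = -2.0 * float(np.sum(np.log(ps)))
    df = 2 * k
    return C, df, float(stats.chi2.sf(C, df))


def dsep_test(spec: DagSpec, table: pd.DataFrame) -> DSepResult:
    """Run the full directional-separation test on standardised site data."""
    validate_dag(spec)
    tests = tuple(claim_pvalue(c, table, spec) for c in basis_set(spec))
    C, df, p = fishers_c([t.p_value for t in tests])
    return DSepResult(claim_tests=tests, C=C, df=df, p_value=p)


def revise_dag(
    spec: DagSpec,
    table: pd.DataFrame,
    alpha: float = 0.05,
    iterate: bool = False,
    max_rounds: int = 10,
) -> tuple[DagSpec, DSepResult]:
    """Add links for failed claims and re-run the d-separation test.

    Every claim with p < ``alpha`` becomes a linear link oriented from the
    claim's earlier to its later member (provenance ``added``), preserving
    acyclicity.  By default a single revision round is performed; with
    ``iterate=True`` rounds continue until no claim fails or the diagram
    saturates.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    current = spec
    result = dsep_test(current, table)
    for _ in range(max_rounds):
        failed = [t for t in result.claim_tests if t.p_value < alpha]
        if not failed:
            break
        extra = [
            LinkSpec(t.claim.earlier, t.claim.later, form="linear",
                     predicted_sign="none", provenance="added")
            for t in failed
        ]
        current = validate_dag(current.with_links(extra))
        result = dsep_test(current, table)
        if not iterate:
            break
    return current, result
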