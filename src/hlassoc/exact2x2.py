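"""Exact conditional inference on carrier 2x2 tables.

Conditioning on both margins of a 2x2 table leaves a single free cell ``A``
(case carriers) distributed as a noncentral hypergeometric with odds-ratio
parameter ``psi``:

    P_psi(A = x)  proportional to  C(K, x) * C(N-K, n1-x) * psi**x

over the feasible support, where ``n1 = a+b`` (cases), ``K = a+c`` (carriers)
and ``N`` is the grand total. Everything here derives from that model:

* the two-sided Fisher exact p-value sums central (psi = 1) point
  probabilities no larger than the observed one;
* the odds-ratio estimate is the conditional MLE, the ``psi`` for which
  ``E_psi[A]`` equals the observed count — the estimator R's ``fisher.test``
  reports;
* the exact confidence interval inverts the conditional tails,
  ``P_psi(A >= a) = alpha/2`` for the lower bound and ``P_psi(A <= a) =
  alpha/2`` for the upper.

All probabilities are computed in log space; root finding is bisection-safe
bracketed Brent on ``log psi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .genotypes import (
    AlleleCall,
    Cohort,
    ContingencyTable2x2,
    HlassocError,
    carrier_table,
)

__all__ = [
    "NchgModel",
    "AssociationResult",
    "nchg_pmf",
    "fisher_two_sided_p",
    "cml_or",
    "exact_ci",
    "corrected_or",
    "associate_allele",
    "screen_alleles",
]

#: log-odds-ratio bracket for root finding; expanded on demand
_LOG_BRACKET = math.log(1e8)
#: relative tolerance used when comparing point probabilities for the
#: two-sided rule (absorbs floating-point ties, as in R's fisher.test)
_P_REL_TOL = 1.0 + 1e-7


class DegenerateTableError(HlassocError, ValueError):
    """A margin of the 2x2 table is empty, so conditional inference is void."""


@dataclass(frozen=True)
class NchgModel:
    """Noncentral hypergeometric model of one 2x2 cell given both margins."""

    n1: int  # row-1 total (cases)
    K: int   # column-1 total (carriers)
    N: int   # grand total

    @classmethod
    def from_table(cls, table: ContingencyTable2x2) -> "NchgModel":
        m = cls(table.n_cases, table.a + table.c, table.total)
        if m.n1 <= 0 or m.n1 >= m.N or m.K <= 0 or m.K >= m.N:
            raise DegenerateTableError(
                f"degenerate margins n1={m.n1}, K={m.K}, N={m.N}: an empty "
                "row or column leaves nothing to condition on"
            )
        return m

    @property
    def support(self) -> np.ndarray:
        """Feasible values of the case-carrier cell ``a``."""
        lo = max(0, self.n1 - (self.N - self.K))
        hi = min(self.n1, self.K)
        return np.arange(lo, hi + 1)

    @property
    def log_weights(self) -> np.ndarray:
        """log[C(K, x) * C(N-K, n1-x)] over the support."""
        x = self.support
        return _log_comb(self.K, x) + _log_comb(self.N - self.K, self.n1 - x)

    def logpmf(self, psi: float) -> np.ndarray:
        if psi <= 0:
            raise ValueError(f"odds ratio parameter psi={psi} must be > 0")
        lp = self.log_weights + self.support * math.log(psi)
        return lp - logsumexp(lp)

    def pmf(self, psi: float) -> np.ndarray:
        return np.exp(self.logpmf(psi))

    def expected(self, psi: float) -> float:
        """E_psi[A]; strictly increasing in psi."""
        return float(np.dot(self.support, self.pmf(psi)))

    def upper_tail(self, a: int, psi: float) -> float:
        """P_psi(A >= a)."""
        p = self.pmf(psi)
        return float(p[self.support >= a].sum())

    def lower_tail(self, a: int, psi: float) -> float:
        """P_psi(A <= a)."""
        p = self.pmf(psi)
        return float(p[self.support <= a].sum())


def _log_comb(n, k) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def nchg_pmf(model: NchgModel, psi: float) -> np.ndarray:
    """Probability mass over ``model.support`` at odds ratio ``psi``."""
    return model.pmf(psi)


# ---------------------------------------------------------------------------
# Fisher two-sided p
# ---------------------------------------------------------------------------

def fisher_two_sided_p(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the point-probability rule.

    Sums the central hypergeometric probabilities of every table with the
    observed margins whose point probability does not exceed the observed
    table's (up to a tiny relative tolerance for floating-point ties).
    """
    model = NchgModel.from_table(table)
    p = model.pmf(1.0)
    p_obs = p[model.support == table.a][0]
    return float(min(1.0, p[p <= p_obs * _P_REL_TOL].sum()))


# ---------------------------------------------------------------------------
# conditional MLE odds ratio
# ---------------------------------------------------------------------------

def _solve_log_psi(f, lo: float = -_LOG_BRACKET, hi: float = _LOG_BRACKET) -> float:
    """Root of a monotone function of log(psi), expanding the bracket if needed."""
    flo, fhi = f(lo), f(hi)
    tries = 0
    while flo * fhi > 0 and tries < 4:
        lo *= 2.0
        hi *= 2.0
        flo, fhi = f(lo), f(hi)
        tries += 1
    if flo * fhi > 0:  # pragma: no cover - pathological margins
        raise HlassocError("root bracketing failed for odds-ratio solve")
    return brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16)


def cml_or(table: ContingencyTable2x2) -> float:
    """Conditional maximum-likelihood odds ratio.

    Solves ``E_psi[A] = a`` on the margin-conditioned model. Returns
    ``math.inf`` when ``a`` sits at the upper support bound and ``0.0`` at the
    lower bound (the likelihood is then maximised on the boundary).
    """
    model = NchgModel.from_table(table)
    a = table.a
    sup = model.support
    if a == sup[-1]:
        return math.inf
    if a == sup[0]:
        return 0.0
    t = _solve_log_psi(lambda t: model.expected(math.exp(t)) - a)
    return math.exp(t)


# ---------------------------------------------------------------------------
# exact confidence interval by test inversion
# ---------------------------------------------------------------------------

def exact_ci(
    table: ContingencyTable2x2, alpha: float = 0.05
) -> tuple[float, float]:
    """Exact CI for the odds ratio by inverting the conditional tails.

    The lower bound solves ``P_psi(A >= a) = alpha/2`` and the upper bound
    ``P_psi(A <= a) = alpha/2``; the bounds are 0 / infinity when ``a`` sits
    on the corresponding support boundary. Endpoints reproduce their nominal
    tail probabilities to full root-finder precision.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} must be in (0, 1)")
    model = NchgModel.from_table(table)
    a = table.a
    sup = model.support
    if a == sup[0]:
        low = 0.0
    else:
        t = _solve_log_psi(lambda t: model.upper_tail(a, math.exp(t)) - alpha / 2)
        low = math.exp(t)
    if a == sup[-1]:
        high = math.inf
    else:
        t = _solve_log_psi(lambda t: model.lower_tail(a, math.exp(t)) - alpha / 2)
        high = math.exp(t)
    return low, high


# ---------------------------------------------------------------------------
# continuity-corrected cross-product odds ratio
# ---------------------------------------------------------------------------

def corrected_or(
    table: ContingencyTable2x2, mode: str = "zero_cells_only"
) -> float:
    """Cross-product odds ratio with a 0.5 continuity correction.

    ``zero_cells_only`` adds 0.5 only to the cells that are zero (this is the
    variant consistent with the reference results); ``all_cells`` adds 0.5 to
    every cell (Haldane-Anscombe).
    """
    if mode not in ("zero_cells_only", "all_cells"):
        raise ValueError(f"unknown correction mode {mode!r}")
    a, b, c, d = (float(v) for v in table.as_tuple())
    if mode == "all_cells":
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a, b, c, d = (v if v > 0 else 0.5 for v in (a, b, c, d))
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# per-feature association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    """Exact-test summary for one carrier-defined feature."""

    feature: str
    table: ContingencyTable2x2
    p_two_sided: float
    or_estimate: float
    or_method: str  # "cml" | "corrected_cross_product"
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_two_sided <= 1.0:
            raise ValueError(f"p={self.p_two_sided} outside (0, 1]")


def result_from_table(
    feature: str,
    table: ContingencyTable2x2,
    alpha: float = 0.05,
    correction_mode: str = "zero_cells_only",
) -> AssociationResult:
    """Assemble an :class:`AssociationResult` for an arbitrary carrier table.

    The odds ratio is the conditional MLE when every cell is positive;
    with a zero cell the continuity-corrected cross-product is reported
    instead (and tagged). The CI is always the exact inversion interval of
    the uncorrected table. A feature carried by everyone or by no one leaves
    nothing to condition on: p is 1, the corrected cross-product is reported,
    and the CI is the whole positive axis.
    """
    carriers = table.a + table.c
    if carriers == 0 or carriers == table.total:
        return AssociationResult(
            feature=feature,
            table=table,
            p_two_sided=1.0,
            or_estimate=corrected_or(table, correction_mode),
            or_method="corrected_cross_product",
            ci_low=0.0,
            ci_high=math.inf,
            alpha=alpha,
        )
    p = fisher_two_sided_p(table)
    if min(table.as_tuple()) > 0:
        or_est, method = cml_or(table), "cml"
    else:
        or_est, method = corrected_or(table, correction_mode), "corrected_cross_product"
    low, high = exact_ci(table, alpha)
    return AssociationResult(
        feature=feature,
        table=table,
        p_two_sided=p,
        or_estimate=or_est,
        or_method=method,
        ci_low=low,
        ci_high=high,
        alpha=alpha,
    )


def associate_allele(
    cohort: Cohort,
    allele: AlleleCall,
    case_group: str = "case",
    control_group: str = "tolerant_control",
    alpha: float = 0.05,
    correction_mode: str = "zero_cells_only",
) -> AssociationResult:
    """Carrier-based exact association of one allele."""
    table = carrier_table(cohort, allele, case_group, control_group)
    return result_from_table(allele.label, table, alpha, correction_mode)


def _rank_key(r: AssociationResult):
    # ascending p, ties by descending OR, then label
    neg_or = -r.or_estimate if math.isfinite(r.or_estimate) else -math.inf
    return (r.p_two_sided, neg_or, r.feature)


def adjust_results(
    results: Sequence[AssociationResult], method: str
) -> list[AssociationResult]:
    """Attach multiple-testing-adjusted p-values (``bonferroni`` or ``bh``)."""
    from statsmodels.stats.multitest import multipletests
    from dataclasses import replace

    if not results:
        return []
    name = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    _, padj, _, _ = multipletests([r.p_two_sided for r in results], method=name)
    return [replace(r, p_adjusted=float(q)) for r, q in zip(results, padj)]


def screen_alleles(
    cohort: Cohort,
    case_group: str = "case",
    control_group: str = "tolerant_control",
    alpha: float = 0.05,
    universe: str = "cases",
    correction_mode: str = "zero_cells_only",
    adjust: str | None = None,
) -> list[AssociationResult]:
    """Exact association of every observed allele, most significant first.

    ``universe`` selects the tested alleles: those observed in the case group
    (default, mirroring a small-case-series screen) or ``"all"`` observed
    anywhere. Raw p-values are reported; pass ``adjust`` for Bonferroni or
    Benjamini-Hochberg annotations.
    """
    group_for_universe = case_group if universe == "cases" else None
    alleles = cohort.observed_alleles(group_for_universe)
    results = [
        associate_allele(
            cohort, al, case_group, control_group, alpha, correction_mode
        )
        for al in alleles
    ]
    results.sort(key=_rank_key)
    if adjust:
        results = adjust_results(results, adjust)
    return results
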