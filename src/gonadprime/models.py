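"""Differentiation-model tests on primed-gene counts.

Three candidate "ground states" of a bipotential progenitor make testable
predictions about the sex split of its primed genes: an extreme *female*
model (a large majority — by default 90% — of primed genes belong to the
female program), the mirror-image *male* model, and a *balanced* model
(50/50).  Each is tested with an exact binomial test on the observed
male/female primed counts: one-tailed for the extreme models (toward the
observed side of the predicted fraction), two-tailed for the balanced
model.  Models with p below ``alpha_model`` are excluded; if all three are
excluded an intermediate, *biased* model in the direction of the majority
sex is selected.

Independence of sex and priming — whether the fraction of markers showing
priming differs between the male and female programs — is tested with the
two-sided exact test on the 2x2 contingency table of primed / not-primed
counts per sex (Fisher's exact test on the hypergeometric null).

All p-values are computed with exact integer/rational arithmetic: the
two-sided p is the sum of all outcomes whose probability mass does not
exceed the observed outcome's, with ties decided exactly rather than to
floating-point tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb

from .study import ThresholdConfig

__all__ = [
    "ModelTestReport",
    "binom_pvalue_one_tailed",
    "binom_pvalue_two_tailed",
    "fisher_two_sided",
    "test_models",
    "test_independence",
    "bias_report",
]


def _as_fraction(p: float) -> Fraction:
    if not 0.0 < p < 1.0:
        raise ValueError(f"success probability must be in (0,1), got {p}")
    return Fraction(p).limit_denominator(10**9)


def _binom_pmfs(n: int, p: Fraction) -> list[Fraction]:
    q = 1 - p
    return [comb(n, k) * p**k * q ** (n - k) for k in range(n + 1)]


def binom_pvalue_one_tailed(k: int, n: int, p0: float) -> float:
    """One-tailed exact binomial p-value toward the observed side of p0.

    Lower tail P(X <= k) when k/n <= p0, upper tail P(X >= k) when
    k/n > p0.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    pmf = _binom_pmfs(n, _as_fraction(p0))
    if Fraction(k, n) <= _as_fraction(p0):
        return float(sum(pmf[: k + 1]))
    return float(sum(pmf[k:]))


def binom_pvalue_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Two-tailed exact binomial p-value (minimum-likelihood definition).

    Sum of P(X = i) over all outcomes i with P(X = i) <= P(X = k), the
    standard exact two-sided definition, capped at 1.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    pmf = _binom_pmfs(n, _as_fraction(p0))
    observed = pmf[k]
    total = sum(m for m in pmf if m <= observed)
    return float(min(total, Fraction(1)))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p-value for independence in a 2x2 table.

    Rows are the two sexes, columns primed / not primed.  Conditioning on
    the margins gives the hypergeometric null; the p-value sums the
    probabilities of every table (with the same margins) whose probability
    does not exceed the observed table's.  A zero margin makes the table
    degenerate: p = 1 with a warning.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n < 1:
        raise ValueError("table total must be >= 1")
    if r1 == 0 or r2 == 0 or c1 == 0 or (n - c1) == 0:
        warnings.warn("zero margin in 2x2 table; independence p-value set to 1")
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    observed = weights[a]
    total = sum(w for w in weights.values() if w <= observed)
    return total / comb(n, c1)


# --------------------------------------------------------------------- report
@dataclass
class ModelTestReport:
    n_male_primed: int
    n_female_primed: int
    p_female_model: float
    p_male_model: float
    p_balanced: float
    excluded: frozenset
    surviving: frozenset
    selected: str
    p_independence: float | None = None
    denominators: tuple | None = None  # (n_male_markers, n_female_markers)

    def to_dict(self) -> dict:
        return {
            "n_male_primed": self.n_male_primed,
            "n_female_primed": self.n_female_primed,
            "p_female_model": self.p_female_model,
            "p_male_model": self.p_male_model,
            "p_balanced": self.p_balanced,
            "excluded": sorted(self.excluded),
            "surviving": sorted(self.surviving),
            "selected": self.selected,
            "p_independence": self.p_independence,
            "denominators": self.denominators,
        }


def test_models(
    n_male: int, n_female: int, cfg: ThresholdConfig | None = None
) -> ModelTestReport:
    """Exact binomial tests of the female / male / balanced models.

    A biased model (male_biased / female_biased, by majority sex) is
    selected only when all three extreme models are excluded; if exactly
    one model survives it is selected; otherwise the outcome is
    ``indeterminate`` with the surviving models listed.
    """
    cfg = cfg or ThresholdConfig()
    n = n_male + n_female
    if n < 1:
        raise ValueError("need at least one primed gene")
    p0 = cfg.model_extreme_fraction
    pvals = {
        "female": binom_pvalue_one_tailed(n_female, n, p0),
        "male": binom_pvalue_one_tailed(n_male, n, p0),
        "balanced": binom_pvalue_two_tailed(n_female, n, 0.5),
    }
    excluded = frozenset(m for m, p in pvals.items() if p < cfg.alpha_model)
    surviving = frozenset(pvals) - excluded
    if not surviving:
        if n_male > n_female:
            selected = "male_biased"
        elif n_female > n_male:
            selected = "female_biased"
        else:
            selected = "indeterminate"
    elif len(surviving) == 1:
        selected = next(iter(surviving))
    else:
        selected = "indeterminate"
    return ModelTestReport(
        n_male_primed=n_male,
        n_female_primed=n_female,
        p_female_model=pvals["female"],
        p_male_model=pvals["male"],
        p_balanced=pvals["balanced"],
        excluded=excluded,
        surviving=surviving,
        selected=selected,
    )


def test_independence(
    primed_m: int, notprimed_m: int, primed_f: int, notprimed_f: int
) -> float:
    """Two-sided exact independence test of sex x primed status."""
    return fisher_two_sided(primed_m, notprimed_m, primed_f, notprimed_f)


def bias_report(priming_result, cfg: ThresholdConfig | None = None) -> ModelTestReport:
    """Model tests for one priming analysis, at gene-level counts.

    Counts are gene-level deduplicated (each symbol once); the independence
    table uses actual gene counts: primed vs not-primed markers per sex.
    """
    cfg = cfg or ThresholdConfig()
    n_male = priming_result.male_primed.gene_level_count
    n_female = priming_result.female_primed.gene_level_count
    report = test_models(n_male, n_female, cfg)
    m_markers = priming_result.male_markers.gene_level_count
    f_markers = priming_result.female_markers.gene_level_count
    report.denominators = (m_markers, f_markers)
    report.p_independence = test_independence(
        n_male, m_markers - n_male, n_female, f_markers - n_female
    )
    return report
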