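"""The co-double test: within- vs among-lineage patterns against the 1:2 null.

Under a preradiation topology and double substitutions only, a double
substitution is twice as likely to produce an among-lineage pattern as
a within-lineage one, so conditional on the total number N of double
patterns the within count is Binomial(N, 1/3).  Gene conversion can
mimic only the within-lineage patterns, so an excess of within
patterns over the 1:2 ratio is evidence for conversion; the test is
one-sided (upper tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_N_DRAWS = 10**6
DEFAULT_SEED = 20170912
NULL_WITHIN_PROB = 1.0 / 3.0


@dataclass(frozen=True)
class ConversionTestResult:
    """Result of the co-double test for one gene."""

    within: int
    among: int
    p_one_sided_exact: float
    p_one_sided_mc: float
    n_draws: int
    seed: int
    chi2_stat: float
    p_chi2_two_sided: float

    @property
    def n_total(self) -> int:
        return self.within + self.among

    def to_dict(self) -> dict:
        return {
            "within": self.within,
            "among": self.among,
            "n_total": self.n_total,
            "p_one_sided_exact": self.p_one_sided_exact,
            "p_one_sided_mc": self.p_one_sided_mc,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "chi2_stat": self.chi2_stat,
            "p_chi2_two_sided": self.p_chi2_two_sided,
        }


def _check_counts(within: int, among: int) -> int:
    if within < 0 or among < 0:
        raise ValueError("counts must be non-negative")
    n = within + among
    if n < 1:
        raise ValueError("within + among must be >= 1")
    return n


def exact_tail_p(within: int, among: int) -> float:
    """Upper-tail binomial probability P(X >= within), X ~ Bin(N, 1/3)."""
    n = _check_counts(within, among)
    return float(stats.binom.sf(within - 1, n, NULL_WITHIN_PROB))


def codouble_test(
    within: int,
    among: int,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = DEFAULT_SEED,
    rng: np.random.Generator | None = None,
) -> ConversionTestResult:
    """Run the one-sided co-double test on within/among pattern counts.

    The exact upper-tail binomial sum is the headline p-value; a
    Monte-Carlo version (proportion of Binomial(N, 1/3) draws at least
    as extreme as the observed within count, with the add-one
    correction so it is never exactly zero) is reported alongside.
    A two-sided chi-square goodness-of-fit against expected counts
    (N/3, 2N/3), one degree of freedom, no continuity correction, is
    included for reference.
    """
    n = _check_counts(within, among)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.binomial(n, NULL_WITHIN_PROB, size=n_draws)
    p_mc = (1 + int((draws >= within).sum())) / (n_draws + 1)
    chi2, p_chi2 = chisq_ratio_test(within, among)
    return ConversionTestResult(
        within=within,
        among=among,
        p_one_sided_exact=exact_tail_p(within, among),
        p_one_sided_mc=float(p_mc),
        n_draws=n_draws,
        seed=seed,
        chi2_stat=chi2,
        p_chi2_two_sided=p_chi2,
    )


def chisq_ratio_test(within: int, among: int) -> tuple[float, float]:
    """Two-sided chi-square goodness of fit of (within, among) to 1:2.

    Expected counts are (N/3, 2N/3); one degree of freedom; no
    continuity correction.
    """
    n = _check_counts(within, among)
    e_within = n / 3.0
    e_among = 2.0 * n / 3.0
    chi2 = (within - e_within) ** 2 / e_within + (among - e_among) ** 2 / e_among
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
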