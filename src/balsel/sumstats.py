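"""Region-level diversity and site-frequency-spectrum neutrality tests.

Implements Watterson's theta, nucleotide diversity pi, Tajima's D and
Fu & Li's starred statistics D* and F* (folded, no outgroup needed), with
two significance routes: an empirical percentile rank against a panel of
reference windows, and a simulation p-value against a coalescent null
distribution.

Tajima's D uses the original 1989 variance constants.  The starred Fu & Li
statistics use the corrected variance constants of the standard follow-up
literature (the Simonsen-Churchill-Aquadro forms), with singletons counted
on the folded spectrum (minor-allele count of one).  Statistics that are
undefined when a region has no segregating sites raise
:class:`UndefinedStatistic` rather than returning a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from balsel.haplotypes import HaplotypeAlignment, ReferencePanel


class UndefinedStatistic(ValueError):
    """Raised when a statistic does not exist for the given data (S=0)."""


@lru_cache(maxsize=4096)
def harmonic(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i."""
    return float(np.sum(1.0 / np.arange(1, k + 1)))


@lru_cache(maxsize=4096)
def harmonic_sq(k: int) -> float:
    """b_k = sum_{i=1}^{k} 1/i^2."""
    return float(np.sum(1.0 / np.arange(1, k + 1) ** 2))


# ----------------------------------------------------------------------
# Estimators
# ----------------------------------------------------------------------

def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's estimator per site: S / (a_{n-1} * L)."""
    if n < 2:
        raise ValueError("Watterson's theta requires n >= 2 chromosomes")
    if L <= 0:
        raise ValueError("sequence length must be positive")
    if S == 0:
        return 0.0
    return S / (harmonic(n - 1) * L)


def _pairwise_pi_locus(aln: HaplotypeAlignment) -> float:
    """Mean pairwise difference count per chromosome pair (whole locus)."""
    n = aln.n_hap
    if n < 2:
        raise ValueError("pi requires n >= 2 chromosomes")
    d = aln.derived_counts().astype(float)
    m = aln.sample_sizes().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(m > 1, d * (m - d) / (m * (m - 1) / 2.0), 0.0)
    return float(per_site.sum())


def nucleotide_diversity(aln: HaplotypeAlignment) -> float:
    """Per-site pi: mean pairwise Hamming distance / L_effective."""
    return _pairwise_pi_locus(aln) / aln.l_effective


def _seg_counts(aln: HaplotypeAlignment) -> tuple[int, int, int]:
    """(n, S, singletons) on the folded spectrum."""
    seg = aln.segregating()
    S = int(seg.sum())
    minor = aln.minor_counts()
    eta_s = int(np.sum(seg & (minor == 1)))
    return aln.n_hap, S, eta_s


def tajimas_d(aln: HaplotypeAlignment) -> float:
    """Tajima's D with the original variance constants."""
    n, S, _ = _seg_counts(aln)
    if S == 0:
        raise UndefinedStatistic("Tajima's D undefined when S=0")
    a1 = harmonic(n - 1)
    a2 = harmonic_sq(n - 1)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    pi = _pairwise_pi_locus(aln)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # n=3 degenerates: both variance constants vanish
        raise UndefinedStatistic(f"Tajima's D variance is 0 at n={n}, S={S}")
    return (pi - S / a1) / math.sqrt(var)


def _fu_li_common(n: int) -> tuple[float, float, float]:
    a = harmonic(n - 1)
    b = harmonic_sq(n - 1)
    if n == 2:
        c = 1.0
    else:
        c = 2.0 * (n * a - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    return a, b, c


def fu_li_dstar(aln: HaplotypeAlignment) -> float:
    """Fu & Li's D*: total polymorphism versus folded singletons."""
    n, S, eta_s = _seg_counts(aln)
    if S == 0:
        raise UndefinedStatistic("Fu & Li's D* undefined when S=0")
    if n < 3:
        raise UndefinedStatistic("D* requires n >= 3")
    a, b, c = _fu_li_common(n)
    an1 = a + 1.0 / n  # a_{n} over sample of n+1 terms
    d = (
        c
        + (n - 2.0) / ((n - 1.0) ** 2)
        + (2.0 / (n - 1.0))
        * (1.5 - (2.0 * an1 - 3.0) / (n - 2.0) - 1.0 / n)
    )
    v = (
        (n / (n - 1.0)) ** 2 * b
        + a ** 2 * d
        - 2.0 * (n * a * (a + 1.0)) / ((n - 1.0) ** 2)
    ) / (a ** 2 + b)
    u = (n / (n - 1.0)) * (a - n / (n - 1.0)) - v
    num = (n / (n - 1.0)) * S - a * eta_s
    return num / math.sqrt(u * S + v * S * S)


def fu_li_fstar(aln: HaplotypeAlignment) -> float:
    """Fu & Li's F*: pairwise diversity versus folded singletons."""
    n, S, eta_s = _seg_counts(aln)
    if S == 0:
        raise UndefinedStatistic("Fu & Li's F* undefined when S=0")
    if n < 3:
        raise UndefinedStatistic("F* requires n >= 3")
    a, b, _ = _fu_li_common(n)
    an1 = a + 1.0 / n
    # corrected variance constants (Simonsen-Churchill-Aquadro forms)
    v = (
        (2.0 * n ** 3 + 110.0 * n ** 2 - 255.0 * n + 153.0)
        / (9.0 * n ** 2 * (n - 1.0))
        + 2.0 * (n - 1.0) * a / n ** 2
        - 8.0 * b / n
    ) / (a ** 2 + b)
    u = (
        (
            4.0 * n ** 2 + 19.0 * n + 3.0 - 12.0 * (n + 1.0) * an1
        )
        / (3.0 * n * (n - 1.0))
    ) / a - v
    pi = _pairwise_pi_locus(aln)
    num = pi - ((n - 1.0) / n) * eta_s
    return num / math.sqrt(u * S + v * S * S)


# ----------------------------------------------------------------------
# Aggregate result
# ----------------------------------------------------------------------

@dataclass
class DiversityResult:
    """Per-region summary: counts, diversity and neutrality statistics.

    ``tajima_d``, ``fu_li_dstar`` and ``fu_li_fstar`` are ``None`` when
    undefined (no segregating sites); they are never reported as zero.
    """

    n: int
    S: int
    eta: int
    eta_s: int
    pi: float
    theta_w: float
    tajima_d: float | None
    fu_li_dstar: float | None
    fu_li_fstar: float | None
    l_effective: int
    population: str | None = None


def diversity(aln: HaplotypeAlignment, population: str | None = None) -> DiversityResult:
    """Compute the full per-region diversity summary.

    Under infinite sites the total mutation count eta equals S; on real
    data with recurrent mutation only biallelic states are retained by the
    readers, so eta == S holds here by construction and both are reported.
    """
    if population is not None:
        aln = aln.for_population(population)
    n, S, eta_s = _seg_counts(aln)
    pi = nucleotide_diversity(aln)
    thw = watterson_theta(S, n, aln.l_effective)

    def _maybe(fn):
        try:
            return fn(aln)
        except UndefinedStatistic:
            return None

    return DiversityResult(
        n=n,
        S=S,
        eta=S,
        eta_s=eta_s,
        pi=pi,
        theta_w=thw,
        tajima_d=_maybe(tajimas_d),
        fu_li_dstar=_maybe(fu_li_dstar),
        fu_li_fstar=_maybe(fu_li_fstar),
        l_effective=aln.l_effective,
        population=population,
    )


# ----------------------------------------------------------------------
# Significance
# ----------------------------------------------------------------------

def empirical_rank(value: float, panel: ReferencePanel | np.ndarray) -> float:
    """Midrank percentile of ``value`` in the panel.

    Proportion of panel entries strictly below the observation plus half
    of the ties, divided by the panel size.
    """
    vals = panel.values if isinstance(panel, ReferencePanel) else np.asarray(panel)
    if vals.size == 0:
        raise ValueError("empty reference panel")
    below = np.sum(vals < value)
    ties = np.sum(vals == value)
    return float((below + 0.5 * ties) / vals.size)


def sim_pvalue(
    observed: float,
    null: ReferencePanel | np.ndarray,
    side: str = "two-sided",
) -> float:
    """Monte-Carlo p-value (r+1)/(m+1) against a simulated null panel.

    ``r`` counts null values at least as extreme as the observation in
    the stated direction; two-sided doubles the smaller tail (capped at 1).
    """
    vals = null.values if isinstance(null, ReferencePanel) else np.asarray(null)
    if vals.size == 0:
        raise ValueError("empty null panel")
    m = vals.size
    p_greater = (np.sum(vals >= observed) + 1.0) / (m + 1.0)
    p_less = (np.sum(vals <= observed) + 1.0) / (m + 1.0)
    if side == "greater":
        return float(p_greater)
    if side == "less":
        return float(p_less)
    if side == "two-sided":
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"unknown side {side!r}")


#: Named statistics usable by the simulator's null-distribution machinery.
STATISTIC_REGISTRY = {
    "S": lambda aln: float(aln.segregating().sum()),
    "pi": nucleotide_diversity,
    "pi_locus": _pairwise_pi_locus,
    "theta_w": lambda aln: watterson_theta(
        int(aln.segregating().sum()), aln.n_hap, aln.l_effective
    ),
    "tajimas_d": tajimas_d,
    "fu_li_dstar": fu_li_dstar,
    "fu_li_fstar": fu_li_fstar,
}
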