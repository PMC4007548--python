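"""Divergence-calibrated TMRCA estimation under infinite sites.

The mutation rate is calibrated from the number of fixed differences to
an outgroup species: with F fixed differences over L callable bases and a
species split t_split years ago, mu_year = F / (L * 2 * t_split) per site
per year (the factor two counts both branches since the split).

The TMRCA estimator is the average, over sampled chromosomes, of the
number of derived alleles each carries — i.e. the mean mutational
distance to the most recent common ancestor, which under infinite sites
is the all-ancestral haplotype — converted to years by mu_year * L.
Because the coalescent tree is ultrametric in real time, this mean
distance estimates mu * TMRCA without bias under neutrality.

The estimator assumes an infinite-sites genealogy without recombination,
so sites violating four-gamete compatibility are removed first (greedy
minimal removal, sites only, never chromosomes).  The standard deviation
comes from a parametric bootstrap: coalescent replicates matched to the
data's Watterson theta, the estimator applied to each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from balsel.haplotypes import HaplotypeAlignment
from balsel.sumstats import harmonic

logger = logging.getLogger(__name__)


class TmrcaError(ValueError):
    pass


# ----------------------------------------------------------------------
# Infinite-sites compatibility filter
# ----------------------------------------------------------------------

def four_gamete_violations(H: np.ndarray) -> np.ndarray:
    """Count, per site, the partner sites with all four gametes present."""
    n, S = H.shape
    viol = np.zeros(S, dtype=np.int64)
    Hf = H.astype(np.int8)
    for i in range(S):
        a = Hf[:, i]
        for j in range(i + 1, S):
            b = Hf[:, j]
            g = {(int(x), int(y)) for x, y in zip(a, b)}
            if len(g) == 4:
                viol[i] += 1
                viol[j] += 1
    return viol


def infinite_sites_filter(
    aln: HaplotypeAlignment,
) -> tuple[HaplotypeAlignment, list[int]]:
    """Remove sites until the alignment passes the four-gamete test.

    Greedy: repeatedly drop the site involved in the most violations
    (leftmost on ties) until none remain.  Returns the filtered alignment
    and the removed site positions.
    """
    keep = np.arange(aln.n_sites)
    removed: list[int] = []
    H = aln.H
    while True:
        viol = four_gamete_violations(H[:, keep])
        if viol.max(initial=0) == 0:
            break
        worst = int(np.argmax(viol))  # argmax takes leftmost tie
        removed.append(int(aln.positions[keep[worst]]))
        keep = np.delete(keep, worst)
    if removed:
        logger.info("removed %d sites violating infinite sites", len(removed))
    return aln.take_sites(keep), removed


# ----------------------------------------------------------------------
# Mutation-rate calibration
# ----------------------------------------------------------------------

@dataclass
class MuCalibration:
    F: int                  # fixed differences to the outgroup
    L: float                # aligned callable length (bp)
    t_split: float          # species split, years
    g: float                # generation time, years
    mu_year: float          # per site per year
    mu_gen: float           # per site per generation
    mu_locus_gen: float     # per locus per generation


def calibrate_mu(
    F: int,
    L: float,
    t_split: float = 6.0e6,
    g: float = 25.0,
) -> MuCalibration:
    """Mutation rate from outgroup divergence: mu_year = F/(L * 2 * t_split)."""
    if F <= 0:
        raise TmrcaError("no fixed differences: cannot calibrate mu")
    if L <= 0 or t_split <= 0 or g <= 0:
        raise TmrcaError("L, t_split and g must be positive")
    mu_year = F / (L * 2.0 * t_split)
    mu_gen = mu_year * g
    return MuCalibration(
        F=int(F),
        L=float(L),
        t_split=float(t_split),
        g=float(g),
        mu_year=mu_year,
        mu_gen=mu_gen,
        mu_locus_gen=mu_gen * L,
    )


# ----------------------------------------------------------------------
# Pairwise-difference TMRCA
# ----------------------------------------------------------------------

@dataclass
class TmrcaEstimate:
    years: float
    sd_years: float | None
    method: str
    n: int
    sites_used: int


def pairwise_diff_tmrca(
    aln: HaplotypeAlignment, cal: MuCalibration
) -> TmrcaEstimate:
    """Mean derived-allele load per chromosome, converted to years.

    Requires a polarized, infinite-sites-compatible alignment; the MRCA
    is the all-ancestral haplotype.
    """
    if aln.n_sites and not bool(np.all(aln.polarized)):
        raise TmrcaError(
            "unpolarized sites present: polarize and filter before TMRCA"
        )
    load = (aln.H == 1).sum(axis=1)
    mean_load = float(np.mean(load)) if aln.n_hap else 0.0
    years = mean_load / (cal.mu_year * cal.L)
    return TmrcaEstimate(
        years=years,
        sd_years=None,
        method="pairwise_diff_to_mrca",
        n=aln.n_hap,
        sites_used=aln.n_sites,
    )


def tmrca_sd(
    aln: HaplotypeAlignment,
    cal: MuCalibration,
    replicates: int = 1000,
    seed: int = 0,
) -> float:
    """Parametric-bootstrap SD of the pairwise-difference TMRCA.

    Coalescent replicates are generated at the effective size implied by
    the data's per-locus Watterson theta and the calibrated mutation
    rate; the estimator is applied to each replicate and the SD of the
    replicate estimates returned.
    """
    from balsel.coalsim import DemographicModel, SimConfig, simulate

    S = int(aln.segregating().sum())
    if S == 0:
        raise TmrcaError("monomorphic data: TMRCA degenerate, SD refused")
    if replicates < 100:
        logger.warning("fewer than 100 bootstrap replicates: SD is noisy")
    n = aln.n_hap
    theta_locus = S / harmonic(n - 1)
    ne = theta_locus / (4.0 * cal.mu_locus_gen)
    cfg = SimConfig(
        n=[n],
        L=int(cal.L),
        theta=theta_locus,
        seed=seed,
        iterations=replicates,
    )
    model = DemographicModel.constant(ne)
    ests = [
        pairwise_diff_tmrca(rep.alignment, cal).years
        for rep in simulate(cfg, model)
    ]
    return float(np.std(ests, ddof=1))


# ----------------------------------------------------------------------
# Effective population size
# ----------------------------------------------------------------------

@dataclass
class NeEstimate:
    ne: float
    theta_locus: float
    mu_locus_gen: float
    theta_source: str


def estimate_ne(
    theta_locus: float,
    cal: MuCalibration,
    theta_source: str = "watterson",
) -> NeEstimate:
    """N_e = theta_locus / (4 * mu_locus_per_generation)."""
    if theta_locus <= 0:
        raise TmrcaError("theta must be positive")
    ne = theta_locus / (4.0 * cal.mu_locus_gen)
    return NeEstimate(
        ne=ne,
        theta_locus=theta_locus,
        mu_locus_gen=cal.mu_locus_gen,
        theta_source=theta_source,
    )
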