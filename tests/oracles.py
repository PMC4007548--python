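"""Independent brute-force reference implementations.

Everything here is written directly from the published formulas as plain
double loops over chromosomes and sites, with the variance constants
derived inline, and is kept deliberately separate from the package's
vectorised code paths so the two can be compared as independent routes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pi_locus_bruteforce(H: np.ndarray) -> float:
    """Mean pairwise Hamming distance over all chromosome pairs."""
    n = H.shape[0]
    total = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int(np.sum(H[i] != H[j]))
        pairs += 1
    return total / pairs


def segregating_sites(H: np.ndarray) -> int:
    S = 0
    for j in range(H.shape[1]):
        col = H[:, j]
        if 0 < col.sum() < len(col):
            S += 1
    return S


def folded_singletons(H: np.ndarray) -> int:
    eta_s = 0
    n = H.shape[0]
    for j in range(H.shape[1]):
        c = int(H[:, j].sum())
        if min(c, n - c) == 1:
            eta_s += 1
    return eta_s


def tajimas_d_bruteforce(H: np.ndarray) -> float:
    n, _ = H.shape
    S = segregating_sites(H)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = pi_locus_bruteforce(H)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fu_li_dstar_bruteforce(H: np.ndarray) -> float:
    n, _ = H.shape
    S = segregating_sites(H)
    eta_s = folded_singletons(H)
    a = sum(1.0 / i for i in range(1, n))
    b = sum(1.0 / i**2 for i in range(1, n))
    an1 = a + 1.0 / n
    c = 1.0 if n == 2 else 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    d = c + (n - 2) / (n - 1) ** 2 + (2 / (n - 1)) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n
    )
    v = (
        (n / (n - 1)) ** 2 * b
        + a**2 * d
        - 2 * (n * a * (a + 1)) / (n - 1) ** 2
    ) / (a**2 + b)
    u = (n / (n - 1)) * (a - n / (n - 1)) - v
    return ((n / (n - 1)) * S - a * eta_s) / math.sqrt(u * S + v * S**2)


def fu_li_fstar_bruteforce(H: np.ndarray) -> float:
    n, _ = H.shape
    S = segregating_sites(H)
    eta_s = folded_singletons(H)
    a = sum(1.0 / i for i in range(1, n))
    b = sum(1.0 / i**2 for i in range(1, n))
    an1 = a + 1.0 / n
    v = (
        (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
        + 2 * (n - 1) * a / n**2
        - 8 * b / n
    ) / (a**2 + b)
    u = (
        (4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1) / (3 * n * (n - 1))
    ) / a - v
    pi = pi_locus_bruteforce(H)
    return (pi - ((n - 1) / n) * eta_s) / math.sqrt(u * S + v * S**2)


def wc_fst_bruteforce(counts, sizes) -> float:
    """Two-or-more-population Weir-Cockerham theta for haploid samples."""
    counts = [float(c) for c in counts]
    sizes = [float(s) for s in sizes]
    r = len(sizes)
    p = [c / s for c, s in zip(counts, sizes)]
    nbar = sum(sizes) / r
    nc = (r * nbar - sum(s**2 for s in sizes) / (r * nbar)) / (r - 1)
    pbar = sum(s * pi for s, pi in zip(sizes, p)) / (r * nbar)
    s2 = sum(s * (pi - pbar) ** 2 for s, pi in zip(sizes, p)) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    return a / (a + b)


def ld_bruteforce(x: np.ndarray, y: np.ndarray):
    """(D, Dprime, r2) from two phased 0/1 columns by direct counting."""
    n = len(x)
    p11 = float(np.sum((x == 1) & (y == 1))) / n
    pa = float(x.sum()) / n
    pb = float(y.sum()) / n
    D = p11 - pa * pb
    if D >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = D / dmax if dmax else 0.0
    r2 = D * D / (pa * (1 - pa) * pb * (1 - pb))
    return D, dprime, r2


def four_gamete_ok(H: np.ndarray) -> bool:
    """Full pairwise audit: True when no site pair shows all 4 gametes."""
    S = H.shape[1]
    for i, j in itertools.combinations(range(S), 2):
        gametes = {(int(a), int(b)) for a, b in zip(H[:, i], H[:, j])}
        if len(gametes) == 4:
            return False
    return True
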