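"""Population differentiation: Weir-Cockerham F_ST, sliding windows, outliers.

Per-site estimates use the Weir & Cockerham (1984) variance-components
theta for haploid (phased haplotype) samples; windowed estimates combine
sites by the ratio of summed numerator and denominator components, the
standard weighting for multi-site estimates.  Negative estimates are
reported as computed, never clamped.

Outlier machinery follows the two designs used for genome scans: windows
are compared against the percentile of a reference window distribution,
and single variants are compared within minor-allele-frequency quantile
classes (by default 50 classes, 95th percentile), so that the threshold is
conditioned on the allele-frequency dependence of F_ST.

Percentiles use the classic nearest-rank convention throughout (the
ceil(p*N)-th smallest panel value), applied identically to MAF-class and
reference-window thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from balsel.haplotypes import MISSING, HaplotypeAlignment, ReferencePanel

logger = logging.getLogger(__name__)

UNDEFINED = float("nan")


def _wc_components(
    counts: np.ndarray, sizes: np.ndarray
) -> tuple[float, float]:
    """Weir-Cockerham (a, b) variance components at one biallelic site.

    ``counts``: allele-1 count per population; ``sizes``: haploid sample
    size per population.  For haploid data the within-individual component
    c vanishes and theta = a / (a + b).
    """
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    keep = sizes > 0
    counts, sizes = counts[keep], sizes[keep]
    r = len(sizes)
    if r < 2:
        raise ValueError("need >= 2 populations with sampled alleles")
    p = counts / sizes
    nbar = sizes.mean()
    nc = (r * nbar - (sizes ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (sizes * p).sum() / (r * nbar)
    s2 = (sizes * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    if pbar in (0.0, 1.0):
        return UNDEFINED, UNDEFINED
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r
    )
    return float(a), float(b)


def wc_fst(counts: np.ndarray, sizes: np.ndarray) -> float:
    """Per-site Weir-Cockerham theta; NaN if monomorphic across pops."""
    a, b = _wc_components(counts, sizes)
    if np.isnan(a):
        return UNDEFINED
    denom = a + b
    if denom == 0:
        return UNDEFINED
    return a / denom


def _per_pop_counts(aln: HaplotypeAlignment) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(counts, sizes) arrays of shape (n_pops, n_sites)."""
    pops = aln.populations
    labels = np.asarray(aln.pop_labels)
    counts = np.stack([( aln.H[labels == p] == 1).sum(axis=0) for p in pops])
    sizes = np.stack([( aln.H[labels == p] != MISSING).sum(axis=0) for p in pops])
    return counts, sizes, pops


def site_fst(aln: HaplotypeAlignment) -> np.ndarray:
    """Multi-population per-site Weir-Cockerham theta for every site."""
    counts, sizes, _ = _per_pop_counts(aln)
    out = np.empty(aln.n_sites)
    for j in range(aln.n_sites):
        out[j] = wc_fst(counts[:, j], sizes[:, j])
    return out


@dataclass
class FstWindow:
    index: int
    first_pos: int
    last_pos: int
    n_snps: int
    pair: tuple[str, str]
    fst: float
    percentile: float | None = None
    outlier: bool | None = None
    truncated: bool = False


def window_fst(
    aln: HaplotypeAlignment,
    window_snps: int = 20,
    step_snps: int = 3,
) -> list[FstWindow]:
    """Sliding-window F_ST: windows of ``window_snps`` SNPs, SNP-index step.

    One record per population pair per window; the window value is the
    ratio of the summed a-components to the summed (a+b)-components over
    the sites of the window.  With fewer usable SNPs than one window a
    single truncated window is returned with a warning.
    """
    seg = np.flatnonzero(aln.segregating())
    counts, sizes, pops = _per_pop_counts(aln)
    S = len(seg)
    if S == 0:
        raise ValueError("no segregating sites for window scan")
    if S < window_snps:
        logger.warning(
            "only %d usable SNPs (< window of %d): single truncated window",
            S,
            window_snps,
        )
        starts = [0]
    else:
        starts = list(range(0, S - window_snps + 1, step_snps))

    out: list[FstWindow] = []
    for w_idx, s0 in enumerate(starts):
        idx = seg[s0 : s0 + window_snps]
        truncated = len(idx) < window_snps
        for pa, pb in combinations(range(len(pops)), 2):
            num = 0.0
            den = 0.0
            for j in idx:
                a, b = _wc_components(
                    counts[[pa, pb], j], sizes[[pa, pb], j]
                )
                if np.isnan(a):
                    continue
                num += a
                den += a + b
            fst = num / den if den != 0 else UNDEFINED
            out.append(
                FstWindow(
                    index=w_idx,
                    first_pos=int(aln.positions[idx[0]]),
                    last_pos=int(aln.positions[idx[-1]]),
                    n_snps=len(idx),
                    pair=(pops[pa], pops[pb]),
                    fst=fst,
                    truncated=truncated,
                )
            )
    return out


# ----------------------------------------------------------------------
# Outlier calling
# ----------------------------------------------------------------------

def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Classic nearest-rank percentile: ceil(pct/100 * N)-th smallest."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty panel")
    rank = int(np.ceil(pct / 100.0 * values.size))
    rank = min(max(rank, 1), values.size)
    return float(values[rank - 1])


def reference_threshold(
    panel: ReferencePanel | np.ndarray, pct: float = 95.0
) -> float:
    """Percentile threshold from a reference distribution of window F_ST."""
    vals = panel.values if isinstance(panel, ReferencePanel) else np.asarray(panel)
    return nearest_rank_percentile(vals, pct)


@dataclass
class MafBinning:
    n_bins: int
    edges: np.ndarray          # bin edges over [0, 0.5]
    thresholds: np.ndarray     # per-bin percentile threshold


def maf_bin_outliers(
    site_values: np.ndarray,
    mafs: np.ndarray,
    bins: int = 50,
    pct: float = 95.0,
) -> tuple[np.ndarray, MafBinning]:
    """Flag per-SNP values above the percentile of their MAF quantile class.

    Quantile class edges are taken over the whole panel's MAF
    distribution; classes left empty by ties are merged with their left
    neighbour (logged).  Returns (flags, binning).
    """
    site_values = np.asarray(site_values, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if site_values.shape != mafs.shape:
        raise ValueError("site_values and mafs must align")
    ok = np.isfinite(site_values) & np.isfinite(mafs)
    if not np.any(ok):
        raise ValueError("no finite sites to bin")

    qs = np.linspace(0, 1, bins + 1)
    edges = np.quantile(mafs[ok], qs)
    edges[0], edges[-1] = 0.0, max(0.5, edges[-1])
    edges = np.unique(edges)
    n_merged = bins - (len(edges) - 1)
    if n_merged > 0:
        logger.info("merged %d empty/tied MAF classes with neighbours", n_merged)

    cls = np.clip(np.searchsorted(edges, mafs, side="right") - 1, 0, len(edges) - 2)
    flags = np.zeros(site_values.shape, dtype=bool)
    thresholds = np.full(len(edges) - 1, np.nan)
    for c in range(len(edges) - 1):
        members = ok & (cls == c)
        if not np.any(members):
            continue
        thr = nearest_rank_percentile(site_values[members], pct)
        thresholds[c] = thr
        flags[members] = site_values[members] > thr
    binning = MafBinning(n_bins=len(edges) - 1, edges=edges, thresholds=thresholds)
    return flags, binning


def windows_to_frame(windows: list[FstWindow]):
    """BED-like table (chrom-less) of a window scan."""
    import pandas as pd

    return pd.DataFrame(
        {
            "window": [w.index for w in windows],
            "start": [w.first_pos for w in windows],
            "end": [w.last_pos for w in windows],
            "pair": ["/".join(w.pair) for w in windows],
            "n_snps": [w.n_snps for w in windows],
            "fst": [w.fst for w in windows],
            "percentile": [w.percentile for w in windows],
            "outlier": [w.outlier for w in windows],
            "truncated": [w.truncated for w in windows],
        }
    )
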