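"""Phased haplotype region data model and readers/writers.

The central container is :class:`HaplotypeAlignment`: an ``n_hap x n_site``
0/1 matrix of phased haplotypes over the biallelic segregating sites of a
genomic region, together with 1-based physical coordinates, per-haplotype
population labels, an optional per-site outgroup allele and per-site
polarization flags.  Coordinates are 1-based inclusive throughout.

Missing data follow an all-or-none column rule: an alignment column
containing any gap/N among the ingroup is removed from both the site set
and the effective length ``L_effective``, so that per-site statistics are
normalised by the number of bases actually screened in every chromosome.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1


class HapDataError(ValueError):
    """Malformed or inconsistent haplotype input."""


@dataclass
class HaplotypeAlignment:
    """Phased 0/1 haplotypes at the biallelic sites of one region.

    Attributes
    ----------
    chrom : str
        Chromosome / contig identifier.
    start, end : int
        1-based inclusive physical bounds of the region.
    positions : ndarray of int
        1-based site coordinates, strictly increasing, within [start, end].
    H : ndarray, shape (n_hap, n_site)
        Allele codes: 0 (ancestral once polarized, otherwise reference
        allele), 1 (derived/alternate).
    sample_ids : list of str
        One id per haplotype (chromosome copy).
    pop_labels : list of str
        Population tag per haplotype.
    alleles : list of (str, str) or None
        Nucleotide spelt by codes 0 and 1 at each site, when known.
    outgroup : ndarray of int or None
        Per-site outgroup allele code: 0, 1, or -1 when the outgroup is
        missing or carries a third state.
    polarized : ndarray of bool
        True where code 0 is established as ancestral.
    l_effective : int
        Gap-adjusted length in bp (callable bases), <= physical length.
    fixed_diffs : int or None
        Ingroup-monomorphic callable positions at which the ingroup differs
        from the outgroup (set by readers that see the full alignment).
    """

    chrom: str
    start: int
    end: int
    positions: np.ndarray
    H: np.ndarray
    sample_ids: list[str]
    pop_labels: list[str]
    alleles: list[tuple[str, str]] | None = None
    outgroup: np.ndarray | None = None
    polarized: np.ndarray | None = None
    l_effective: int | None = None
    fixed_diffs: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.H = np.asarray(self.H, dtype=np.int8)
        if self.H.ndim != 2:
            raise HapDataError("haplotype matrix must be 2-D")
        n_hap, n_site = self.H.shape
        if len(self.sample_ids) != n_hap or len(self.pop_labels) != n_hap:
            raise HapDataError(
                "sample_ids/pop_labels length does not match haplotype count"
            )
        if self.positions.shape != (n_site,):
            raise HapDataError("positions length does not match site count")
        if n_site and (
            np.any(np.diff(self.positions) <= 0)
            or self.positions[0] < self.start
            or self.positions[-1] > self.end
        ):
            raise HapDataError(
                "positions must be strictly increasing within [start, end]"
            )
        if self.polarized is None:
            self.polarized = np.zeros(n_site, dtype=bool)
        else:
            self.polarized = np.asarray(self.polarized, dtype=bool)
        if self.outgroup is not None:
            self.outgroup = np.asarray(self.outgroup, dtype=np.int8)
        if self.l_effective is None:
            self.l_effective = self.l_physical
        if self.l_effective > self.l_physical:
            raise HapDataError("L_effective cannot exceed physical length")
        ok = (self.H == 0) | (self.H == 1) | (self.H == MISSING)
        if not bool(np.all(ok)):
            raise HapDataError("haplotype matrix entries must be 0, 1 or -1")

    # -- basic geometry -------------------------------------------------
    @property
    def n_hap(self) -> int:
        return self.H.shape[0]

    @property
    def n_sites(self) -> int:
        return self.H.shape[1]

    @property
    def l_physical(self) -> int:
        return self.end - self.start + 1

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    # -- allele counting ------------------------------------------------
    def derived_counts(self) -> np.ndarray:
        """Per-site count of the '1' allele among non-missing haplotypes."""
        return np.asarray((self.H == 1).sum(axis=0), dtype=np.int64)

    def sample_sizes(self) -> np.ndarray:
        """Per-site number of non-missing haplotypes."""
        return np.asarray((self.H != MISSING).sum(axis=0), dtype=np.int64)

    def minor_counts(self) -> np.ndarray:
        d = self.derived_counts()
        return np.minimum(d, self.sample_sizes() - d)

    def segregating(self) -> np.ndarray:
        d = self.derived_counts()
        return (d > 0) & (d < self.sample_sizes())

    # -- subsetting -----------------------------------------------------
    def for_population(self, pop: str) -> "HaplotypeAlignment":
        """Restrict to one population; sites monomorphic there are kept."""
        keep = [i for i, p in enumerate(self.pop_labels) if p == pop]
        if not keep:
            raise HapDataError(f"no haplotypes labelled {pop!r}")
        return replace(
            self,
            H=self.H[keep],
            sample_ids=[self.sample_ids[i] for i in keep],
            pop_labels=[self.pop_labels[i] for i in keep],
        )

    def take_sites(self, idx: Sequence[int] | np.ndarray) -> "HaplotypeAlignment":
        idx = np.asarray(idx, dtype=np.int64)
        return replace(
            self,
            H=self.H[:, idx],
            positions=self.positions[idx],
            alleles=[self.alleles[i] for i in idx] if self.alleles else None,
            outgroup=self.outgroup[idx] if self.outgroup is not None else None,
            polarized=self.polarized[idx],
        )

    def drop_monomorphic(self) -> "HaplotypeAlignment":
        return self.take_sites(np.flatnonzero(self.segregating()))

    # -- export ---------------------------------------------------------
    def site_table(self):
        """Per-site TSV-ready table with per-population derived counts."""
        import pandas as pd

        rows = {
            "chrom": self.chrom,
            "pos": self.positions,
            "ancestral": [
                (self.alleles[j][0] if self.alleles else "0")
                for j in range(self.n_sites)
            ],
            "derived": [
                (self.alleles[j][1] if self.alleles else "1")
                for j in range(self.n_sites)
            ],
            "polarized": self.polarized.astype(int),
        }
        df = pd.DataFrame(rows)
        labels = np.asarray(self.pop_labels)
        for pop in self.populations:
            sub = self.H[labels == pop]
            df[f"derived_{pop}"] = (sub == 1).sum(axis=0)
            df[f"n_{pop}"] = (sub != MISSING).sum(axis=0)
        return df


@dataclass
class ReferencePanel:
    """Window-level values of one statistic used for empirical ranking.

    Typically a few hundred same-length windows from independently
    resequenced genes (empirical) or replicate coalescent simulations
    (simulated).
    """

    statistic: str
    values: np.ndarray
    window_length: int | None = None
    sample_size: int | None = None
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise HapDataError("reference panel must be non-empty")
        if not np.all(np.isfinite(self.values)):
            raise HapDataError("reference panel values must be finite")

    def __len__(self) -> int:
        return int(self.values.size)


# ----------------------------------------------------------------------
# VCF reading
# ----------------------------------------------------------------------

def read_phased_vcf(
    path: str,
    region: str | None = None,
    pop_map: Mapping[str, str] | None = None,
) -> HaplotypeAlignment:
    """Read phased biallelic SNVs from a VCF into a haplotype matrix.

    Indels and multiallelic records are dropped (a count is logged).
    Each diploid sample contributes two haplotype rows (``id_a``/``id_b``).
    An unphased genotype raises, naming the sample and position.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if pop_map is None:
        pop_map = {s: "pop1" for s in samples}
    keep = [i for i, s in enumerate(samples) if s in pop_map]
    if not keep:
        raise HapDataError("no VCF samples present in the population map")

    want_chrom = want_lo = want_hi = None
    if region:
        m = re.match(r"^(\S+?):(\d+)-(\d+)$", region)
        if not m:
            raise HapDataError(f"malformed region {region!r} (chrom:start-end)")
        want_chrom, want_lo, want_hi = m.group(1), int(m.group(2)), int(m.group(3))

    chrom = None
    positions: list[int] = []
    alleles: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    n_dropped = 0
    for rec in vcf:
        if want_chrom is not None and (
            rec.CHROM != want_chrom or not (want_lo <= rec.POS <= want_hi)
        ):
            continue
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_dropped += 1
            continue
        chrom = rec.CHROM if chrom is None else chrom
        gts = rec.genotypes  # [a, b, phased] per sample
        col = np.empty(2 * len(keep), dtype=np.int8)
        for k, i in enumerate(keep):
            a, b, phased = gts[i][0], gts[i][1], gts[i][2]
            het = a >= 0 and b >= 0 and a != b
            if not phased and het:
                raise HapDataError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            col[2 * k] = a if a >= 0 else MISSING
            col[2 * k + 1] = b if b >= 0 else MISSING
        positions.append(rec.POS)
        alleles.append((rec.REF, rec.ALT[0]))
        columns.append(col)
    if not positions:
        raise HapDataError("no biallelic SNVs in the requested region")
    if n_dropped:
        logger.info("dropped %d indel/multiallelic records", n_dropped)

    H = np.stack(columns, axis=1)
    sample_ids = []
    pop_labels = []
    for i in keep:
        for suffix in ("a", "b"):
            sample_ids.append(f"{samples[i]}_{suffix}")
            pop_labels.append(pop_map[samples[i]])
    start, end = int(positions[0]), int(positions[-1])
    if want_lo is not None:
        start, end = want_lo, want_hi
    return HaplotypeAlignment(
        chrom=chrom or "unknown",
        start=start,
        end=end,
        positions=np.asarray(positions),
        H=H,
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        alleles=alleles,
    )


# ----------------------------------------------------------------------
# FASTA reading
# ----------------------------------------------------------------------

def read_haplotype_fasta(
    path: str,
    outgroup_id: str | None = None,
    pop_map: Mapping[str, str] | None = None,
    chrom: str = "region",
    start: int = 1,
) -> HaplotypeAlignment:
    """Read an aligned FASTA of haplotype sequences.

    Ingroup columns with exactly two alleles become sites.  Columns with a
    gap/N in any ingroup sequence are excluded from the site set and from
    ``L_effective`` (all-or-none rule); columns with more than two ingroup
    alleles are excluded from the site set with a warning but still count
    as callable sequence.  The ``outgroup_id`` row, if given, is stored
    per site and ingroup-monomorphic mismatches to it are counted as fixed
    differences.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise HapDataError("empty FASTA")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise HapDataError("aligned sequences must have equal length")
    L = lengths.pop()

    out_seq = None
    ingroup = []
    for r in records:
        if outgroup_id is not None and r.id == outgroup_id:
            out_seq = np.frombuffer(str(r.seq).upper().encode(), dtype="S1")
        else:
            ingroup.append(r)
    if outgroup_id is not None and out_seq is None:
        raise HapDataError(f"outgroup {outgroup_id!r} not found in FASTA")
    if len(ingroup) < 2:
        raise HapDataError("need at least two ingroup sequences")

    M = np.stack(
        [np.frombuffer(str(r.seq).upper().encode(), dtype="S1") for r in ingroup]
    )
    bad = np.isin(M, [b"-", b"N"]).any(axis=0)
    l_eff = int(L - bad.sum())

    positions = []
    alleles = []
    cols = []
    out_codes = []
    fixed = 0
    n_multi = 0
    for j in range(L):
        if bad[j]:
            continue
        col = M[:, j]
        uniq = sorted(set(col.tolist()))
        if len(uniq) == 1:
            if out_seq is not None and out_seq[j] not in (b"-", b"N"):
                if out_seq[j] != uniq[0]:
                    fixed += 1
            continue
        if len(uniq) > 2:
            n_multi += 1
            continue
        a0, a1 = uniq[0].decode(), uniq[1].decode()
        positions.append(start + j)
        alleles.append((a0, a1))
        cols.append((col == uniq[1]).astype(np.int8))
        if out_seq is None:
            out_codes.append(MISSING)
        elif out_seq[j] == uniq[0]:
            out_codes.append(0)
        elif out_seq[j] == uniq[1]:
            out_codes.append(1)
        else:
            out_codes.append(MISSING)
    if n_multi:
        logger.warning("excluded %d columns with >2 ingroup alleles", n_multi)

    n_hap = len(ingroup)
    H = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((n_hap, 0), dtype=np.int8)
    )
    ids = [r.id for r in ingroup]
    pops = [pop_map.get(r.id, "pop1") if pop_map else "pop1" for r in ingroup]
    return HaplotypeAlignment(
        chrom=chrom,
        start=start,
        end=start + L - 1,
        positions=np.asarray(positions, dtype=np.int64),
        H=H,
        sample_ids=ids,
        pop_labels=pops,
        alleles=alleles,
        outgroup=np.asarray(out_codes, dtype=np.int8) if out_seq is not None else None,
        l_effective=l_eff,
        fixed_diffs=fixed if out_seq is not None else None,
    )


# ----------------------------------------------------------------------
# Polarization
# ----------------------------------------------------------------------

def polarize(aln: HaplotypeAlignment) -> tuple[HaplotypeAlignment, int]:
    """Orient alleles as ancestral (0) / derived (1) using the outgroup.

    At sites where the outgroup carries one of the two ingroup alleles that
    allele becomes 0; sites where it is missing or carries a third state
    stay unpolarized (usable by folded statistics only).  Returns the new
    alignment and the fixed-difference count recorded at read time.
    """
    if aln.outgroup is None:
        raise HapDataError("polarization requires an outgroup")
    H = aln.H.copy()
    alleles = list(aln.alleles) if aln.alleles else None
    polarized = np.zeros(aln.n_sites, dtype=bool)
    outg = aln.outgroup.copy()
    for j in range(aln.n_sites):
        og = aln.outgroup[j]
        if og == 0:
            polarized[j] = True
        elif og == 1:
            col = H[:, j]
            obs = col != MISSING
            col[obs] = 1 - col[obs]
            polarized[j] = True
            outg[j] = 0
            if alleles:
                a0, a1 = alleles[j]
                alleles[j] = (a1, a0)
    new = replace(aln, H=H, alleles=alleles, polarized=polarized, outgroup=outg)
    return new, int(aln.fixed_diffs or 0)


# ----------------------------------------------------------------------
# ms-dialect text format
# ----------------------------------------------------------------------

def write_ms(alignments: HaplotypeAlignment | Iterable[HaplotypeAlignment]) -> str:
    """Serialise alignments as ms-dialect replicate blocks.

    Positions are emitted as fractions of the physical length; the 0/1
    matrix is written one haplotype per row.
    """
    if isinstance(alignments, HaplotypeAlignment):
        alignments = [alignments]
    alignments = list(alignments)
    out = io.StringIO()
    first = alignments[0]
    out.write(
        f"balsel {first.n_hap} {len(alignments)} -L {first.l_physical}\n\n"
    )
    for aln in alignments:
        out.write("//\n")
        out.write(f"segsites: {aln.n_sites}\n")
        if aln.n_sites:
            L = aln.l_physical
            fracs = " ".join(
                f"{(p - aln.start) / L:.10f}" for p in aln.positions
            )
            out.write(f"positions: {fracs}\n")
            for row in aln.H:
                out.write("".join(str(int(x)) for x in row) + "\n")
        out.write("\n")
    return out.getvalue()


def read_ms(
    text: str,
    length: int | None = None,
    pop_sizes: Sequence[int] | None = None,
    pop_names: Sequence[str] | None = None,
) -> list[HaplotypeAlignment]:
    """Parse ms-dialect text into alignments (derived coded 1, polarized)."""
    lines = text.splitlines()
    if not lines:
        raise HapDataError("empty ms input")
    header = lines[0].split()
    L = length
    if L is None and "-L" in header:
        L = int(header[header.index("-L") + 1])
    if L is None:
        L = 1_000_000  # positions stay meaningful as fractions

    reps: list[HaplotypeAlignment] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        if i >= n_lines or not lines[i].startswith("segsites:"):
            raise HapDataError(f"expected 'segsites:' at line {i + 1}")
        try:
            seg = int(lines[i].split()[1])
        except (IndexError, ValueError) as exc:
            raise HapDataError(f"malformed segsites at line {i + 1}") from exc
        i += 1
        positions = np.zeros(0, dtype=np.int64)
        rows: list[str] = []
        if seg > 0:
            if i >= n_lines or not lines[i].startswith("positions:"):
                raise HapDataError(f"expected 'positions:' at line {i + 1}")
            fracs = [float(x) for x in lines[i].split()[1:]]
            if len(fracs) != seg:
                raise HapDataError(f"position count mismatch at line {i + 1}")
            positions = _fractions_to_positions(np.asarray(fracs), L)
            i += 1
            while i < n_lines and lines[i].strip() and set(lines[i].strip()) <= {"0", "1"}:
                rows.append(lines[i].strip())
                i += 1
            if any(len(r) != seg for r in rows):
                raise HapDataError("haplotype row length does not match segsites")
            H = np.array([[int(c) for c in r] for r in rows], dtype=np.int8)
        else:
            # rows for 0 sites: consume nothing
            H = np.zeros((0, 0), dtype=np.int8)
        n_hap = H.shape[0]
        if seg == 0 and pop_sizes is not None:
            n_hap = int(sum(pop_sizes))
            H = np.zeros((n_hap, 0), dtype=np.int8)
        labels = _labels_for(n_hap, pop_sizes, pop_names)
        reps.append(
            HaplotypeAlignment(
                chrom="sim",
                start=1,
                end=L,
                positions=positions,
                H=H,
                sample_ids=[f"hap{k}" for k in range(n_hap)],
                pop_labels=labels,
                polarized=np.ones(seg, dtype=bool),
                outgroup=np.zeros(seg, dtype=np.int8) if seg else np.zeros(0, dtype=np.int8),
            )
        )
    if not reps:
        raise HapDataError("no replicate blocks ('//') found")
    return reps


def _labels_for(
    n_hap: int,
    pop_sizes: Sequence[int] | None,
    pop_names: Sequence[str] | None,
) -> list[str]:
    if pop_sizes is None:
        return ["pop1"] * n_hap
    if sum(pop_sizes) != n_hap:
        raise HapDataError("pop_sizes do not sum to haplotype count")
    names = (
        list(pop_names)
        if pop_names is not None
        else [f"pop{i + 1}" for i in range(len(pop_sizes))]
    )
    labels: list[str] = []
    for name, k in zip(names, pop_sizes):
        labels.extend([name] * k)
    return labels


def _fractions_to_positions(fracs: np.ndarray, L: int) -> np.ndarray:
    """Map (0,1] fractions to strictly increasing 1-based integers."""
    pos = np.floor(fracs * L).astype(np.int64) + 1
    pos = np.clip(pos, 1, L)
    for k in range(1, len(pos)):
        if pos[k] <= pos[k - 1]:
            pos[k] = pos[k - 1] + 1
    # ran past the end after collision resolution: shift left
    over = pos[-1] - L if len(pos) else 0
    if over > 0:
        pos = pos - over
        for k in range(len(pos) - 1, 0, -1):
            if pos[k - 1] >= pos[k]:
                pos[k - 1] = pos[k] - 1
        if pos[0] < 1:
            raise HapDataError("more sites than base pairs in region")
    return pos
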