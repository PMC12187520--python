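"""The global mutually-exclusive index between a promoter mark's domains and
H3K36me3 domains.

m_s = B_r / B_v, where B_r = n_A * n_B / n_total is the coincidence count
expected at random and B_v = n_bi is the observed count of co-marked
domains. m_s > 1 means fewer co-occurrences than chance — the two marks
exclude each other. The counting unit for n_bi is an A-domain (the promoter
mark's) overlapping any H3K36me3 domain by at least ``min_overlap`` bp, and
n_total defaults to the size of the union of evaluated domains,
n_A + n_B - n_bi; both conventions are explicit fields of the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import GenomeSpec, Interval, iter_by_chrom


@dataclass(frozen=True)
class ExclusivityResult:
    n_a: int
    n_b: int
    n_total: int
    n_bi: int
    b_r: float
    b_v: int
    m_s: float  # +inf when n_bi == 0 (perfect exclusivity)

    @property
    def exclusive(self) -> bool:
        return self.m_s > 1.0


def count_codomains(domains_a: list[Interval], domains_b: list[Interval], min_overlap: int = 1) -> int:
    """Number of A-domains overlapping >= min_overlap bp with any B-domain.

    Both sets must be internally disjoint; each is sorted per chromosome
    internally.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    b_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in iter_by_chrom(domains_b):
        b_by_chrom[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    count = 0
    for a in domains_a:
        got = b_by_chrom.get(a.chrom)
        if got is None:
            continue
        starts, ends = got
        # B-domains that could reach min_overlap with a: start < a.end and end > a.start
        lo = np.searchsorted(ends, a.start, side="right")
        hi = np.searchsorted(starts, a.end, side="left")
        if lo >= hi:
            continue
        ov = np.minimum(ends[lo:hi], a.end) - np.maximum(starts[lo:hi], a.start)
        if (ov >= min_overlap).any():
            count += 1
    return count


def mutual_exclusive_index(n_a: int, n_b: int, n_bi: int, n_total: int | None = None) -> ExclusivityResult:
    """Evaluate m_s = B_r / B_v from domain counts.

    n_total defaults to n_A + n_B - n_bi, the number of distinct evaluated
    domains. n_bi = 0 yields m_s = +inf (no observed coincidence at all).
    """
    if n_total is None:
        n_total = n_a + n_b - n_bi
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_bi < 0:
        raise ValueError("n_bi must be nonnegative")
    b_r = n_a * n_b / n_total
    m_s = math.inf if n_bi == 0 else b_r / n_bi
    return ExclusivityResult(n_a=n_a, n_b=n_b, n_total=n_total, n_bi=n_bi, b_r=b_r, b_v=n_bi, m_s=m_s)


def compute_exclusivity(
    domains_a: list[Interval],
    domains_b: list[Interval],
    min_overlap: int = 1,
    n_total: int | None = None,
) -> ExclusivityResult:
    """count_codomains + mutual_exclusive_index in one call."""
    n_bi = count_codomains(domains_a, domains_b, min_overlap=min_overlap)
    return mutual_exclusive_index(len(domains_a), len(domains_b), n_bi, n_total=n_total)


def shuffle_domains(
    domains: list[Interval],
    genome: GenomeSpec,
    seed: int | np.random.Generator = 0,
    max_tries: int = 1000,
) -> list[Interval]:
    """Width-preserving random placement of domains, the null model for m_s.

    Each domain is re-placed uniformly on its own chromosome without overlap
    with already-placed domains (largest first, to ease packing).
    Deterministic given the seed. Raises if a domain cannot be placed within
    ``max_tries`` attempts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = genome.chrom_sizes
    placed: dict[str, list[tuple[int, int]]] = {}
    out: list[Interval] = []
    for iv in sorted(domains, key=lambda d: -d.width):
        if iv.chrom not in sizes:
            raise ValueError(f"domain chromosome {iv.chrom!r} not in genome")
        space = sizes[iv.chrom] - iv.width
        if space < 0:
            raise ValueError(f"domain wider than chromosome {iv.chrom}")
        taken = placed.setdefault(iv.chrom, [])
        for _ in range(max_tries):
            s = int(rng.integers(0, space + 1))
            e = s + iv.width
            if all(e <= ts or s >= te for ts, te in taken):
                taken.append((s, e))
                out.append(Interval(iv.chrom, s, e, iv.label))
                break
        else:
            raise RuntimeError(f"could not place a {iv.width} bp domain on {iv.chrom} after {max_tries} tries")
    return sorted(out, key=lambda d: (d.chrom, d.start))
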