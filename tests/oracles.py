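"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths they verify.
"""

from __future__ import annotations

import itertools
from math import comb


def naive_digest(sequence: str, site: str, cut_offset: int) -> list[tuple[int, int]]:
    """Position-by-position scan for recognition sites, then interval split."""
    seq = sequence.upper()
    cuts = []
    for i in range(len(seq) - len(site) + 1):
        if seq[i : i + len(site)] == site:
            cuts.append(i + cut_offset)
    bounds = sorted(set([0] + cuts + [len(seq)]))
    return [
        (s, e) for s, e in zip(bounds[:-1], bounds[1:]) if e > s
    ]


def stepup_bh(pvals: list[float]) -> list[float]:
    """Literal O(m^2) evaluation of q_(i) = min_{j>=i} m*p_(j)/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_i, idx in enumerate(order, start=1):
        best = min(
            m * pvals[order[j - 1]] / j for j in range(rank_i, m + 1)
        )
        q[idx] = min(best, 1.0)
    return q


def brute_force_pairs(variants, contacts, fragments_by_chrom, genes, min_libraries=1):
    """Triple-nested join: variant fragment x contact x gene overlap.

    Returns {(rsid, gene_id): library set}.
    """
    frag_iv = {
        f.key: (f.chrom, f.start, f.end)
        for frags in fragments_by_chrom.values()
        for f in frags
    }
    result: dict[tuple[str, str], set[str]] = {}
    for v in variants:
        if v.fragment_index is None:
            continue
        vkey = (v.chrom, v.fragment_index)
        for c in contacts:
            if c.frag_a == c.frag_b:
                continue
            if c.frag_a == vkey:
                partner = c.frag_b
            elif c.frag_b == vkey:
                partner = c.frag_a
            else:
                continue
            pchrom, pstart, pend = frag_iv[partner]
            for g in genes:
                if g.chrom == pchrom and g.start < pend and pstart < g.end:
                    result.setdefault((v.rsid, g.gene_id), set()).add(c.library_id)
    return {
        k: libs for k, libs in result.items() if len(libs) >= min_libraries
    }


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws (N <= 12)."""
    universe = list(range(N))
    term = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(universe, n) if len(term & set(draw)) >= k
    )
    return hits / comb(N, n)


def ld_from_counts(n_ab: int, n_aB: int, n_Ab: int, n_ab_low: int):
    """(r2, d_prime) from a 2x2 haplotype table.

    Arguments are counts of (1,1), (1,0), (0,1), (0,0) haplotypes.
    """
    n = n_ab + n_aB + n_Ab + n_ab_low
    pa = (n_ab + n_aB) / n
    pb = (n_ab + n_Ab) / n
    pab = n_ab / n
    d = pab - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return r2, 0.0
    return r2, abs(d) / dmax
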