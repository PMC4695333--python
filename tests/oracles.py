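"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the package's implementation paths: plain loops,
textbook formulas and regex scans only.
"""

from __future__ import annotations

import math
import re

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up with explicit monotonization."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, m * pvalues[i] / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def pooled_t_two_sample(a: list[float], b: list[float]) -> tuple[float, float]:
    """Classic pooled-variance two-sample t and its two-sided p-value."""
    from scipy.stats import t as t_dist

    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (m1 - m2) / se
    return t, 2 * t_dist.sf(abs(t), df)


def regex_digest_lengths(sequence: str, pattern: str = "CCGG", offset: int = 1) -> list[int]:
    cuts = [m.start() + offset for m in re.finditer(f"(?={pattern})", sequence)]
    bounds = [0] + [c for c in cuts if 0 < c < len(sequence)] + [len(sequence)]
    return [b - a for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def expected_consensus(molecule: str, cpg_methylated: dict[int, bool]) -> str:
    """Expected deduced fragment for an error-free fully covered molecule.

    Per strand, a cytosine survives conversion only if it is a methylated
    CpG; the two strand consensus sequences are then merged with the
    forward partner being the lexicographically smaller one (equal read
    support), and merging restores a C wherever the reverse complement of
    the partner shows one.
    """

    def strand_consensus(strand: str, meth: dict[int, bool]) -> str:
        out = []
        for i, base in enumerate(strand):
            if base == "C" and i + 1 < len(strand) and strand[i + 1] == "G" and meth.get(i, False):
                out.append("C")
            elif base == "C":
                out.append("T")
            else:
                out.append(base)
        return "".join(out)

    fwd_meth = dict(cpg_methylated)
    # reverse-strand CpG C sits at position len-2-i for a forward CpG C at i
    rev_meth = {len(molecule) - 2 - i: v for i, v in cpg_methylated.items()}
    fwd = strand_consensus(molecule, fwd_meth)
    rev = strand_consensus(revcomp(molecule), rev_meth)
    forward_partner, partner = (fwd, rev) if fwd <= rev else (rev, fwd)
    rc_partner = revcomp(partner)
    merged = "".join(
        "C" if base == "T" and rc_partner[i] == "C" else base
        for i, base in enumerate(forward_partner)
    )
    # merged fragments are reported in canonical (lexicographically smaller)
    # orientation because a two-strand consensus has no inherent strand
    return min(merged, revcomp(merged))


def worst_of_three_ranking(stats: list[tuple[str, float, float, float]]) -> list[str]:
    """Exhaustive worst-of-three ranking oracle.

    ``stats`` holds (id, combined_p, |lfc|, |diff|); competition ranks are
    assigned by brute-force counting, and ids are returned ordered by the
    worst rank then p then id.
    """
    def comp_rank(values: list[float], bigger_better: bool) -> list[int]:
        ranks = []
        for v in values:
            better = sum(1 for u in values if (u > v if bigger_better else u < v))
            ranks.append(better + 1)
        return ranks

    ps = [s[1] for s in stats]
    lfcs = [s[2] for s in stats]
    diffs = [s[3] for s in stats]
    rp = comp_rank(ps, bigger_better=False)
    rl = comp_rank(lfcs, bigger_better=True)
    rd = comp_rank(diffs, bigger_better=True)
    combined = [max(a, b, c) for a, b, c in zip(rp, rl, rd)]
    order = sorted(range(len(stats)), key=lambda i: (combined[i], ps[i], stats[i][0]))
    return [stats[i][0] for i in order]
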