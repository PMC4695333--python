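"""Per-CpG methylation calling on the deduced genome.

Forward-orientation reads report a cytosine directly (C = methylated,
T = unmethylated); reverse-complement-orientation reads report through the
complementary base at the paired guanine of the CpG (G = methylated,
A = unmethylated), so both strands of a CpG are pooled into one site.  Any
other observed base is ambiguous and counts toward neither tally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .genome import DeducedGenome
from .io_formats import SampleSheet, reverse_complement


@dataclass
class SiteMethylation:
    fragment_id: str
    position: int  # 0-based C position within the fragment
    sample_id: str
    count_methylated: int
    count_unmethylated: int
    context: str = "CpG"

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def level(self) -> float:
        total = self.coverage
        return self.count_methylated / total if total else float("nan")


@dataclass(frozen=True)
class CoverageFilter:
    """Keep sites with min_coverage <= reads <= max_coverage (inclusive)."""

    min_coverage: int = 8
    max_coverage: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= self.max_coverage):
            raise ValueError("need 0 < min_coverage <= max_coverage")


@dataclass
class FragmentMethylation:
    fragment_id: str
    sample_id: str
    level: float
    n_sites: int
    mean_coverage: float


def _context_positions(sequence: str, contexts: set[str]) -> dict[int, str]:
    """Cytosine positions of the requested contexts on the forward strand."""
    out: dict[int, str] = {}
    n = len(sequence)
    for i, base in enumerate(sequence):
        if base != "C":
            continue
        nxt = sequence[i + 1] if i + 1 < n else ""
        nxt2 = sequence[i + 2] if i + 2 < n else ""
        if nxt == "G":
            ctx = "CpG"
        elif nxt2 == "G" and nxt in "ACT":
            ctx = "CHG"
        elif nxt in "ACT" and nxt2 in "ACT":
            ctx = "CHH"
        else:
            continue  # truncated context at the fragment edge
        if ctx in contexts:
            out[i] = ctx
    return out


def call_methylation(
    alignments: Iterable[AlignmentRecord],
    reads_by_id: dict[str, str],
    genome: DeducedGenome,
    contexts: set[str] | None = None,
) -> list[SiteMethylation]:
    """Tally methylated/unmethylated evidence per cytosine site per sample.

    ``reads_by_id`` maps read_id to the read sequence (alignment records do
    not carry sequences).  CpG sites receive evidence from both
    orientations; CHG/CHH sites only from forward-orientation reads (the
    opposite strand of a non-CpG cytosine carries no symmetric partner).
    """
    contexts = contexts or {"CpG"}
    frag_seqs = {f.fragment_id: f.sequence for f in genome.fragments}
    frag_contexts = {
        fid: _context_positions(seq, contexts) for fid, seq in frag_seqs.items()
    }
    tally: dict[tuple[str, int, str], list] = {}  # key -> [meth, unmeth, ctx]

    for rec in alignments:
        if rec.fragment_id not in frag_seqs:
            raise KeyError(f"alignment references unknown fragment {rec.fragment_id!r}")
        positions = frag_contexts[rec.fragment_id]
        seq = reads_by_id[rec.read_id]
        lo, hi = rec.offset, rec.offset + rec.length
        if rec.orientation == "+":
            for p, ctx in positions.items():
                if lo <= p < hi:
                    base = seq[p - lo]
                    if base in "CT":
                        rec_key = (rec.fragment_id, p, rec.sample_id)
                        entry = tally.setdefault(rec_key, [0, 0, ctx])
                        entry[0 if base == "C" else 1] += 1
        else:
            rc = reverse_complement(seq)
            for p, ctx in positions.items():
                if ctx != "CpG":
                    continue
                g = p + 1  # the paired guanine carries the reverse-strand evidence
                if lo <= g < hi:
                    base = rc[g - lo]
                    if base in "GA":
                        rec_key = (rec.fragment_id, p, rec.sample_id)
                        entry = tally.setdefault(rec_key, [0, 0, ctx])
                        entry[0 if base == "G" else 1] += 1

    return [
        SiteMethylation(fid, pos, sid, meth, unmeth, ctx)
        for (fid, pos, sid), (meth, unmeth, ctx) in sorted(tally.items())
    ]


def filter_sites(
    calls: Iterable[SiteMethylation], cov_filter: CoverageFilter
) -> list[SiteMethylation]:
    return [
        c
        for c in calls
        if cov_filter.min_coverage <= c.coverage <= cov_filter.max_coverage
    ]


def aggregate_fragments(
    calls: Iterable[SiteMethylation], genome: DeducedGenome
) -> list[FragmentMethylation]:
    """Coverage-weighted fragment-level methylation per sample.

    level = sum(methylated) / sum(methylated + unmethylated) over the
    fragment's passing CpGs; fragments without passing sites are omitted.
    """
    known = {f.fragment_id for f in genome.fragments}
    acc: dict[tuple[str, str], list] = {}
    for c in calls:
        if c.fragment_id not in known:
            raise KeyError(f"call references unknown fragment {c.fragment_id!r}")
        entry = acc.setdefault((c.fragment_id, c.sample_id), [0, 0, 0])
        entry[0] += c.count_methylated
        entry[1] += c.count_unmethylated
        entry[2] += 1
    out = []
    for (fid, sid), (meth, unmeth, n_sites) in sorted(acc.items()):
        total = meth + unmeth
        if total == 0:
            continue
        out.append(
            FragmentMethylation(fid, sid, meth / total, n_sites, total / n_sites)
        )
    return out


def build_methylation_matrix(
    calls: Sequence[SiteMethylation], samples: SampleSheet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site x sample matrices of levels and coverages.

    Rows are (fragment_id, position) in fragment order then position;
    columns follow the sample sheet; missing cells are NaN.
    """
    sites = sorted({(c.fragment_id, c.position) for c in calls})
    index = pd.MultiIndex.from_tuples(sites, names=["fragment_id", "position"])
    levels = pd.DataFrame(np.nan, index=index, columns=list(samples.sample_ids))
    coverage = pd.DataFrame(np.nan, index=index, columns=list(samples.sample_ids))
    for c in calls:
        levels.loc[(c.fragment_id, c.position), c.sample_id] = c.level
        coverage.loc[(c.fragment_id, c.position), c.sample_id] = c.coverage
    return levels, coverage


def build_fragment_matrix(
    fragment_levels: Sequence[FragmentMethylation], samples: SampleSheet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fragment x sample matrices of levels and mean coverages."""
    frags = sorted({f.fragment_id for f in fragment_levels})
    levels = pd.DataFrame(np.nan, index=frags, columns=list(samples.sample_ids))
    coverage = pd.DataFrame(np.nan, index=frags, columns=list(samples.sample_ids))
    for f in fragment_levels:
        levels.loc[f.fragment_id, f.sample_id] = f.level
        coverage.loc[f.fragment_id, f.sample_id] = f.mean_coverage
    return levels, coverage
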