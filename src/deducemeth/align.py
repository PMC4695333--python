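"""Bisulfite-aware ungapped read alignment against a deduced genome.

Alignment uses exact k-mer seeds on the two converted frames — the C->T
frame for forward-strand hits and the G->A frame for reverse-complement
hits — followed by full verification of every candidate diagonal with the
asymmetric bisulfite matching rule: a genomic C may legitimately be read as
T on the forward strand (and a genomic G as A when the read comes from the
opposite strand), but never the other way round.  Fragments are indexed
individually, so no alignment can cross a spacer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome import DeducedGenome
from .io_formats import RRBSRead, convert_c2t, convert_g2a, reverse_complement
from .simulate import SpikeInControl


@dataclass
class AlignerParams:
    max_mismatch_rate: float = 0.08
    multimap_policy: str = "random-best"  # or "best-unique"
    seed: int = 0
    report_unaligned: bool = False
    seed_length: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.max_mismatch_rate < 1):
            raise ValueError("max_mismatch_rate must be in (0, 1)")
        if self.multimap_policy not in {"random-best", "best-unique"}:
            raise ValueError(f"unknown multimap_policy {self.multimap_policy!r}")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    sample_id: str
    fragment_id: str
    offset: int
    orientation: str  # "+" forward, "-" reverse-complement
    length: int
    mismatches: int
    mapq_proxy: int  # second-best minus best mismatch count (large when unique)


@dataclass
class ConversionMetrics:
    """Spike-in derived bisulfite conversion quality.

    underconversion_rate: fraction of unmethylated-control Cs still read as C.
    overconversion_rate: fraction of methylated-control CpG Cs read as T.
    """

    underconversion_rate: float
    overconversion_rate: float
    n_control_reads: int


class AlignmentIndex:
    """Exact k-mer seed index over the converted frames of every fragment."""

    def __init__(self, genome: DeducedGenome, seed_length: int = 16) -> None:
        self.genome = genome
        self.k = seed_length
        self.fragments = {f.fragment_id: f.sequence for f in genome.fragments}
        self._ct: dict[str, list[tuple[str, int]]] = {}
        self._ga: dict[str, list[tuple[str, int]]] = {}
        for frag in genome.fragments:
            ct = convert_c2t(frag.sequence)
            ga = convert_g2a(frag.sequence)
            for i in range(len(ct) - self.k + 1):
                self._ct.setdefault(ct[i : i + self.k], []).append((frag.fragment_id, i))
                self._ga.setdefault(ga[i : i + self.k], []).append((frag.fragment_id, i))

    def seed_hits(self, query: str, frame: str) -> set[tuple[str, int]]:
        """Candidate (fragment_id, start) diagonals for a converted query."""
        table = self._ct if frame == "ct" else self._ga
        hits: set[tuple[str, int]] = set()
        for off in range(len(query) - self.k + 1):
            for frag_id, pos in table.get(query[off : off + self.k], ()):
                start = pos - off
                if start >= 0:
                    hits.add((frag_id, start))
        return hits


def build_index(genome: DeducedGenome, params: AlignerParams | None = None) -> AlignmentIndex:
    params = params or AlignerParams()
    return AlignmentIndex(genome, params.seed_length)


def _count_mismatches_fwd(read: str, ref: str) -> int:
    """Forward rule: match iff equal or (ref C, read T)."""
    mism = 0
    for r, g in zip(read, ref):
        if r != g and not (g == "C" and r == "T"):
            mism += 1
    return mism


def _count_mismatches_rev(rc_read: str, ref: str) -> int:
    """Reverse rule on the forward frame: match iff equal or (ref G, read A)."""
    mism = 0
    for r, g in zip(rc_read, ref):
        if r != g and not (g == "G" and r == "A"):
            mism += 1
    return mism


def align_read(
    read: RRBSRead,
    index: AlignmentIndex,
    params: AlignerParams,
    rng: np.random.Generator | None = None,
) -> AlignmentRecord | None:
    """Best ungapped bisulfite-aware placement of one read, or None.

    Candidates come from seed hits in both orientations; the placement with
    the fewest mismatches wins.  Ties are broken by ``multimap_policy``:
    best-unique reports nothing on ambiguity, random-best picks one hit with
    the seeded generator.  Placements above ``max_mismatch_rate`` are
    rejected.
    """
    n = len(read.sequence)
    if n < index.k:
        return None
    candidates: list[tuple[int, str, int, str]] = []  # (mismatches, frag, start, orient)
    fwd_q = convert_c2t(read.sequence)
    rc = reverse_complement(read.sequence)
    rc_q = convert_g2a(rc)
    for frame, query, verify_seq in (("ct", fwd_q, read.sequence), ("ga", rc_q, rc)):
        for frag_id, start in index.seed_hits(query, frame):
            ref = index.fragments[frag_id]
            if start + n > len(ref):
                continue
            window = ref[start : start + n]
            if frame == "ct":
                mism = _count_mismatches_fwd(verify_seq, window)
                orient = "+"
            else:
                mism = _count_mismatches_rev(verify_seq, window)
                orient = "-"
            candidates.append((mism, frag_id, start, orient))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    best_mism = candidates[0][0]
    if best_mism / n > params.max_mismatch_rate:
        return None
    best = [c for c in candidates if c[0] == best_mism]
    second_best = min((c[0] for c in candidates if c[0] > best_mism), default=n + 1)
    if len(best) > 1:
        if params.multimap_policy == "best-unique":
            return None
        assert rng is not None, "random-best policy needs a generator"
        chosen = best[int(rng.integers(len(best)))]
        mapq = 0
    else:
        chosen = best[0]
        mapq = second_best - best_mism
    mism, frag_id, start, orient = chosen
    return AlignmentRecord(
        read_id=read.read_id,
        sample_id=read.sample_id,
        fragment_id=frag_id,
        offset=start,
        orientation=orient,
        length=n,
        mismatches=mism,
        mapq_proxy=mapq,
    )


def align_sample(
    reads: Iterable[RRBSRead],
    index: AlignmentIndex,
    params: AlignerParams | None = None,
) -> tuple[list[AlignmentRecord], float]:
    """Align a sample's reads; returns (alignments, mapping efficiency)."""
    params = params or AlignerParams()
    rng = np.random.default_rng(params.seed)
    alignments = []
    total = 0
    for read in reads:
        total += 1
        rec = align_read(read, index, params, rng)
        if rec is not None:
            alignments.append(rec)
    efficiency = len(alignments) / total if total else 0.0
    return alignments, efficiency


def compute_conversion_metrics(
    reads: Iterable[RRBSRead],
    controls: Sequence[SpikeInControl],
    params: AlignerParams | None = None,
) -> ConversionMetrics:
    """Align reads to spike-in controls and tally per-cytosine conversion.

    For unmethylated controls every aligned-strand cytosine counts toward the
    underconversion rate (C still read as C); for methylated controls only
    CpG cytosines count toward the overconversion rate (C read as T).
    Reverse-orientation reads contribute through the complementary G/A
    evidence on the opposite strand.  With zero aligned control reads the
    rates are NaN and a warning is emitted.
    """
    import warnings

    from .genome import DeducedFragment, DeducedGenome

    params = params or AlignerParams()
    control_genome = DeducedGenome(
        fragments=[
            DeducedFragment(c.name, c.sequence, n_reads=0) for c in controls
        ],
        spacer_length=0,
    )
    index = AlignmentIndex(control_genome, params.seed_length)
    by_name = {c.name: c for c in controls}
    rng = np.random.default_rng(params.seed)

    under_kept = under_total = 0
    over_converted = over_total = 0
    n_aligned = 0
    for read in reads:
        rec = align_read(read, index, params, rng)
        if rec is None:
            continue
        n_aligned += 1
        ctrl = by_name[rec.fragment_id]
        seq = ctrl.sequence
        cpgs = {i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"}
        if rec.orientation == "+":
            obs = read.sequence
            for i in range(rec.offset, rec.offset + rec.length):
                if seq[i] != "C":
                    continue
                base = obs[i - rec.offset]
                if base not in "CT":
                    continue
                if ctrl.methylated:
                    if i in cpgs:
                        over_total += 1
                        over_converted += base == "T"
                else:
                    under_total += 1
                    under_kept += base == "C"
        else:
            obs = reverse_complement(read.sequence)
            # reverse-strand cytosines sit opposite forward-strand Gs
            for i in range(rec.offset, rec.offset + rec.length):
                if seq[i] != "G":
                    continue
                base = obs[i - rec.offset]
                if base not in "GA":
                    continue
                is_cpg_g = i >= 1 and seq[i - 1] == "C"
                if ctrl.methylated:
                    if is_cpg_g:
                        over_total += 1
                        over_converted += base == "A"
                else:
                    under_total += 1
                    under_kept += base == "G"
    if n_aligned == 0:
        warnings.warn("no reads aligned to the spike-in controls; rates undefined")
        return ConversionMetrics(float("nan"), float("nan"), 0)
    under = under_kept / under_total if under_total else float("nan")
    over = over_converted / over_total if over_total else float("nan")
    return ConversionMetrics(under, over, n_aligned)
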