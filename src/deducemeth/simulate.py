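"""Synthetic RRBS data with known ground truth.

The simulator produces a random genome with tunable GC content and CpG
enrichment, performs an in-silico MspI (C^CGG) digest, applies size
selection, and emits bisulfite-converted sequencing reads from both strands
of each selected fragment, together with a per-sample per-CpG methylation
truth table.  Spike-in conversion controls are generated the same way.

Model of the library molecule: MspI cuts C^CGG with a staggered 2-base
overhang that is filled in during end repair, so the double-stranded library
molecule for an internal digest fragment [cut_i, cut_j) is
``genome[cut_i : cut_j + 2]`` — it starts with CGG and ends with CCG on both
strands, exactly the termini that reference-free strand merging relies on.
Chromosome-terminal fragments lack an MspI end and are not turned into
library molecules.  Digest fragments themselves still tile [0, L) exactly.

Methylation is drawn per CpG per DNA molecule (Bernoulli with the truth
probability), and each molecule emits one read from each strand, so the two
strands of a molecule always agree on methylation state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import RRBSRead, SampleSheet, reverse_complement

MSPI = ("CCGG", 1)  # recognition pattern, cut offset (C^CGG)
TAQI = ("TCGA", 1)  # T^CGA

# spike-in controls are added at 0.1% of the genomic material
DEFAULT_SPIKE_IN_FRACTION = 0.001


def spike_in_read_count(
    n_sample_reads: int, fraction: float = DEFAULT_SPIKE_IN_FRACTION
) -> int:
    """Number of control reads for a sample at the default 0.1% mass fraction."""
    return max(1, round(n_sample_reads * fraction))


@dataclass(frozen=True)
class DigestFragment:
    """Half-open genomic interval produced by an in-silico digest."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimGenome:
    """A simulated genome with its CpG site positions (0-based C positions)."""

    sequence: str
    cpg_positions: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        for p in self.cpg_positions:
            if self.sequence[p : p + 2] != "CG":
                raise ValueError(f"position {p} is not the C of a CpG")


@dataclass(frozen=True)
class SpikeInControl:
    """A synthetic conversion-control oligonucleotide."""

    name: str
    sequence: str
    methylated: bool

    def __post_init__(self) -> None:
        if self.methylated and "CG" not in self.sequence:
            raise ValueError("methylated control must contain a CpG")
        if not self.methylated and "C" not in self.sequence:
            raise ValueError("unmethylated control must contain a C")


DEFAULT_SPIKE_INS = (
    SpikeInControl(
        "meth_control",
        "ACGTACGGATCGTTACGAATCGGTTACGTAGCGATTACGGTATCGATACG",
        methylated=True,
    ),
    SpikeInControl(
        "unmeth_control",
        "ATCATTCCATGACTTCATGGAACTTCATCCTAGACTTGGTACCATTGACT",
        methylated=False,
    ),
)


def in_silico_digest(sequence: str, site: tuple[str, int] = MSPI) -> list[DigestFragment]:
    """Cut a genome at every occurrence of the recognition pattern.

    The cut falls ``offset`` bases into each pattern occurrence (MspI: after
    the first C).  Overlapping occurrences are honored; the returned
    fragments tile [0, len(sequence)) in genomic order.
    """
    pattern, offset = site
    if not sequence:
        return []
    cuts = [m.start() + offset for m in re.finditer(f"(?={re.escape(pattern)})", sequence)]
    bounds = [0] + [c for c in cuts if 0 < c < len(sequence)] + [len(sequence)]
    return [DigestFragment(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def fragment_length_histogram(
    fragments: Iterable[DigestFragment], adapter_length: int = 0
) -> dict[int, int]:
    """Histogram of library insert sizes (fragment length + 2 adapters)."""
    hist: dict[int, int] = {}
    for frag in fragments:
        size = frag.length + 2 * adapter_length
        hist[size] = hist.get(size, 0) + 1
    return dict(sorted(hist.items()))


def simulate_genome(
    length: int,
    gc_fraction: float = 0.5,
    cpg_enrichment: float = 8.0,
    seed: int = 0,
) -> SimGenome:
    """Sample a genome as a first-order chain with boosted C->G transitions.

    Base composition follows ``gc_fraction``; after a C, the probability of a
    G is multiplied by ``cpg_enrichment`` (renormalized), inflating CpG —
    and hence MspI CCGG — density over the i.i.d. expectation, mimicking the
    CpG-island bias that RRBS exploits.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    base_p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    after_c = base_p.copy()
    after_c[2] *= cpg_enrichment  # G
    total = after_c.sum()
    if total > 0:
        after_c = after_c / total
    cum_base = np.cumsum(base_p)
    cum_after_c = np.cumsum(after_c)
    u = rng.random(length)
    chars = []
    prev = ""
    for i in range(length):
        cum = cum_after_c if prev == "C" else cum_base
        r = u[i]
        prev = "A" if r < cum[0] else "C" if r < cum[1] else "G" if r < cum[2] else "T"
        chars.append(prev)
    genome = "".join(chars)
    cpgs = tuple(m.start() for m in re.finditer("(?=CG)", genome))
    return SimGenome(genome, cpgs, seed)


def uniform_methylation_truth(
    genome: SimGenome,
    groups: Sequence[str],
    seed: int = 0,
    low: float = 0.0,
    high: float = 1.0,
) -> dict[tuple[str, int], float]:
    """Per-(group, CpG) truth probabilities drawn Uniform(low, high)."""
    rng = np.random.default_rng(seed)
    truth = {}
    for group in groups:
        levels = rng.uniform(low, high, size=len(genome.cpg_positions))
        for pos, m in zip(genome.cpg_positions, levels):
            truth[(group, pos)] = float(m)
    return truth


def constant_methylation_truth(
    genome: SimGenome, groups: Sequence[str], level: float
) -> dict[tuple[str, int], float]:
    return {(g, p): float(level) for g in groups for p in genome.cpg_positions}


def library_molecules(
    genome: SimGenome,
    size_range: tuple[int, int],
    site: tuple[str, int] = MSPI,
) -> list[tuple[DigestFragment, str]]:
    """Size-selected library molecules: internal digest fragments + CG fill-in.

    Returns (digest fragment, molecule sequence) pairs where the molecule is
    ``genome[start:end+2]`` and ``size_range`` filters on molecule length.
    """
    seq = genome.sequence
    frags = in_silico_digest(seq, site)
    lo, hi = size_range
    out = []
    for frag in frags:
        if frag.start == 0 or frag.end == len(seq):
            continue  # no ligatable MspI end on one side
        mol = seq[frag.start : frag.end + 2]
        if lo <= len(mol) <= hi:
            out.append((frag, mol))
    return out


def _mutate(seq: list[str], rng: np.random.Generator, error_rate: float) -> None:
    if error_rate <= 0:
        return
    n = len(seq)
    errs = np.nonzero(rng.random(n) < error_rate)[0]
    for i in errs:
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(3)]


def _bisulfite_strand(
    strand_seq: str,
    cpg_states: Mapping[int, bool],
    strand_cpg_map: Mapping[int, int],
    conversion_rate: float,
    overconversion_rate: float,
    rng: np.random.Generator,
) -> list[str]:
    """Convert one strand of a molecule.

    ``strand_cpg_map`` maps strand positions of CpG cytosines to molecule CpG
    keys whose Bernoulli methylation state is shared between strands.
    """
    out = list(strand_seq)
    for i, base in enumerate(out):
        if base != "C":
            continue
        if i in strand_cpg_map:
            methylated = cpg_states[strand_cpg_map[i]]
            if methylated:
                if rng.random() < overconversion_rate:
                    out[i] = "T"
            else:
                if rng.random() < conversion_rate:
                    out[i] = "T"
        else:
            if rng.random() < conversion_rate:
                out[i] = "T"
    return out


def simulate_rrbs_reads(
    genome: SimGenome,
    truth: Mapping[tuple[str, int], float],
    samples: SampleSheet,
    depth: float = 30.0,
    read_length: int = 50,
    size_range: tuple[int, int] = (40, 220),
    error_rate: float = 0.0,
    conversion_rate: float = 1.0,
    overconversion_rate: float = 0.0,
    seed: int = 0,
    site: tuple[str, int] = MSPI,
    paired_strands: bool = False,
) -> tuple[dict[str, list[RRBSRead]], pd.DataFrame]:
    """Emit bisulfite reads per sample plus a per-sample per-CpG truth table.

    For each (DNA duplex, CpG) a methylation state is drawn Bernoulli(truth)
    and shared by the two strands of that duplex; the C is then read as C
    with probability ``1 - overconversion_rate`` when methylated and
    ``1 - conversion_rate`` when not.  Non-CpG cytosines convert at
    ``conversion_rate``.  Reads are MspI-anchored at a fragment end and
    truncated to ``read_length``; sequencing errors are applied uniformly
    after conversion.

    By default each read samples a fresh duplex on a random strand
    (bisulfite conversion separates the strands into independent library
    molecules, so re-observing the same duplex is rare in practice); with
    ``paired_strands=True`` every duplex emits one read from each strand,
    which makes the shared per-duplex methylation states observable for
    strand-merging experiments.
    """
    molecules = library_molecules(genome, size_range, site)
    if not molecules:
        raise ValueError("no fragments pass size selection")
    rng = np.random.default_rng(seed)
    reads: dict[str, list[RRBSRead]] = {s: [] for s in samples.sample_ids}
    tally: dict[tuple[str, int], list[int]] = {}  # (sample, genome CpG pos) -> [meth, total]

    for sample_id, group in zip(samples.sample_ids, samples.group_labels):
        for frag, mol in molecules:
            m = len(mol)
            # molecule CpG positions and their genome coordinates
            mol_cpgs = [i for i in range(m - 1) if mol[i : i + 2] == "CG"]
            fwd_map = {i: i for i in mol_cpgs}
            # reverse strand: strand position q maps to molecule position m-1-q;
            # the reverse-strand C of a CpG sits opposite the forward G at i+1.
            rev_map = {m - 2 - i: i for i in mol_cpgs}
            genome_pos = {i: frag.start + i for i in mol_cpgs}
            rc = reverse_complement(mol)

            def emit(states: dict[int, bool], forward: bool) -> None:
                if forward:
                    conv = _bisulfite_strand(
                        mol, states, fwd_map, conversion_rate, overconversion_rate, rng
                    )[:read_length]
                    strand = "+"
                else:
                    conv = _bisulfite_strand(
                        rc, states, rev_map, conversion_rate, overconversion_rate, rng
                    )[:read_length]
                    strand = "-"
                _mutate(conv, rng, error_rate)
                rid = f"{sample_id}:{frag.start}-{frag.end}:{strand}:{len(reads[sample_id])}"
                reads[sample_id].append(
                    RRBSRead(rid, sample_id, "".join(conv), (40,) * len(conv))
                )

            n_duplexes = rng.poisson(depth / 2.0 if paired_strands else depth)
            for _ in range(n_duplexes):
                states = {
                    i: bool(rng.random() < truth[(group, genome_pos[i])]) for i in mol_cpgs
                }
                for i in mol_cpgs:
                    key = (sample_id, genome_pos[i])
                    rec = tally.setdefault(key, [0, 0])
                    rec[0] += states[i]
                    rec[1] += 1
                if paired_strands:
                    emit(states, True)
                    emit(states, False)
                else:
                    emit(states, bool(rng.random() < 0.5))

    rows = []
    group_of = dict(zip(samples.sample_ids, samples.group_labels))
    for (sample_id, pos), (meth, total) in sorted(tally.items()):
        rows.append(
            {
                "sample_id": sample_id,
                "cpg_position": pos,
                "true_level": truth[(group_of[sample_id], pos)],
                "molecules_methylated": meth,
                "molecules_total": total,
            }
        )
    return reads, pd.DataFrame(rows)


def simulate_spike_ins(
    controls: Sequence[SpikeInControl] = DEFAULT_SPIKE_INS,
    conversion_rate: float = 1.0,
    overconversion_rate: float = 0.0,
    n_reads: int = 100,
    seed: int = 0,
    sample_id: str = "spikein",
) -> list[RRBSRead]:
    """Bisulfite reads from fully methylated / unmethylated control oligos.

    Unmethylated controls convert every C at ``conversion_rate``; methylated
    controls convert CpG Cs erroneously at ``overconversion_rate`` (their
    non-CpG Cs, if any, are treated as unmethylated).
    """
    rng = np.random.default_rng(seed)
    out = []
    for ctrl in controls:
        seq = ctrl.sequence
        cpgs = {i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"}
        for r in range(n_reads):
            bases = list(seq)
            for i, base in enumerate(bases):
                if base != "C":
                    continue
                if ctrl.methylated and i in cpgs:
                    if rng.random() < overconversion_rate:
                        bases[i] = "T"
                else:
                    if rng.random() < conversion_rate:
                        bases[i] = "T"
            out.append(
                RRBSRead(f"{ctrl.name}:{r}", sample_id, "".join(bases), (40,) * len(bases))
            )
    return out
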