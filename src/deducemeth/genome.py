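"""Construction of a deduced genome from trimmed bisulfite reads.

The builder turns per-sample RRBS reads into consensus fragment sequences
without any reference genome, in six steps:

1. pre-filter: deduplicate reads within each sample, then keep only
   converted (all-C-to-T) sequences observed at least ``min_multiplicity``
   times across samples;
2. preliminary grouping: reads identical after full conversion form one
   pre-consensus, restoring a C wherever >= ``c_call_threshold`` of the
   member reads (weighted by copy number) show a C;
3. clustering: pre-consensus sequences within ``merge_threshold`` mismatch
   ratio (ungapped, anchored at the MspI cut, over the shorter length) are
   merged into groups, largest group first;
4. refinement: members diverging from their group consensus by more than
   ``refine_threshold`` are split off and re-clustered until convergence;
5. strand merging: consensus sequences that become perfect reverse
   complements under the degenerate C->T / G->A transform are merged,
   pooling the cytosine evidence of the two strands;
6. concatenation: fragments are joined with runs of Ns into one deduced
   genome with a coordinate index.

Because a genomic cytosine survives in a consensus only if some covering
read shows a C, cytosines unmethylated in every sample are represented as
Ts — unless an opposite-strand read covers them, in which case strand
merging restores them (the complementary G is conversion-proof).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import RRBSRead, convert_c2t, convert_g2a, reverse_complement


@dataclass
class BuilderParams:
    """Tunable thresholds of the deduced-genome builder.

    Defaults are the method's published operating point: reads must occur at
    least twice across samples, a C is restored when at least 5% of reads
    show it, fragments under 8% mismatch are merged, members over 5%
    mismatch to their consensus are split off, and fragments are joined by
    50-N spacers (one read length).
    """

    min_multiplicity: int = 2
    c_call_threshold: float = 0.05
    merge_threshold: float = 0.08
    refine_threshold: float = 0.05
    spacer_length: int = 50
    restriction_start: str = r"[CT]GG"
    restriction_end: str = r"[CT][CT]G"
    max_refine_iterations: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.refine_threshold <= self.merge_threshold < 1):
            raise ValueError("need 0 < refine_threshold <= merge_threshold < 1")


@dataclass
class PreConsensus:
    """Consensus of reads sharing one fully converted sequence."""

    converted_key: str
    member_count: int  # total read copies collapsed into this pre-consensus
    c_fraction: tuple[float, ...]
    sequence: str

    def __post_init__(self) -> None:
        if convert_c2t(self.sequence) != self.converted_key:
            raise ValueError("consensus must reduce to its converted key")


@dataclass
class FragmentGroup:
    """A cluster of pre-consensus sequences with a joint consensus."""

    members: list[PreConsensus]
    representative: str

    @property
    def size(self) -> int:
        return sum(m.member_count for m in self.members)

    @property
    def seed_key(self) -> str:
        return convert_c2t(self.representative)


@dataclass(frozen=True)
class DeducedFragment:
    fragment_id: str
    sequence: str
    n_reads: int
    strand_merged: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("fragment sequence must be non-empty")


@dataclass
class DeducedGenome:
    """Ordered fragments plus their coordinates in the N-spaced concatenation."""

    fragments: list[DeducedFragment]
    spacer_length: int = 50
    coordinate_index: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.coordinate_index:
            offset = 0
            for i, frag in enumerate(self.fragments):
                if i:
                    offset += self.spacer_length
                self.coordinate_index[frag.fragment_id] = (offset, offset + len(frag.sequence))
                offset += len(frag.sequence)

    @property
    def sequence(self) -> str:
        return ("N" * self.spacer_length).join(f.sequence for f in self.fragments)

    def fragment_by_id(self, fragment_id: str) -> DeducedFragment:
        for f in self.fragments:
            if f.fragment_id == fragment_id:
                return f
        raise KeyError(fragment_id)

    def to_fasta_records(self) -> list[tuple[str, str]]:
        return [(f.fragment_id, f.sequence) for f in self.fragments]


# ---------------------------------------------------------------------------
# Step 1: pre-filtering
# ---------------------------------------------------------------------------


def prefilter_reads(
    reads_by_sample: Mapping[str, Iterable[RRBSRead]],
    params: BuilderParams,
) -> dict[str, list[tuple[str, int]]]:
    """Collapse duplicates and drop rare converted sequences.

    Returns converted_key -> list of (unconverted representative, copy
    count).  Within each sample exact duplicate sequences collapse to one
    representative (the first seen) whose copy count is retained as weight.
    A converted key survives when its multiplicity — the number of
    representatives (distinct sequence per sample) sharing it — reaches
    ``min_multiplicity``.  Reads containing N are excluded from genome
    building.
    """
    any_read = False
    by_key: dict[str, dict[tuple[str, str], int]] = {}
    for sample_id, reads in reads_by_sample.items():
        for read in reads:
            any_read = True
            if "N" in read.sequence:
                continue
            seq = read.sequence
            key = read.converted_sequence
            members = by_key.setdefault(key, {})
            members[(sample_id, seq)] = members.get((sample_id, seq), 0) + 1
    if not any_read:
        raise ValueError("no reads for genome construction")
    out: dict[str, list[tuple[str, int]]] = {}
    for key, members in by_key.items():
        if len(members) < params.min_multiplicity:
            continue
        out[key] = [(seq, count) for (_sample, seq), count in sorted(members.items())]
    return out


# ---------------------------------------------------------------------------
# Step 2: preliminary grouping
# ---------------------------------------------------------------------------


def _restore_cs(key: str, members: Sequence[tuple[str, int]], threshold: float) -> tuple[str, tuple[float, ...]]:
    """C-restoration rule: position becomes C when the weighted fraction of
    members showing C reaches ``threshold`` (inclusive)."""
    total = sum(w for _, w in members)
    fractions = []
    out = list(key)
    for i, base in enumerate(key):
        c_weight = sum(w for seq, w in members if i < len(seq) and seq[i] == "C")
        frac = c_weight / total if total else 0.0
        fractions.append(frac)
        if base == "T" and frac >= threshold:
            out[i] = "C"
    return "".join(out), tuple(fractions)


def preliminary_grouping(
    filtered: Mapping[str, Sequence[tuple[str, int]]],
    params: BuilderParams,
) -> list[PreConsensus]:
    """One pre-consensus per converted key, with the 5% C-restoration rule."""
    out = []
    for key in sorted(filtered):
        members = filtered[key]
        seq, fractions = _restore_cs(key, members, params.c_call_threshold)
        out.append(
            PreConsensus(
                converted_key=key,
                member_count=sum(w for _, w in members),
                c_fraction=fractions,
                sequence=seq,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Step 3: clustering
# ---------------------------------------------------------------------------


def mismatch_ratio(a: str, b: str) -> float:
    """Ungapped mismatch ratio anchored at position 0, over the shorter length."""
    n = min(len(a), len(b))
    if n == 0:
        return 1.0
    mism = sum(1 for i in range(n) if a[i] != b[i])
    return mism / n


def _group_consensus(members: Sequence[PreConsensus], threshold: float) -> str:
    """Weighted per-position majority with C restoration at ``threshold``.

    The consensus spans the longest member; each position is decided by the
    members long enough to cover it.
    """
    length = max(len(m.sequence) for m in members)
    out = []
    for i in range(length):
        weights: dict[str, int] = {}
        c_weight = 0
        total = 0
        for m in members:
            if i >= len(m.sequence):
                continue
            base = m.sequence[i]
            w = m.member_count
            total += w
            # weight the member's own C evidence, not just its consensus call
            c_w = round(m.c_fraction[i] * m.member_count)
            c_weight += c_w
            if base == "C":
                base = "T"  # majority vote happens on the converted frame
            weights[base] = weights.get(base, 0) + w
        best = max(sorted(weights), key=lambda b: weights[b])
        if best == "T" and total and c_weight / total >= threshold:
            best = "C"
        out.append(best)
    return "".join(out)


def cluster_fragments(
    pre: Sequence[PreConsensus], params: BuilderParams
) -> list[FragmentGroup]:
    """Greedy similarity clustering of pre-consensus sequences.

    Sequences are processed in descending member_count (ties lexicographic
    by converted key); each joins the largest existing group whose seed is
    within ``merge_threshold`` (strict) mismatch ratio, else seeds a new
    group.  Group consensus applies the majority + C-restoration rule.
    """
    ordered = sorted(pre, key=lambda p: (-p.member_count, p.converted_key))
    groups: list[FragmentGroup] = []
    for item in ordered:
        candidates = [
            g
            for g in groups
            if mismatch_ratio(item.converted_key, g.seed_key) < params.merge_threshold
        ]
        if candidates:
            target = min(candidates, key=lambda g: (-g.size, g.seed_key))
            target.members.append(item)
        else:
            groups.append(FragmentGroup(members=[item], representative=item.sequence))
    for g in groups:
        g.representative = _group_consensus(g.members, params.c_call_threshold)
    return groups


# ---------------------------------------------------------------------------
# Step 4: refinement
# ---------------------------------------------------------------------------


def refine_consensus(
    groups: Sequence[FragmentGroup], params: BuilderParams
) -> list[FragmentGroup]:
    """Split members that diverge > ``refine_threshold`` from their consensus.

    Divergent members are removed and re-clustered among themselves; this
    repeats until no member exceeds the threshold (mismatch computed on the
    converted frame, over the shorter length).
    """
    current = [FragmentGroup(members=list(g.members), representative=g.representative) for g in groups]
    for _ in range(params.max_refine_iterations):
        next_groups: list[FragmentGroup] = []
        outliers: list[PreConsensus] = []
        changed = False
        for g in current:
            seed = convert_c2t(g.representative)
            keep = [m for m in g.members if mismatch_ratio(m.converted_key, seed) <= params.refine_threshold]
            out = [m for m in g.members if m not in keep]
            if out:
                changed = True
                outliers.extend(out)
            if keep:
                ng = FragmentGroup(members=keep, representative="")
                ng.representative = _group_consensus(keep, params.c_call_threshold)
                next_groups.append(ng)
        if outliers:
            next_groups.extend(cluster_fragments(outliers, params))
        current = next_groups
        if not changed:
            return current
    raise RuntimeError(
        f"consensus refinement did not converge in {params.max_refine_iterations} "
        f"iterations ({len(current)} groups)"
    )


# ---------------------------------------------------------------------------
# Step 5: strand merging
# ---------------------------------------------------------------------------


def _degenerate(seq: str) -> str:
    """C->T and G->A transform collapsing bisulfite ambiguity on both strands."""
    return convert_g2a(convert_c2t(seq))


def merge_reverse_complements(
    groups: Sequence[FragmentGroup], params: BuilderParams
) -> list[DeducedFragment]:
    """Pair opposite-strand consensus sequences and pool their C evidence.

    Only sequences starting with ``restriction_start`` and ending with
    ``restriction_end`` are candidates.  Two equal-length candidates pair
    when their degenerate transforms are exact reverse complements; the
    merged sequence takes the forward partner and sets a C at every T that
    faces a C in the literal reverse complement of its partner.  Each
    fragment merges at most once (greedy, larger groups first).
    """
    start_re = re.compile(f"^{params.restriction_start}")
    end_re = re.compile(f"{params.restriction_end}$")
    ordered = sorted(
        enumerate(groups), key=lambda ig: (-ig[1].size, ig[1].representative)
    )
    candidates = {
        i: bool(start_re.search(g.representative) and end_re.search(g.representative))
        for i, g in enumerate(groups)
    }
    by_transform: dict[str, list[int]] = {}
    for i, g in ordered:
        if candidates[i]:
            by_transform.setdefault(_degenerate(g.representative), []).append(i)

    merged: dict[int, DeducedFragment] = {}
    used: set[int] = set()
    for i, g in ordered:
        if i in used:
            continue
        partner_idx = None
        if candidates[i]:
            want = reverse_complement(_degenerate(g.representative))
            for j in by_transform.get(want, []):
                if j != i and j not in used and len(groups[j].representative) == len(g.representative):
                    partner_idx = j
                    break
        if partner_idx is None:
            merged[i] = DeducedFragment(
                fragment_id="", sequence=g.representative, n_reads=g.size
            )
            used.add(i)
            continue
        partner = groups[partner_idx]
        rc_partner = reverse_complement(partner.representative)
        seq = list(g.representative)
        for k, base in enumerate(seq):
            if base == "T" and k < len(rc_partner) and rc_partner[k] == "C":
                seq[k] = "C"
        # a merged fragment represents both strands: canonicalize to the
        # lexicographically smaller orientation so rebuilding from the
        # deduced genome is a fixed point
        merged_seq = "".join(seq)
        merged_seq = min(merged_seq, reverse_complement(merged_seq))
        merged[i] = DeducedFragment(
            fragment_id="",
            sequence=merged_seq,
            n_reads=g.size + partner.size,
            strand_merged=True,
        )
        used.add(i)
        used.add(partner_idx)

    return _assign_ids(list(merged.values()))


def _assign_ids(fragments: Sequence[DeducedFragment]) -> list[DeducedFragment]:
    ordered = sorted(fragments, key=lambda f: (-f.n_reads, f.sequence))
    width = max(6, len(str(len(ordered))))
    return [
        DeducedFragment(f"frag_{i:0{width}d}", f.sequence, f.n_reads, f.strand_merged)
        for i, f in enumerate(ordered, start=1)
    ]


# ---------------------------------------------------------------------------
# Step 6: concatenation
# ---------------------------------------------------------------------------


def concatenate_genome(
    fragments: Sequence[DeducedFragment], params: BuilderParams
) -> DeducedGenome:
    """Join fragments (descending n_reads, ties by sequence) with N spacers."""
    if not fragments:
        raise ValueError("cannot build a deduced genome from zero fragments")
    ordered = sorted(fragments, key=lambda f: (-f.n_reads, f.sequence))
    return DeducedGenome(fragments=list(ordered), spacer_length=params.spacer_length)


def build_deduced_genome(
    reads_by_sample: Mapping[str, Iterable[RRBSRead]],
    params: BuilderParams | None = None,
) -> DeducedGenome:
    """Run the full six-step deduced-genome construction."""
    params = params or BuilderParams()
    filtered = prefilter_reads(reads_by_sample, params)
    if not filtered:
        raise ValueError("no reads for genome construction")
    pre = preliminary_grouping(filtered, params)
    groups = cluster_fragments(pre, params)
    groups = refine_consensus(groups, params)
    fragments = merge_reverse_complements(groups, params)
    return concatenate_genome(fragments, params)


def fragment_table(genome: DeducedGenome) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "fragment_id": f.fragment_id,
                "length": len(f.sequence),
                "n_reads": f.n_reads,
                "strand_merged": f.strand_merged,
            }
            for f in genome.fragments
        ]
    )
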