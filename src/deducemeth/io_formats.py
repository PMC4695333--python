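"""Readers, writers and read trimming for the external formats of the pipeline.

Covers FASTQ (optionally gzipped), FASTA, MEME-minimal / JASPAR pfm motif
matrices, tab-separated per-site methylation call tables and YAML/TSV sample
sheets.  Quality/adapter trimming of raw RRBS reads also lives here because it
operates purely on the read records.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

# Illumina TruSeq single-end adapter as used for RRBS trimming.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
PHRED_OFFSET = 33

_CONV_C2T = str.maketrans("C", "T")
_CONV_G2A = str.maketrans("G", "A")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def convert_c2t(seq: str) -> str:
    """Fully bisulfite-convert a sequence in silico (every C becomes T)."""
    return seq.translate(_CONV_C2T)


def convert_g2a(seq: str) -> str:
    return seq.translate(_CONV_G2A)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RRBSRead:
    """One sequenced bisulfite read with sample identity and quality."""

    read_id: str
    sample_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None
    _converted: str | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def converted_sequence(self) -> str:
        """The all-C-to-T converted sequence (cached)."""
        if self._converted is None:
            self._converted = convert_c2t(self.sequence)
        return self._converted

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MotifMatrix:
    """A position frequency matrix over A, C, G, T.

    ``frequencies`` has shape (length, 4) with rows summing to one; column
    order is A, C, G, T.
    """

    motif_id: str
    frequencies: np.ndarray
    pseudocount: float = 0.0

    BASE_ORDER = "ACGT"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.ndim != 2 or self.frequencies.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id!r}: matrix must be (length, 4)")
        if self.frequencies.shape[0] < 1:
            raise ValueError(f"motif {self.motif_id!r}: length must be >= 1")
        sums = self.frequencies.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"motif {self.motif_id!r}: rows must sum to 1")

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    def reverse_complement(self) -> "MotifMatrix":
        """Matrix scanning the opposite strand: reverse positions, swap A<->T, C<->G."""
        rc = self.frequencies[::-1, ::-1].copy()
        return MotifMatrix(self.motif_id, rc, self.pseudocount)


@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-group assignment with optional FASTQ paths."""

    sample_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    fastq_paths: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if len(self.group_labels) != len(self.sample_ids):
            raise ValueError("one group label per sample required")
        if self.fastq_paths is not None and len(self.fastq_paths) != len(self.sample_ids):
            raise ValueError("one fastq path per sample required")

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, grp in zip(self.sample_ids, self.group_labels):
            out.setdefault(grp, []).append(sid)
        return out

    def validate_for_differential(self) -> None:
        groups = self.groups
        if len(groups) < 2:
            raise ValueError("differential analysis needs >= 2 groups")
        for label, members in groups.items():
            if len(members) < 2:
                raise ValueError(f"group {label!r} has < 2 samples")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Load a sample sheet from YAML (list of mappings) or TSV."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            records = yaml.safe_load(fh)
        rows = [(r["sample_id"], r["group_label"], r.get("fastq_path")) for r in records]
    else:
        df = pd.read_csv(path, sep="\t")
        rows = [
            (str(r.sample_id), str(r.group_label), getattr(r, "fastq_path", None))
            for r in df.itertuples()
        ]
    paths = tuple(str(r[2]) for r in rows) if all(r[2] is not None for r in rows) else None
    return SampleSheet(
        sample_ids=tuple(r[0] for r in rows),
        group_labels=tuple(r[1] for r in rows),
        fastq_paths=paths,
    )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path, sample_id: str = "") -> Iterator[RRBSRead]:
    """Stream reads from a (possibly gzipped) 4-line FASTQ file.

    Malformed records (sequence/quality length mismatch) raise a ValueError
    naming the 0-based record index.
    """
    with _open_text(path) as handle:
        index = 0
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index} in {path}: {exc}") from exc
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {index} in {path}: "
                    f"sequence and quality lengths differ"
                )
            quals = tuple(ord(c) - PHRED_OFFSET for c in qual)
            yield RRBSRead(title.split()[0], sample_id, seq.upper(), quals)
            index += 1


def write_fastq(reads: Iterable[RRBSRead], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for read in reads:
            quals = read.qualities
            if quals is None:
                quals = (40,) * len(read.sequence)
            qstr = "".join(chr(q + PHRED_OFFSET) for q in quals)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qstr}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------


def _quality_trim_index(qualities: Sequence[int], cutoff: int) -> int:
    """3' cut index under the BWA running-sum rule.

    Scanning from the 3' end, accumulate (cutoff - q); the read is cut at the
    position where the running sum is maximal (leftmost maximum), provided the
    maximum is positive.  A full scan (no early break) makes the rule
    idempotent: re-trimming the trimmed read never removes further bases.
    """
    best = 0
    cut = len(qualities)
    running = 0
    for i in range(len(qualities) - 1, -1, -1):
        running += cutoff - qualities[i]
        if running >= best and running > 0:
            best = running
            cut = i
    return cut


def _adapter_trim_index(seq: str, adapter: str, error_rate: float, min_overlap: int) -> int:
    """Leftmost position where a read suffix matches an adapter prefix.

    Overlap ``ov`` at position p compares seq[p:p+ov] with adapter[:ov]
    (ov = min(remaining read, adapter length)); accepted when mismatches
    <= floor(error_rate * ov) and ov >= min_overlap.  Returns len(seq) when
    no position qualifies.
    """
    n = len(seq)
    alen = len(adapter)
    for p in range(n):
        ov = min(n - p, alen)
        if ov < min_overlap:
            break
        allowed = int(error_rate * ov)
        mismatches = 0
        ok = True
        for j in range(ov):
            if seq[p + j] != adapter[j]:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return p
    return n


def trim_read(
    read: RRBSRead,
    quality_cutoff: int = 20,
    adapter: str = DEFAULT_ADAPTER,
    min_length: int = 16,
    error_rate: float = 0.1,
    min_overlap: int = 1,
) -> RRBSRead | None:
    """Quality- and adapter-trim one read; returns None when it is discarded.

    3' quality trimming (running-sum rule) and adapter removal
    (suffix-vs-prefix match at ``error_rate`` mismatches, minimum overlap
    ``min_overlap``) alternate until neither removes anything — removing an
    adapter can expose a low-quality tail and vice versa — which makes the
    whole operation idempotent.  Reads shorter than ``min_length`` after
    trimming are discarded.
    """
    seq = read.sequence
    quals = read.qualities
    changed = True
    while changed and seq:
        changed = False
        if quals is not None:
            cut = _quality_trim_index(quals, quality_cutoff)
            if cut < len(seq):
                seq, quals = seq[:cut], quals[:cut]
                changed = True
        p = _adapter_trim_index(seq, adapter, error_rate, min_overlap)
        if p < len(seq):
            seq = seq[:p]
            if quals is not None:
                quals = quals[:p]
            changed = True
    if len(seq) < min_length:
        return None
    return RRBSRead(read.read_id, read.sample_id, seq, quals)


# ---------------------------------------------------------------------------
# Motif matrices
# ---------------------------------------------------------------------------


def _normalize_counts(counts: np.ndarray, motif_id: str, pseudocount: float) -> np.ndarray:
    counts = np.asarray(counts, dtype=float) + pseudocount
    sums = counts.sum(axis=1)
    bad = np.nonzero(sums <= 0)[0]
    if bad.size:
        raise ValueError(f"motif {motif_id!r}: position {bad[0]} does not sum to a positive total")
    return counts / sums[:, None]


def read_meme_motifs(path: str | Path, pseudocount: float = 0.0) -> list[MotifMatrix]:
    """Parse motif matrices from MEME minimal format or JASPAR pfm files.

    Counts (JASPAR) or probabilities (MEME) are normalized per position after
    adding ``pseudocount``.
    """
    text = _open_text(path).read()
    if "letter-probability matrix" in text:
        return _parse_meme(text, pseudocount)
    return _parse_jaspar(text, pseudocount)


def _parse_meme(text: str, pseudocount: float) -> list[MotifMatrix]:
    motifs: list[MotifMatrix] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1] if len(parts) > 1 else f"motif_{len(motifs)}"
            # advance to the letter-probability header
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            i += 1
            rows = []
            while i < len(lines):
                vals = lines[i].split()
                if len(vals) != 4:
                    break
                try:
                    rows.append([float(v) for v in vals])
                except ValueError:
                    break
                i += 1
            if not rows:
                raise ValueError(f"motif {motif_id!r}: empty probability matrix")
            motifs.append(MotifMatrix(motif_id, _normalize_counts(np.array(rows), motif_id, pseudocount), pseudocount))
        else:
            i += 1
    return motifs


def _parse_jaspar(text: str, pseudocount: float) -> list[MotifMatrix]:
    motifs: list[MotifMatrix] = []
    blocks: list[tuple[str, list[str]]] = []
    current: tuple[str, list[str]] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current:
                blocks.append(current)
            current = (line[1:].split()[0], [])
        elif current is not None:
            current[1].append(line)
    if current:
        blocks.append(current)
    for motif_id, rows in blocks:
        if len(rows) != 4:
            raise ValueError(f"motif {motif_id!r}: expected 4 base rows, got {len(rows)}")
        matrix = {}
        for row in rows:
            m = re.match(r"([ACGT])\s*\[?\s*([\d.\s]+)\]?", row)
            if not m:
                raise ValueError(f"motif {motif_id!r}: unparseable row {row!r}")
            matrix[m.group(1)] = [float(v) for v in m.group(2).split()]
        counts = np.array([matrix[b] for b in "ACGT"]).T
        motifs.append(MotifMatrix(motif_id, _normalize_counts(counts, motif_id, pseudocount), pseudocount))
    return motifs


def write_meme_motifs(motifs: Iterable[MotifMatrix], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.length}\n")
            for row in m.frequencies:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Methylation call tables
# ---------------------------------------------------------------------------

CALL_TABLE_COLUMNS = [
    "fragment_id",
    "start",
    "end",
    "strand",
    "sample_id",
    "count_methylated",
    "count_unmethylated",
    "level",
]


def write_methylation_table(calls: Iterable, path: str | Path) -> None:
    """Write per-site calls as a BED-like TSV (0-based half-open, strand '+')."""
    rows = []
    for c in calls:
        total = c.count_methylated + c.count_unmethylated
        level = c.count_methylated / total if total else float("nan")
        rows.append(
            (c.fragment_id, c.position, c.position + 1, "+", c.sample_id,
             c.count_methylated, c.count_unmethylated, level)
        )
    df = pd.DataFrame(rows, columns=CALL_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_methylation_table(path: str | Path):
    """Read back a call table written by :func:`write_methylation_table`."""
    from .calling import SiteMethylation

    df = pd.read_csv(path, sep="\t")
    return [
        SiteMethylation(
            fragment_id=str(r.fragment_id),
            position=int(r.start),
            sample_id=str(r.sample_id),
            count_methylated=int(r.count_methylated),
            count_unmethylated=int(r.count_unmethylated),
        )
        for r in df.itertuples()
    ]
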