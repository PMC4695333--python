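"""End-to-end orchestration of the reference-free workflow.

Stages: trim -> deduce genome -> align -> call/filter -> differential ->
top-fragment export -> motif enrichment.  Every stage writes its outputs to
the run directory in plain-text formats and a JSON manifest records a config
snapshot plus per-stage input checksums; with ``resume=True`` a stage whose
input checksum matches the previous run reloads its outputs from disk
instead of recomputing, so changing e.g. the coverage filter re-executes
only the stages downstream of it.  All randomness flows from a single seed;
a fixed (config, seed) pair yields byte-identical outputs, and alignment may
be partitioned across threads by sample without changing any output.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import align as _align
from . import calling as _calling
from . import diffmeth as _diffmeth
from . import genome as _genome
from . import io_formats as _io
from . import motifs as _motifs
from . import simulate as _simulate


@dataclass
class PipelineConfig:
    sample_sheet: str
    output_dir: str
    builder: _genome.BuilderParams = field(default_factory=_genome.BuilderParams)
    aligner: _align.AlignerParams = field(default_factory=_align.AlignerParams)
    coverage: _calling.CoverageFilter = field(default_factory=_calling.CoverageFilter)
    moderation: _diffmeth.ModerationParams = field(default_factory=_diffmeth.ModerationParams)
    shuffle: _motifs.ShuffleParams = field(default_factory=_motifs.ShuffleParams)
    contexts: tuple[str, ...] = ("CpG",)
    motif_db: str | None = None
    top_n: int = 500
    min_mean_coverage: float = 2.0
    max_adjusted_p: float = 0.05
    threads: int = 1
    seed: int = 0
    resume: bool = False

    def snapshot(self) -> dict:
        return asdict(self)


def _checksum(parts: Sequence[str]) -> str:
    h = hashlib.sha256()
    for part in parts:
        h.update(part.encode())
        h.update(b"\0")
    return h.hexdigest()


def _file_hash(*paths: Path) -> str:
    h = hashlib.sha256()
    for path in paths:
        h.update(Path(path).read_bytes())
        h.update(b"\0")
    return h.hexdigest()


class PipelineRun:
    """One pipeline execution rooted at ``config.output_dir``."""

    def __init__(self, config: PipelineConfig) -> None:
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest: dict = {"config": config.snapshot(), "stages": {}}
        self._previous: dict = {}
        if config.resume and self.manifest_path.exists():
            self._previous = json.loads(self.manifest_path.read_text())
        self.log_lines: list[str] = []
        self.executed_stages: list[str] = []

    # -- plumbing -----------------------------------------------------------

    def _fresh(self, stage: str, input_hash: str, outputs: Sequence[Path]) -> bool:
        prev = self._previous.get("stages", {}).get(stage)
        if not self.config.resume or prev is None:
            return False
        if prev.get("input_hash") != input_hash:
            return False
        return all(p.exists() for p in outputs)

    def _record(self, stage: str, input_hash: str, seconds: float, skipped: bool, **counts) -> None:
        self.manifest["stages"][stage] = {
            "input_hash": input_hash,
            "wall_time_s": round(seconds, 3),
            "skipped": skipped,
            **counts,
        }
        if not skipped:
            self.executed_stages.append(stage)
        line = f"[{stage}] " + " ".join(f"{k}={v}" for k, v in counts.items())
        if skipped:
            line += " (resumed)"
        self.log_lines.append(line)

    def _write_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    # -- run ----------------------------------------------------------------

    def run(self, reads_by_sample: Mapping[str, list[_io.RRBSRead]] | None = None) -> Path:
        """Execute all stages; ``reads_by_sample`` bypasses FASTQ loading."""
        cfg = self.config
        sheet = _io.read_sample_sheet(cfg.sample_sheet)
        sheet.validate_for_differential()

        if reads_by_sample is None:
            if sheet.fastq_paths is None:
                raise ValueError("sample sheet has no fastq paths and no reads were supplied")
            reads_by_sample = {
                sid: list(_io.read_fastq(path, sample_id=sid))
                for sid, path in zip(sheet.sample_ids, sheet.fastq_paths)
            }

        trimmed = self._stage_trim(reads_by_sample)
        genome = self._stage_deduce(trimmed)
        alignments = self._stage_align(trimmed, genome)
        reads_by_id = {
            r.read_id: r.sequence for reads in trimmed.values() for r in reads
        }
        filtered, coverage_map = self._stage_call(alignments, reads_by_id, genome, sheet)
        ranked = self._stage_differential(filtered, sheet, coverage_map)
        exported = self._stage_export(ranked, genome)
        self._stage_motifs(exported)
        self.manifest["log"] = self.log_lines
        self._write_manifest()
        return self.out

    # -- stages -------------------------------------------------------------

    def _stage_trim(self, reads_by_sample):
        t0 = time.time()
        input_hash = _checksum(
            [f"{sid}:{r.read_id}:{r.sequence}" for sid in sorted(reads_by_sample) for r in reads_by_sample[sid]]
        )
        sids = sorted(reads_by_sample)
        outputs = [self.out / f"trimmed_{sid}.fastq" for sid in sids]
        if self._fresh("trim", input_hash, outputs):
            trimmed = {
                sid: list(_io.read_fastq(path, sample_id=sid))
                for sid, path in zip(sids, outputs)
            }
            self._record("trim", input_hash, time.time() - t0, True,
                         reads_out=sum(len(v) for v in trimmed.values()))
            return trimmed
        trimmed: dict[str, list[_io.RRBSRead]] = {}
        n_in = 0
        for sid, path in zip(sids, outputs):
            kept = []
            for read in reads_by_sample[sid]:
                n_in += 1
                t = _io.trim_read(read)
                if t is not None:
                    kept.append(t)
            trimmed[sid] = kept
            _io.write_fastq(kept, path)
        n_out = sum(len(v) for v in trimmed.values())
        self._record("trim", input_hash, time.time() - t0, False, reads_in=n_in, reads_out=n_out)
        return trimmed

    def _stage_deduce(self, trimmed):
        t0 = time.time()
        input_hash = _checksum(
            [str(asdict(self.config.builder))]
            + [f"{sid}:{r.sequence}" for sid in sorted(trimmed) for r in trimmed[sid]]
        )
        fasta = self.out / "deduced_genome.fa"
        frag_fasta = self.out / "deduced_fragments.fa"
        table_path = self.out / "deduced_fragments.tsv"
        if self._fresh("deduce", input_hash, [fasta, frag_fasta, table_path]):
            table = pd.read_csv(table_path, sep="\t")
            seqs = dict(_io.read_fasta(frag_fasta))
            fragments = [
                _genome.DeducedFragment(
                    str(r.fragment_id), seqs[str(r.fragment_id)], int(r.n_reads), bool(r.strand_merged)
                )
                for r in table.itertuples()
            ]
            genome = _genome.DeducedGenome(fragments, self.config.builder.spacer_length)
            self._record("deduce", input_hash, time.time() - t0, True, fragments=len(fragments))
            return genome
        genome = _genome.build_deduced_genome(trimmed, self.config.builder)
        _io.write_fasta([("deduced_genome", genome.sequence)], fasta)
        _io.write_fasta(genome.to_fasta_records(), frag_fasta)
        _genome.fragment_table(genome).to_csv(table_path, sep="\t", index=False)
        self._record("deduce", input_hash, time.time() - t0, False, fragments=len(genome.fragments))
        return genome

    def _align_one(self, sid, reads, index):
        records, eff = _align.align_sample(reads, index, self.config.aligner)
        return sid, records, eff

    def _stage_align(self, trimmed, genome):
        t0 = time.time()
        input_hash = _checksum(
            [genome.sequence, str(asdict(self.config.aligner))]
            + [f"{sid}:{r.sequence}" for sid in sorted(trimmed) for r in trimmed[sid]]
        )
        table_path = self.out / "alignments.tsv"
        summary_path = self.out / "alignment_summary.tsv"
        if self._fresh("align", input_hash, [table_path, summary_path]):
            df = pd.read_csv(table_path, sep="\t")
            alignments = [
                _align.AlignmentRecord(
                    str(r.read_id), str(r.sample_id), str(r.fragment_id),
                    int(r.offset), str(r.orientation), int(r.length),
                    int(r.mismatches), int(r.mapq_proxy),
                )
                for r in df.itertuples()
            ]
            self._record("align", input_hash, time.time() - t0, True, aligned=len(alignments))
            return alignments
        index = _align.build_index(genome, self.config.aligner)
        sids = sorted(trimmed)
        results = {}
        if self.config.threads > 1:
            from concurrent.futures import ThreadPoolExecutor

            with ThreadPoolExecutor(max_workers=self.config.threads) as pool:
                futures = [
                    pool.submit(self._align_one, sid, trimmed[sid], index) for sid in sids
                ]
                for fut in futures:
                    sid, records, eff = fut.result()
                    results[sid] = (records, eff)
        else:
            for sid in sids:
                _, records, eff = self._align_one(sid, trimmed[sid], index)
                results[sid] = (records, eff)
        alignments = []
        summary_rows = []
        for sid in sids:
            records, eff = results[sid]
            alignments.extend(records)
            summary_rows.append(
                {"sample_id": sid, "reads": len(trimmed[sid]), "aligned": len(records),
                 "efficiency": round(eff, 6)}
            )
        pd.DataFrame(
            [asdict(a) for a in alignments],
            columns=["read_id", "sample_id", "fragment_id", "offset", "orientation",
                     "length", "mismatches", "mapq_proxy"],
        ).to_csv(table_path, sep="\t", index=False)
        pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
        eff_all = sum(r["aligned"] for r in summary_rows) / max(1, sum(r["reads"] for r in summary_rows))
        self._record("align", input_hash, time.time() - t0, False,
                     aligned=len(alignments), efficiency=round(eff_all, 4))
        return alignments

    def _stage_call(self, alignments, reads_by_id, genome, sheet):
        t0 = time.time()
        input_hash = _checksum(
            [_file_hash(self.out / "alignments.tsv"),
             str(asdict(self.config.coverage)), ",".join(self.config.contexts)]
        )
        raw_path = self.out / "methylation_calls.tsv"
        filt_path = self.out / "methylation_calls_filtered.tsv"
        if self._fresh("call", input_hash, [raw_path, filt_path]):
            filtered = _io.read_methylation_table(filt_path)
            self._record("call", input_hash, time.time() - t0, True,
                         passing=len({(c.fragment_id, c.position) for c in filtered}))
        else:
            calls = _calling.call_methylation(
                alignments, reads_by_id, genome, set(self.config.contexts)
            )
            _io.write_methylation_table(calls, raw_path)
            filtered = _calling.filter_sites(calls, self.config.coverage)
            _io.write_methylation_table(filtered, filt_path)
            self._record("call", input_hash, time.time() - t0, False,
                         sites=len({(c.fragment_id, c.position) for c in calls}),
                         passing=len({(c.fragment_id, c.position) for c in filtered}))
        cov_acc: dict[tuple[str, int], list[int]] = {}
        for c in filtered:
            cov_acc.setdefault((c.fragment_id, c.position), []).append(c.coverage)
        coverage_map = {k: float(np.mean(v)) for k, v in cov_acc.items()}
        return filtered, coverage_map

    def _stage_differential(self, filtered, sheet, coverage_map):
        t0 = time.time()
        input_hash = _checksum(
            [_file_hash(self.out / "methylation_calls_filtered.tsv"),
             str(asdict(self.config.moderation)), ",".join(sheet.group_labels)]
        )
        site_path = self.out / "site_results.tsv"
        frag_path = self.out / "fragment_results.tsv"
        matrix_path = self.out / "methylation_matrix.tsv"
        if self._fresh("differential", input_hash, [site_path, frag_path, matrix_path]):
            df = pd.read_csv(frag_path, sep="\t")
            ranked = [
                _diffmeth.FragmentTestResult(
                    str(r.fragment_id), float(r.combined_p), float(r.mean_diff),
                    float(r.log_fold_change), float(r.mean_coverage),
                    int(r.rank_p), int(r.rank_lfc), int(r.rank_diff),
                )
                for r in df.itertuples()
            ]
            self._record("differential", input_hash, time.time() - t0, True, fragments=len(ranked))
            return ranked
        levels, _cov = _calling.build_methylation_matrix(filtered, sheet)
        levels.to_csv(matrix_path, sep="\t")
        site_results = _diffmeth.moderated_t_test(levels, sheet.groups, self.config.moderation)
        _diffmeth.site_results_table(site_results).to_csv(site_path, sep="\t", index=False)
        frags = _diffmeth.evaluate_fragments(
            site_results, coverage_map, epsilon=self.config.moderation.epsilon
        )
        ranked = _diffmeth.rank_fragments(frags)
        _diffmeth.fragment_results_table(ranked).to_csv(frag_path, sep="\t", index=False)
        self._record("differential", input_hash, time.time() - t0, False,
                     sites_tested=len(site_results), fragments=len(ranked))
        return ranked

    def _stage_export(self, ranked, genome):
        t0 = time.time()
        input_hash = _checksum(
            [str(self.config.top_n), str(self.config.min_mean_coverage),
             str(self.config.max_adjusted_p),
             _file_hash(self.out / "fragment_results.tsv",
                        self.out / "deduced_fragments.fa")]
        )
        paths = {
            d: self.out / f"top_fragments_{d}.fa" for d in ("hyper_group1", "hyper_group2")
        }
        if self._fresh("export", input_hash, list(paths.values())):
            exported = {d: _io.read_fasta(p) for d, p in paths.items()}
            self._record("export", input_hash, time.time() - t0, True,
                         **{d: len(v) for d, v in exported.items()})
            return exported
        sequences = {f.fragment_id: f.sequence for f in genome.fragments}
        exported = _diffmeth.select_top_fragments(
            ranked, sequences, n=self.config.top_n,
            min_mean_coverage=self.config.min_mean_coverage,
            max_adjusted_p=self.config.max_adjusted_p,
        )
        for direction, records in exported.items():
            _io.write_fasta(records, paths[direction])
        self._record("export", input_hash, time.time() - t0, False,
                     **{d: len(v) for d, v in exported.items()})
        return exported

    def _stage_motifs(self, exported):
        t0 = time.time()
        if self.config.motif_db is None:
            self.manifest["stages"]["motifs"] = {"skipped": True, "reason": "no motif_db"}
            self.log_lines.append("[motifs] skipped (no motif database configured)")
            return None
        fg = [seq for _, seq in exported["hyper_group1"]]
        bg = [seq for _, seq in exported["hyper_group2"]]
        input_hash = _checksum(
            [self.config.motif_db, str(asdict(self.config.shuffle))] + fg + bg
        )
        table_path = self.out / "motif_results.tsv"
        if self._fresh("motifs", input_hash, [table_path]):
            self._record("motifs", input_hash, time.time() - t0, True)
            return None
        if not fg or not bg:
            self._record("motifs", input_hash, time.time() - t0, False, motifs=0)
            return None
        motifs = _io.read_meme_motifs(self.config.motif_db, pseudocount=0.5)
        results = _motifs.differential_motif_analysis(fg, bg, motifs, self.config.shuffle)
        _motifs.results_table(results).to_csv(table_path, sep="\t", index=False)
        self._record("motifs", input_hash, time.time() - t0, False,
                     motifs=len(results),
                     differential=sum(r.verdict == "differential" for r in results))
        return results


def run_pipeline(
    config: PipelineConfig,
    reads_by_sample: Mapping[str, list[_io.RRBSRead]] | None = None,
) -> PipelineRun:
    run = PipelineRun(config)
    run.run(reads_by_sample)
    return run


# ---------------------------------------------------------------------------
# Self test
# ---------------------------------------------------------------------------


def selftest(seed: int = 0, out_dir: str | Path | None = None, verbose: bool = True) -> dict:
    """Run the simulator at desk scale through the full pipeline and assert
    the core recovery properties; returns the measured quantities."""
    import tempfile

    from scipy.stats import pearsonr

    report: dict = {}
    tmp = Path(out_dir) if out_dir else Path(tempfile.mkdtemp(prefix="deducemeth_selftest_"))
    tmp.mkdir(parents=True, exist_ok=True)

    genome = _simulate.simulate_genome(60_000, gc_fraction=0.5, cpg_enrichment=8.0, seed=seed)
    sheet = _io.SampleSheet(
        sample_ids=tuple(f"s{i}" for i in range(1, 9)),
        group_labels=("g1",) * 4 + ("g2",) * 4,
    )
    truth = _simulate.uniform_methylation_truth(genome, ["g1", "g2"], seed=seed + 1)
    reads, _ = _simulate.simulate_rrbs_reads(
        genome, truth, sheet, depth=30, read_length=50, size_range=(30, 50), seed=seed + 2
    )
    sheet_path = tmp / "samples.tsv"
    pd.DataFrame(
        {"sample_id": sheet.sample_ids, "group_label": sheet.group_labels}
    ).to_csv(sheet_path, sep="\t", index=False)
    config = PipelineConfig(
        sample_sheet=str(sheet_path), output_dir=str(tmp / "run"), seed=seed
    )
    run_pipeline(config, reads_by_sample=reads)

    report["methylation_recovery_r"], report["n_recovery_points"] = methylation_recovery(
        tmp / "run", genome, truth, dict(zip(sheet.sample_ids, sheet.group_labels))
    )

    summary = pd.read_csv(tmp / "run" / "alignment_summary.tsv", sep="\t")
    report["mapping_efficiency"] = float(summary["aligned"].sum() / summary["reads"].sum())

    controls = _simulate.DEFAULT_SPIKE_INS
    spike_reads = _simulate.simulate_spike_ins(
        controls, conversion_rate=0.99, overconversion_rate=0.01, n_reads=200, seed=seed + 3
    )
    metrics = _align.compute_conversion_metrics(spike_reads, controls)
    report["underconversion_rate"] = metrics.underconversion_rate
    report["overconversion_rate"] = metrics.overconversion_rate
    if metrics.underconversion_rate > 0.05:
        report["conversion_warning"] = (
            f"underconversion {metrics.underconversion_rate:.3f} exceeds 5%"
        )

    ok = report["methylation_recovery_r"] >= 0.95 and report["mapping_efficiency"] >= 0.95
    report["pass"] = bool(ok)
    if verbose:
        for k, v in report.items():
            print(f"{k}: {v}")
    if not ok:
        raise AssertionError(f"selftest failed: {report}")
    return report


def methylation_recovery(
    run_dir: Path,
    genome: _simulate.SimGenome,
    truth: Mapping[tuple[str, int], float],
    group_of: Mapping[str, str],
    min_coverage: int = 0,
) -> tuple[float, int]:
    """Correlate called levels in a run directory with simulation truth.

    Each deduced fragment is located in the simulated genome by searching
    the fully converted frame (unique at desk scale), mapping every called
    site back to its genomic CpG.
    """
    from scipy.stats import pearsonr

    calls = pd.read_csv(Path(run_dir) / "methylation_calls_filtered.tsv", sep="\t")
    frag_seqs = dict(_io.read_fasta(Path(run_dir) / "deduced_fragments.fa"))
    conv_genome = _io.convert_c2t(genome.sequence)
    conv_genome_rc = _io.convert_c2t(_io.reverse_complement(genome.sequence))
    offsets: dict[str, tuple[int, str]] = {}
    for fid, seq in frag_seqs.items():
        conv = _io.convert_c2t(seq)
        pos = conv_genome.find(conv)
        if pos >= 0:
            offsets[fid] = (pos, "+")
            continue
        pos = conv_genome_rc.find(conv)
        if pos >= 0:
            offsets[fid] = (len(genome.sequence) - pos - len(seq), "-")
    called, true_vals = [], []
    for row in calls.itertuples():
        fid = str(row.fragment_id)
        if fid not in offsets:
            continue
        pos, strand = offsets[fid]
        if strand == "+":
            gpos = pos + int(row.start)
        else:
            # fragment is the reverse strand: its CpG C sits opposite the
            # forward-strand G, whose CpG C is one base before
            gpos = pos + len(frag_seqs[fid]) - 2 - int(row.start)
        key = (group_of[str(row.sample_id)], gpos)
        if key not in truth:
            continue
        if row.count_methylated + row.count_unmethylated < min_coverage:
            continue
        called.append(float(row.level))
        true_vals.append(float(truth[key]))
    if len(called) < 3:
        return float("nan"), len(called)
    return float(pearsonr(called, true_vals)[0]), len(called)
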