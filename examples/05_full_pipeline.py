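"""The whole workflow in one call, plus the built-in selftest.

Simulates a two-group dataset, writes FASTQ + sample sheet, and runs
trim -> deduce -> align -> call -> differential -> export through the
pipeline orchestrator; stage outputs and a manifest land in the run
directory. The selftest wraps the same flow and asserts the recovery
properties.
"""

import tempfile
from pathlib import Path

import pandas as pd

from deducemeth import SampleSheet, simulate_genome, simulate_rrbs_reads
from deducemeth.io_formats import write_fastq
from deducemeth.pipeline import PipelineConfig, run_pipeline, selftest
from deducemeth.simulate import uniform_methylation_truth

tmp = Path(tempfile.mkdtemp(prefix="deducemeth_example_"))
genome = simulate_genome(60_000, cpg_enrichment=8.0, seed=11)
sheet = SampleSheet(tuple(f"s{i}" for i in range(1, 9)), ("g1",) * 4 + ("g2",) * 4)
truth = uniform_methylation_truth(genome, ["g1", "g2"], seed=12)
reads, _ = simulate_rrbs_reads(genome, truth, sheet, depth=30, size_range=(30, 50), seed=13)

rows = []
for sid, grp in zip(sheet.sample_ids, sheet.group_labels):
    fq = tmp / f"{sid}.fastq"
    write_fastq(reads[sid], fq)
    rows.append({"sample_id": sid, "group_label": grp, "fastq_path": str(fq)})
pd.DataFrame(rows).to_csv(tmp / "samples.tsv", sep="\t", index=False)

run = run_pipeline(PipelineConfig(sample_sheet=str(tmp / "samples.tsv"),
                                  output_dir=str(tmp / "run"), seed=14))
for line in run.log_lines:
    print(line)
print(f"outputs in {tmp / 'run'}")

print("\n== selftest (simulate + full pipeline + recovery assertions)")
selftest(seed=0)
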