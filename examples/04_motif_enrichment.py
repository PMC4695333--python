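"""Reference-free motif enrichment with Markov-shuffle composition control.

Plants a consensus motif in half the foreground sequences and also tests a
GC-skewed comparison in which a GC-rich motif looks enriched purely through
base composition; the 60%-rule shuffle filter flags the latter as an
artifact while the planted motif survives.
"""

import numpy as np

from deducemeth import MotifMatrix, ShuffleParams, differential_motif_analysis


def consensus_motif(motif_id, consensus, strength=0.9):
    rest = (1 - strength) / 3
    rows = []
    for b in consensus:
        row = [rest] * 4
        row["ACGT".index(b)] = strength
        rows.append(row)
    return MotifMatrix(motif_id, np.array(rows))


rng = np.random.default_rng(8)


def seqs(n, probs=(0.25, 0.25, 0.25, 0.25)):
    return ["".join(rng.choice(list("ACGT"), size=50, p=list(probs))) for _ in range(n)]


library = [
    consensus_motif("planted", "ACGTCAGT"),
    consensus_motif("gc_rich", "GCCGCC", strength=0.7),
    consensus_motif("decoy", "TATAAAT"),
]

fg = [s[:20] + "ACGTCAGT" + s[28:] if i % 2 == 0 else s for i, s in enumerate(seqs(100))]
bg = seqs(100)
print("== planted-motif comparison (matched composition)")
for r in differential_motif_analysis(fg, bg, library, ShuffleParams(n_iterations=10, seed=9)):
    print(f"  {r.motif_id}: adjusted_p={r.adjusted_p:.3g}, "
          f"shuffle_hit_fraction={r.enriched_fraction:.2f} -> {r.verdict}")

print("== GC-rich fg vs AT-rich bg (no planted motif)")
fg_gc = seqs(100, probs=(0.15, 0.35, 0.35, 0.15))
bg_at = seqs(100, probs=(0.35, 0.15, 0.15, 0.35))
for r in differential_motif_analysis(fg_gc, bg_at, library, ShuffleParams(n_iterations=10, seed=10)):
    print(f"  {r.motif_id}: adjusted_p={r.adjusted_p:.3g}, "
          f"shuffle_hit_fraction={r.enriched_fraction:.2f} -> {r.verdict}")
# expected: 'planted' is differential in the first comparison; in the second,
# 'gc_rich' is significant in the primary test but demoted to a
# composition-bias artifact because the shuffled controls reproduce it.
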