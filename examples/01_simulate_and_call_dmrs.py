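"""Simulate a paired MeDIP study and call differentially methylated regions.

Builds the default synthetic scene (2 x 1 Mb genome, 6 treated/control
pairs, 100 planted DMRs at 2-fold effect), computes paired t statistics on
size-factor-normalized 1 kb window counts, calls DMRs at |t| > 7, and
estimates the genome-level FDR by within-window permutation. Because the
truth is known, recovery is reported against the planted windows.
"""

from medipdiff import call_dmrs, paired_t, permutation_fdr, simulate_study

scene = simulate_study(seed=1)
print(f"windows: {scene.grid.n_windows}, samples: {scene.counts.raw.shape[1]}")
print(f"size factors: {scene.counts.size_factors.round(3).to_dict()}")

t_frame = paired_t(scene.counts)
calls = call_dmrs(t_frame, scene.grid, threshold=7.0)
n_hyper = sum(c.direction == "hyper" for c in calls)
print(f"\nDMRs at |t| > 7: {len(calls)} ({n_hyper} hyper, {len(calls) - n_hyper} hypo)")

perm = permutation_fdr(scene.counts, calls, threshold=7.0, n_permutations=500, seed=1)
print(f"permutation FDR estimate (B=500): {perm.fdr_estimate:.4f}")

called = {c.index for c in calls}
truth = {int(i) for i in scene.truth.dmr_indices}
print(f"\nplanted windows recovered: {len(called & truth)}/{len(truth)}")
print(f"false calls: {len(called - truth)} "
      f"(realized FDP {len(called - truth) / len(called):.3f})")
print("\nAn FDR estimate near the realized false-discovery proportion, with")
print("most planted windows recovered, means the |t| > 7 rule plus the")
print("permutation null behave as designed at this depth and pairing.")
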