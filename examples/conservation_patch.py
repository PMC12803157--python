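"""Test whether a surface patch is more conserved than its surroundings.

Builds a 50-sequence alignment in which positions 14–18 (the "loop"
around a catalytic arginine at 16) never mutate while the rest mutates
at 30 % per site, scores per-column conservation as 1 − H/ln 20, and
runs a permutation test of the patch mean against the background.
"""

from denngap import conservation_scores, make_msa, patch_conservation_test, read_msa

reference = "ACDEFGHIKLMNPQRSTVWY" * 3  # 60 residues
patch = set(range(14, 19))
background = set(range(20, 60))

msa = make_msa(reference, n_sequences=50, conserved_positions=patch,
               substitution_rate=0.3, seed=3)
track = conservation_scores(read_msa(msa), "REF")

print("patch scores:", [round(float(track.score(r)), 3) for r in sorted(patch)])
print("example background scores:",
      [round(float(track.score(r)), 3) for r in sorted(background)[:5]])

result = patch_conservation_test(track, patch, background,
                                 n_permutations=10000, seed=1)
print(f"\nobserved patch mean conservation: {result.observed_mean:.3f}")
print(f"permutation p-value ({result.n_permutations} draws): {result.p_value:.2e}")
print(
    "\nA small p-value says random same-sized residue subsets of the surface"
    "\nessentially never reach the patch's mean conservation."
)
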