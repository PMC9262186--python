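"""Inverse folding: find sequences whose structure matches a dot-bracket
target, and build a structure-only pre-training dataset from it.

The internal folder is a weighted maximum-pairing model (G-C 3, A-U 2,
G-U 1); the search reports the achieved base-pair distance honestly
(0 = the fold equals the target exactly).
"""

from termscan import (
    fold_nussinov,
    gc_content,
    generate_pretraining_set,
    inverse_fold,
    pairs_to_dotbracket,
)

target = "....((((((((...))))))))......."
result = inverse_fold(target, seed=11)
print("target   :", target)
print("sequence :", result.sequence)
print("refolded :", pairs_to_dotbracket(fold_nussinov(result.sequence), len(target)))
print(f"distance {result.achieved_distance} after {result.iterations} iterations")
print()

pset = generate_pretraining_set([target], n_positive=40, seed=5)
gc = gc_content(pset.records)
print(f"pre-training set: {len(pset.records)} records "
      f"({len(pset.pretrain_idx)} pre-train / {len(pset.earlystop_idx)} early-stop)")
print(f"GC content positives: {gc[1]['mean']:.3f}  negatives: {gc[0]['mean']:.3f}")
print("\nPositives share the target's structure but not the GC-rich sequence")
print("bias of real terminators; negatives are uniform random, length-matched.")
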