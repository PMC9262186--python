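"""In-silico mutagenesis: which terminator sections and how much of the
stem pairing does a model rely on?

Uses an analytic stand-in scorer with a known closed form (the fraction of
intact stem pairs) so the example runs instantly and the expected numbers
are obvious; swap in any trained TermModel for real experiments.
"""

import numpy as np

from termscan import GeneratorParams, make_terminator, section_impact, structure_impact
from termscan.structure import PAIRING_DINUCLEOTIDES

# fixed section lengths so every record shares the same stem coordinates
params = GeneratorParams(
    a_tail_len=(8, 8), stem_len=(8, 8), loop_len=(5, 5), u_tail_len=(8, 8)
)
rng = np.random.default_rng(0)
records = [make_terminator(params, seed=rng, record_id=f"t{i}") for i in range(40)]
pairing = set(PAIRING_DINUCLEOTIDES)
pairs = records[0].stem_pairs()


def intact_stem_fraction(seqs):
    """Scores 1.0 for a fully paired stem, (8-k)/8 after k disruptions."""
    return np.array(
        [sum((s[i] + s[j]) in pairing for i, j in pairs) / len(pairs) for s in seqs]
    )


sec = section_impact(intact_stem_fraction, records, n_repeats=15, seed=1)
print("section impacts (1 - mutated/original mean output):")
for name, impact in sec.impacts.items():
    print(f"  {name:>9}: {impact:+.3f}")

struct = structure_impact(
    intact_stem_fraction, records, k_range=range(1, 9), n_repeats=15, seed=2
)
print("\nstem-pairing impacts (1 - disrupt/retain mean output):")
for k, impact in struct.impacts.items():
    print(f"  k={k}: {impact:.3f}   (closed form: {k}/8 = {k/8:.3f})")
print("\nOnly the stem sections move this scorer, and the pairing impact")
print("grows linearly with the number of disrupted pairs, as it must.")
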