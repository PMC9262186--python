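"""Generate synthetic ground-truth data: annotated terminators, a tRNA-like
cloverleaf, and a genome with implanted elements.

Every record carries its anatomy (seven sections) and dot-bracket
structure, so downstream steps (training, mutagenesis, scanning) know the
truth exactly.
"""

from termscan import (
    CLOVERLEAF,
    GeneratorParams,
    make_genome,
    make_terminator,
    make_transcripts,
    make_trna_like,
)

record = make_terminator(GeneratorParams(), seed=1)
print("terminator record:", record.id, f"({len(record)} nt)")
print(" ", record.sequence)
print(" ", record.structure)
for name, (start, end) in record.sections.items():
    print(f"  {name:>9}: [{start:2d},{end:2d})  {record.section_seq(name)}")
print()

trna = make_trna_like(CLOVERLEAF, seed=3)
print(f"tRNA-like record ({len(trna)} nt), inverse-folded to a cloverleaf:")
print(" ", trna.sequence)
print(" ", trna.structure)
print()

genome = make_genome(n_elements=5, genome_length=20_000, seed=7)
transcripts, sites = make_transcripts(genome, seed=8)
print(f"genome: {len(genome)} nt with {len(genome.implanted)} implanted elements")
for elem, tx in zip(sorted(genome.implanted, key=lambda e: e.start), transcripts):
    print(
        f"  {elem.id}: [{elem.start},{elem.end}) {elem.strand} "
        f"site={elem.site}  transcript [{tx.start},{tx.end})"
    )
print("\nThe site is the 3' end of each element; transcripts add flanking")
print("context the way real transcribed regions would.")
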