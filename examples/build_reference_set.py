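"""Build a chimera-control reference set from a (synthetic) ITS corpus.

Generates a small fungal-ITS-like corpus with known taxonomy, clusters it
into genus-level groups at 80% identity and species hypotheses (SHs) at
97-100%, and keeps one representative sequence per multi-member SH at the
98.5% level — the chimera-free reference set.
"""

from itschimera import CorpusSpec, build_reference_dataset, generate_corpus

spec = CorpusSpec(n_genera=4, species_per_genus=3, seqs_per_species=3, seed=42)
records, truth = generate_corpus(spec)
print(f"corpus: {len(records)} sequences, "
      f"{len({e.species for e in truth})} true species")

refset = build_reference_dataset(records)
print(f"reference set: {len(refset)} sequences "
      f"(one per species hypothesis at 98.5% identity)")

for rec in refset.records[:3]:
    sh_id, source = refset.provenance[rec.id]
    print(f"  {rec.id} -> {sh_id} ({source}), {len(rec.seq)} nt")

# Each reference stands for one species hypothesis; `automatic` means the
# modal sequence type was chosen, with ties broken by length then id.
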