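"""Search a synthetic family database and inspect the top hits.

Generates two families of noise-perturbed homologs plus decoys, encodes
them with the packaged alphabet and runs the full prefilter + alignment +
scoring pipeline for one query.
"""

import foldscan as fs
from foldscan.fixtures import SyntheticFamilySpec, make_family

families = make_family(SyntheticFamilySpec(n_families=2, members_per_family=3,
                                           n_decoys=3, seed=7))
matrix = fs.default_substitution_matrix()
entries = fs.make_entries(families.chains, fs.default_alphabet())

query = entries[0]
results = fs.search_database([query], entries, matrix)

print(f"query: {query.entry_id} ({len(query)} residues), "
      f"database: {len(entries)} entries")
print(f"{'target':<12}{'corr.bits':>10}{'LDDT':>8}{'TM':>8}{'struct.bits':>13}")
for rec in results[query.entry_id]:
    print(f"{rec.target_id:<12}{rec.alignment.corrected_bits:>10.1f}"
          f"{rec.lddt_mean:>8.2f}{rec.tm_avg:>8.2f}{rec.structural_bits:>13.1f}")
print()
print("The self-hit scores perfectly (LDDT = TM = 1); the other family")
print("members follow with high scores, and unrelated decoys are either")
print("suppressed by the prefilter or rank far below.")
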