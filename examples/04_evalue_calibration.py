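"""Calibrate E-values: per-query Gumbel fits and the regression network.

Aligns variable-length queries against shuffled copies of a database,
fits the extreme-value parameters per query, trains the (mu, lambda)
regression and re-estimates the reported-E correction on a scrambled
search. A held-out scrambled search then checks that the mean number of
hits with E <= x tracks x.
"""

import numpy as np

import foldscan as fs
from foldscan.fixtures import SyntheticFamilySpec, make_family

families = make_family(SyntheticFamilySpec(seed=42, n_decoys=10))
matrix = fs.default_substitution_matrix()
alphabet = fs.default_alphabet()
entries = fs.make_entries(families.chains, alphabet)

queries = fs.pipeline.calibration_query_set(alphabet, n_queries=110, seed=5)
table = fs.build_calibration_table(queries, entries, matrix, n_align=150, seed=7)
mus = [row["mu"] for row in table]
print(f"calibration table: {len(table)} queries, "
      f"mu range {min(mus):.1f} .. {max(mus):.1f} bits")

model = fs.train_evalue_net(table, seed=3, letters=matrix.letters)
model = fs.pipeline.calibrate_search_correction(model, entries, matrix,
                                                n_scrambled=30, seed=101)
print(f"reported E = {model.correction_scale:.2f} * E_raw ^ "
      f"{model.correction_exponent:.2f}")

raw = fs.pipeline.scrambled_raw_evalues(model, entries, matrix,
                                        n_scrambled=30, seed=202)
print(f"{'E threshold':>12}{'mean hits/query':>18}")
for x in (0.1, 1.0, 10.0):
    corrected = [model.correction_scale * ev ** model.correction_exponent
                 for ev in raw]
    mean_fp = np.mean([(ev <= x).sum() for ev in corrected])
    print(f"{x:>12}{mean_fp:>18.2f}")
print()
print("A calibrated E-value means: searching with an unrelated (scrambled)")
print("query, you expect about E hits at or below that E-value.")
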