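"""Score genes with I_TE and CAI, and show the GCR mutation-bias correction.

Part 1 reproduces the Ala GCR example: in E. coli highly expressed genes
GCG (2654) outnumbers GCA (1973), so CAI-style weights call GCG optimal;
dividing by a GCG-skewed background flips the preference to GCA — the codon
actually favoured by tRNA-mediated selection.

Part 2 simulates genes with a planted bias b toward family-optimal codons
and shows that I_TE recovers the planted ranking.
"""

import numpy as np
from scipy.stats import spearmanr

from ribosignal import (
    CodonUsageTable,
    codon_usage_from_cds,
    generate_biased_cds_set,
    ite_score,
    partition_codon_families,
    relative_adaptedness,
)

part = partition_codon_families(11)  # default: six-fold families split 4+2

heg = CodonUsageTable({"GCA": 1973, "GCG": 2654})
bg = CodonUsageTable({"GCA": 1000, "GCG": 3000})
w_cai = relative_adaptedness(heg, None, part).w
w_ite = relative_adaptedness(heg, bg, part).w
print("Ala GCR weights  (codon: CAI-style -> background-corrected)")
for codon in ("GCA", "GCG"):
    print(f"  {codon}: {w_cai[codon]:.4f} -> {w_ite[codon]:.4f}")
print("  corrected weights rank GCA first: selection, not mutation, favours it\n")

rng = np.random.default_rng(0)
b = rng.uniform(0, 1, 100)
seqs, truth, background = generate_biased_cds_set(100, b, seed=0, n_codons=300)
heg_seqs, _, _ = generate_biased_cds_set(30, 0.95, seed=1, n_codons=300)
wt = relative_adaptedness(codon_usage_from_cds(heg_seqs), background, part)
scores = [ite_score(s, wt).score for s in seqs]
rho = spearmanr(truth.b, scores).statistic
print(f"Spearman rho between planted bias and I_TE over 100 genes: {rho:.3f}")
print("  (close to 1: the index recovers the planted codon-bias ranking)")
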