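"""Two-sample MR on a hand-built exposure/outcome fixture.

Shows allele harmonization (swapped alleles are flipped back), the Wald
ratio for a single instrument, IVW for several, and the MR-Egger intercept
as a pleiotropy check.
"""

import numpy as np
import pandas as pd

from targetmr import harmonize, ivw, mr_egger, wald_ratio

exposure = pd.DataFrame(
    {
        "variant_id": ["rs1", "rs2", "rs3"],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "beta": [0.12, 0.20, 0.15],
        "se": [0.01, 0.015, 0.012],
        "eaf": [0.30, 0.20, 0.45],
        "gene": "GENE1",
    }
)
# the outcome GWAS reports rs2 with swapped alleles: its beta is on the
# opposite allele and must be flipped during harmonization
outcome = pd.DataFrame(
    {
        "variant_id": ["rs1", "rs2", "rs3"],
        "effect_allele": ["A", "T", "G"],
        "other_allele": ["G", "C", "A"],
        "beta": [0.06, -0.095, 0.08],
        "se": [0.02, 0.02, 0.02],
        "eaf": [0.30, 0.80, 0.45],
    }
)

pairs = harmonize(exposure, outcome)
print(pairs[["variant_id", "beta_exp", "beta_out", "action"]])

w = wald_ratio(pairs["beta_exp"][0], pairs["se_exp"][0], pairs["beta_out"][0], pairs["se_out"][0])
print(f"\nWald ratio (rs1 only): beta={w['beta']:.3f} se={w['se']:.3f} p={w['pval']:.2e}")

res = ivw(pairs["beta_exp"], pairs["se_exp"], pairs["beta_out"], pairs["se_out"])
print(f"IVW over 3 instruments: beta={res['beta']:.3f} se={res['se']:.3f} "
      f"p={res['pval']:.2e} Q={res['q_stat']:.2f} (Q p={res['q_pval']:.2f})")

egger = mr_egger(pairs["beta_exp"], pairs["se_exp"], pairs["beta_out"], pairs["se_out"])
print(f"MR-Egger: slope={egger['beta']:.3f}, intercept={egger['egger_intercept']:.4f} "
      f"(p={egger['egger_intercept_pval']:.2f})")
# An IVW beta of ~0.5 says one unit of exposure raises the outcome by half a
# unit; a near-zero Egger intercept means no evidence of directional
# pleiotropy; a small Q p-value would flag heterogeneous instruments.
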