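"""Earthmover's distance between missense and synonymous site distributions.

A gene whose missense variation avoids part of the CDS (a candidate MDR)
shows a larger transport cost between its missense and synonymous positional
distributions than a gene where both classes are spread uniformly.
"""

import numpy as np

from mdrscan import gene_emd, make_transcript
from mdrscan.synthetic import simulate_population_variants

rng = np.random.default_rng(11)

tx = make_transcript(1500, rng, transcript_id="DEMO3")
null_variants = simulate_population_variants(tx, 0.2, 0.2, rng)
planted_variants = simulate_population_variants(
    tx, 0.2, 0.2, rng, planted_interval=(1200, 1500), epsilon=0.0
)

emd_null = gene_emd(tx, null_variants)
emd_planted = gene_emd(tx, planted_variants)
print(f"uniform missense (no MDR):          EMD = {emd_null:.4f}")
print(f"missense erased on the 3' 300 bp:   EMD = {emd_planted:.4f}")
print(
    "\nThe depleted gene scores higher: its missense mass must be moved "
    "further to match\nthe synonymous distribution, which is the signature "
    "used to rank MDR candidates."
)
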