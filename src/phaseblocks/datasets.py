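"""Small built-in datasets, generated programmatically.

The centrepiece is the classic 10-heterozygous-SNP worked example used to
illustrate how block determination interacts with switch errors: the truth
puts every alternate allele on one copy, while the estimate swaps copies at
loci 5 and 7 (1-based), i.e. it carries exactly two switch errors.  On this
toy, switch error is 2/10 = 20%, a 3-SNP sliding window (step 1) gives
IHBP = 4/8 = 50%, a 5-SNP window gives 6/6 = 100%, and the correctly phased
runs have lengths {4, 2, 4} so LCPR = 10/3.
"""
from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .model import HaplotypePanel, VariantMap
from .trio import TruthPhase, truth_from_haplotypes


def toy_switch_example() -> Tuple[Dict[str, TruthPhase], HaplotypePanel]:
    """The 10-het-SNP toy: (truth, estimated panel) for one individual.

    The estimate's copy-1 alleles agree with the truth's paternal copy at
    loci 1-4 and 8-10 and with the maternal copy at loci 5-6 (1-based), so
    the agreement chain flips at loci 5 and 7: two switch errors.
    """
    m = 10
    variants = VariantMap.default(m)
    truth_alleles = np.zeros((1, m, 2), dtype=np.int8)
    truth_alleles[0, :, 1] = 1  # paternal all-ref, maternal all-alt: all sites het
    truth_panel = HaplotypePanel(["toy"], variants, truth_alleles)
    truths = truth_from_haplotypes(truth_panel)

    est = np.zeros((1, m, 2), dtype=np.int8)
    est[0, :, 1] = 1
    swapped = [4, 5]  # 0-based: loci 5 and 6 carry the maternal allele on copy 1
    est[0, swapped, 0] = 1
    est[0, swapped, 1] = 0
    estimate = HaplotypePanel(["toy"], variants, est)
    return truths, estimate
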