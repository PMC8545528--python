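#!/usr/bin/env python
"""Differential expression and ceRNA coexpression, checked against truth.

Welch t-test on log2 values with the fold-change 1.5 gate (p < 0.05) per
gene, Pearson coexpression for hub-lncRNA ceRNA pairs, then a comparison
of the significant calls with the planted DE genes.
"""

import json
import os

import pandas as pd

import _common

cfg = _common.config()
block = _common.ensure(cfg, "expression")["expression"]
_common.show("expression", block)

de = pd.read_csv(os.path.join(cfg.outdir, "expression",
                              "differential_expression.tsv"),
                 sep="\t", index_col=0)
truth = json.load(open(os.path.join(cfg.outdir, "inputs",
                                    "ground_truth.json")))
planted = set(truth["planted_de_genes"])
called = set(de[de["significant"]].index)
sens = len(called & planted) / len(planted)
fdp = len(called - planted) / len(called) if called else 0.0
print(f"planted DE genes: {len(planted)}; called: {len(called)}; "
      f"sensitivity {sens:.3f}; false-discovery proportion {fdp:.3f}")
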