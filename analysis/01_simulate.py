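#!/usr/bin/env python
"""Generate the synthetic study inputs at study scale.

Emulates the real study's data shapes: a ~9,000-protein scale-free PPI
backbone, 1,349/371/269 diabetes/retinopathy/shared disease genes, 1,848
lncRNAs with Poisson ceRNA edges, a 25-case/5-control expression matrix
with 10% planted DE genes (|log2FC| = 1.5), and 500 SNPs with planted
allele-dependent binding sites.  Everything downstream reads these files.
"""

import _common

cfg = _common.config()
block = _common.ensure(cfg, "simulate")["simulate"]
_common.show("simulate", block)
print(f"inputs written under {cfg.outdir}/inputs/")
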