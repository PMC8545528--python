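#!/usr/bin/env python
"""Over-representation analysis of the detected modules.

Each top module's coding genes are tested against the bundled gene-set
collection by the hypergeometric test with BH correction, using the
collection genes present in the network as the universe.
"""

import _common

cfg = _common.config()
block = _common.ensure(cfg, "enrichment")["enrichment"]
_common.show("enrichment", block)
print(f"per-module enrichment tables under {cfg.outdir}/enrichment/")
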