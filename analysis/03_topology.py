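#!/usr/bin/env python
"""Topological characterisation of the integrated network.

Computes per-node degree, betweenness centrality and topological
coefficient; fits log-log power laws to each node class's degree
distribution; compares the metrics across node types (Mann-Whitney);
selects the top-50 degree hubs; and profiles which disease classes the
hub lncRNAs' ceRNA partners belong to.
"""

import _common

cfg = _common.config()
block = _common.ensure(cfg, "topology")["topology"]
_common.show("topology", block)
print(f"per-node metrics and comparison tables under {cfg.outdir}/topology/")
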