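#!/usr/bin/env python
"""SNP overlay: LD filtering, binding-site gain/loss, ceRNA disturbance.

Filters SNPs to leads plus LD proxies (r^2 > 0.8), rescans transcript
windows under both alleles for miRNA seed sites and TF motifs, propagates
gains/losses to ceRNA-edge created/disrupted statuses, and summarises the
lncRNA-SNP association map.  Calls are then compared with the planted
site-event truth.
"""

import json
import os

import pandas as pd

import _common

cfg = _common.config()
block = _common.ensure(cfg, "variants")["variants"]
_common.show("variants", block)

events = pd.read_csv(os.path.join(cfg.outdir, "variants",
                                  "site_events.tsv"), sep="\t")
truth = json.load(open(os.path.join(cfg.outdir, "inputs",
                                    "ground_truth.json")))
planted = {(e["snp_id"], e["element_id"], e["effect"])
           for e in truth["planted_site_events"]}
# events are restricted to SNPs surviving the LD filter, so compare on them
called = {(r.snp_id, r.element_id, r.effect) for r in events.itertuples()}
missed = {p for p in planted if p[0] in set(events["snp_id"])} - called
print(f"planted events: {len(planted)}; called after LD filter: "
      f"{len(called)}; spurious: {len(called - planted)}; "
      f"missed (among LD-kept SNPs): {len(missed)}")
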