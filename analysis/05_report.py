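#!/usr/bin/env python
"""Aggregate all stage outputs into one report.

Collects the scan, GEA and IBD/IBE results plus provenance (config hash,
seed) into results/run/report.json and prints the headline numbers.
"""

import json

from coastgen.pipeline import RunConfig, run

cfg = RunConfig(outdir="results/run", seed=1)
rep = run("report", cfg)
print("report hash:", rep["report_hash"])
if "scan" in rep and "recovery" in rep["scan"]:
    print("sweep recovery:", json.dumps(rep["scan"]["recovery"]))
if "gea" in rep:
    print("candidate SNPs:", rep["gea"]["n_candidates"])
print("full report: results/run/report.json")
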