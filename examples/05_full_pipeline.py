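"""One-command pipeline run with a provenance manifest.

Simulates two cohorts, counts, tests, calls and annotates DMRs,
computes overlaps and classification, and records every output file
with a checksum. Re-running with the same seed reproduces every DMR
table byte for byte.
"""

import json

from medipdmr import RunConfig, run_pipeline

cfg = RunConfig(
    seed=5, out_dir="scratch/example_run",
    cohorts=["mother", "father"], shared_fraction=0.3, n_genes=25,
    simulate={"n_chroms": 1, "chrom_length": 1_000_000,
              "n_case": 10, "n_control": 10, "n_planted": 8},
    log_level="INFO")

manifest = run_pipeline(cfg)

print("\nstages and their outputs:")
for stage, entry in manifest["stages"].items():
    print(f"  {stage}: {', '.join(sorted(entry['files']))}")

with open("scratch/example_run/classification.json") as fh:
    print("\nper-cohort LDA leave-one-out accuracy:",
          json.load(fh)["loo_accuracy"])
print("\nThe manifest's checksums make a rerun with the same seed "
      "verifiably identical.")
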