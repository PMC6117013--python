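"""Generate a linked synthetic cohort and look at its composition.

Writes perinatal.csv, hospital.csv, dispensing.csv and truth.csv (the
evaluation-only ground-truth labels) to scratch/synthetic/ and prints
the scenario mix.  Each scenario is a dispensing pattern built to land
on a known side of the reclassification criteria.
"""

import sys

from scp_reclass import GeneratorConfig, generate

out_dir = sys.argv[1] if len(sys.argv) > 1 else "scratch/synthetic"

config = GeneratorConfig(n_women=5000, seed=42)
cohort = generate(config)
paths = cohort.write(out_dir)

print(f"pregnancies: {len(cohort.perinatal)}")
print(f"hospital separations: {len(cohort.hospital)}")
print(f"dispensing claims: {len(cohort.dispensing)}")
print("\nscenario mix (truth labels, never read by the pipeline):")
print(cohort.truth["scenario"].value_counts().to_string())
print(f"\nfiles written to {out_dir}/")
# 'unexposed' women have no cessation-pharmacotherapy claims; the four
# exposed scenarios target the timing / duration / adherence criteria.
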