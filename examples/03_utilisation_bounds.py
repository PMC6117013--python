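"""Lower- and upper-bound utilisation prevalence per therapy era.

The lower bound counts therapy users among recorded smokers only; the
upper bound adds the women the cascade reclassified (who are, by
construction, therapy users), so it can only move the prevalence up.
Each therapy is measured over the conception dates for which it was
subsidised.
"""

from scp_reclass import GeneratorConfig, classify_cohort, generate, relative_increase
from scp_reclass.pipeline import utilisation_table

cohort = generate(GeneratorConfig(n_women=10_000, seed=7))
classified = classify_cohort(cohort.perinatal, cohort.hospital, cohort.dispensing)

estimates = utilisation_table(classified)
print(f"{'therapy':<12} {'era from':<11} {'bound':<6} {'users/smokers':<14} prevalence")
for e in estimates:
    print(
        f"{e.therapy:<12} {e.era_start.isoformat():<11} {e.bound:<6} "
        f"{e.numerator}/{e.denominator:<12} {e.prevalence:.1f}%"
    )

print("\nrelative increase lower -> upper:")
for therapy in ("nrt", "bupropion", "varenicline", "any"):
    pair = {e.bound: e.prevalence for e in estimates if e.therapy == therapy}
    print(f"  {therapy:<12} {relative_increase(pair['lower'], pair['upper'])}%")
# The true prevalence lies between the bounds: the upper bound may
# overshoot because smokers without any claims never enter its denominator.
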