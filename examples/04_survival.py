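"""Kaplan-Meier curves by grade and the log-rank test on a phantom cohort.

Phantom survival is exponential with a longer LGG scale, so the two curves
separate and the log-rank test should reject equality on a modest cohort.
"""

from gliofusion import PhantomSpec, generate_cohort, km_estimate, logrank
from gliofusion.survival import impute_missing_os, records_from_manifest

_, manifest = generate_cohort(PhantomSpec(n_lgg=30, n_hgg=30, seed=5))
records = records_from_manifest(manifest)
for group in ("LGG", "HGG"):
    records = impute_missing_os(records, group)  # no-op here: nothing missing

for group in ("LGG", "HGG"):
    km = km_estimate([r for r in records if r.group == group])
    half = next((t for t, s in zip(km.event_times, km.survival_probs) if s <= 0.5),
                float("nan"))
    print(f"{group}: {len(km.event_times)} event times, median OS ~ {half:.1f} months")

result = logrank([r for r in records if r.group == "LGG"],
                 [r for r in records if r.group == "HGG"])
print(f"log-rank chi2 = {result.chi_square:.2f}, p = {result.p_value:.2e}")
# p << 0.05: the survival difference between grades is not sampling noise.
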