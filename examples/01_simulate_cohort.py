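"""Simulate a lesion cohort with the published feature prevalences.

Draws 311 HCC and 162 non-HCC lesions, then compares the empirical
prevalence of a few ancillary features against the generator's targets.
"""

from liradsaf import sample_cohort, published_prevalence_spec

spec = published_prevalence_spec()
cohort = sample_cohort(spec, seed=1)
df = cohort.data
print(f"cohort: {len(df)} lesions "
      f"({(df.group == 'HCC').sum()} HCC / {(df.group == 'nonHCC').sum()} non-HCC)")

print(f"{'feature':<22}{'target HCC':>11}{'drawn HCC':>11}"
      f"{'target non':>11}{'drawn non':>11}")
for name in ("mild_moderate_T2", "restricted_diffusion", "marked_T2",
             "hbp_isointensity"):
    p_hcc, p_non = spec.prevalence[name]
    e_hcc = df[df.group == "HCC"][name].mean()
    e_non = df[df.group == "nonHCC"][name].mean()
    print(f"{name:<22}{p_hcc:>11.3f}{e_hcc:>11.3f}{p_non:>11.3f}{e_non:>11.3f}")

# Each "drawn" column is a binomial realization of its "target" column: at
# n = 311/162 the two should agree to within a few percentage points, and the
# HCC-vs-non-HCC gaps (e.g. marked T2: ~1% vs ~22%) are what the screening
# stage later rediscovers.
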