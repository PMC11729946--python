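"""Generate a synthetic linked administrative dataset and look at its shape.

Draws 10,000 persons from the default national segment mixture, attaches
chronic-disease, program and encounter records, and prints the latent
segment shares.  Because strict mode is on, these latent labels are exactly
recoverable by the classifier (see example 02).
"""

import healthscopes as hs

cfg = hs.SyntheticConfig(n_persons=10_000, seed=7)
pop = hs.generate_population(cfg)
hs.generate_followup(pop, cfg)

print(f"persons:    {len(pop.persons):>6}")
print(f"conditions: {len(pop.conditions):>6}")
print(f"programs:   {len(pop.programs):>6}")
print(f"encounters: {len(pop.encounters):>6}")
print(f"followup:   {len(pop.followup):>6}  (index-year survivors only)")

shares = pop.latent["latent_segment"].value_counts(normalize=True)
print("\nlatent segment shares (top 5):")
for seg, share in shares.head(5).items():
    print(f"  [{seg}] {share:6.1%}   target {hs.DEFAULT_MIXTURE[seg]:6.1%}")
# The largest segment is the mostly-healthy [A] tier at ~64%, matching the
# configured national mixture; rare high-need tiers are ~1% or less.
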