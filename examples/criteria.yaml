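# Classification-criteria config (defaults shown).
# Pass to `healthscopes segment --config criteria.yaml` or
# `CriteriaConfig.from_yaml(...)`.

# Risk factors that qualify a person as "at risk" (any one suffices).
risk_factor_set:
  - chas_blue        # high-subsidy financial-assistance tier
  - rental_housing   # public rental housing
  - obesity_history  # historical obesity diagnosis (BMI >= 27.5)
  - lives_alone

# First-match rule order, highest healthcare need first.
precedence: [L, K, I, J, H, G, D, F, E, C, B, A]

# Child <= 18, senior >= 65.
age_band_cutoffs: [18, 65]

# Operationalize "final year of life" with lookahead to next-year deaths
# (requires a dies_next_year feature column) instead of in-year death.
eol_lookahead: false
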