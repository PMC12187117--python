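"""Base-case cost-utility analysis: AI-guided management vs standard care.

Both arms run the same decision tree + Markov model; the AI arm adds the
analysis price once at entry and shifts statin management according to the
observed per-stratum change shares.
"""
from ccta_cea import (
    default_model_config,
    default_parameters,
    evaluate_strategies,
    expected_event_table,
)

config = default_model_config()   # 700 GBP per analysis, 3.5%/yr discounting
params = default_parameters()

ai, sc, ce = evaluate_strategies(config, params)
print(f"AI-guided arm:      cost {ce.cost_ai:8.0f} GBP   QALYs {ce.qaly_ai:.2f}")
print(f"standard care arm:  cost {ce.cost_sc:8.0f} GBP   QALYs {ce.qaly_sc:.2f}")
print(f"increment:          cost {ce.delta_cost:8.0f} GBP   QALYs {ce.delta_qaly:.3f}")
print(f"ICER: {ce.icer:,.0f} GBP per QALY gained ({ce.status})")
print()
print(f"expected events per {config.n_simulated_patients} patients over 30 years:")
print(expected_event_table(ai, sc, config.n_simulated_patients)
      .round(1).to_string(index=False))
print()
print("An ICER well below the 20,000-30,000 GBP/QALY approval band means "
      "the AI analysis buys health at a price the NHS normally accepts.")
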