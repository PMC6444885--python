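"""Compute the composite hallucination severity score (HSS).

The HSS is the sum of the z-scored misperception percentage (bistable
percept task) and the z-scored questionnaire total; it turns two noisy
instruments into one continuous severity axis.
"""

import hallnet as hn

manifest, *_ = hn.generate_cohort(hn.SimulationConfig(seed=1))
sev = hn.compute_hss(manifest)
print(sev.head(5).to_string(index=False))
print(f"\nHSS mean {sev['hss'].mean():+.3f} (0 by construction), "
      f"range [{sev['hss'].min():.2f}, {sev['hss'].max():.2f}]")

demo = hn.correlate_demographics(sev, manifest)
print("\nHSS vs demographics (method picked by a normality screen):")
print(demo.to_string(index=False))
print("Small |r| with large p means severity is unrelated to that variable.")
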