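"""Undisturbed vs disturbed flow (reduced-size demonstration).

Compares matched flight batches at low (0.05) and high (0.3) turbulence
intensity: the EER-vs-distance curves separate close to the source, where
extra dispersion fragments the plume, and the disturbed batch explores more
on average.
"""

from mothnav.experiments import turbulence_comparison

rep = turbulence_comparison(n_per_condition=10, seed=0)
lo, hi = rep["intensities"]
print(f"success rate: intensity {lo} -> {rep['success_rate'][lo]:.2f}, "
      f"intensity {hi} -> {rep['success_rate'][hi]:.2f}")
print(f"mean EER:     intensity {lo} -> {rep['mean_eer'][lo]:.3f}, "
      f"intensity {hi} -> {rep['mean_eer'][hi]:.3f}")
print(f"near-source (< 0.6 m) mean EER: {rep['near_source_mean_eer']}")
print(f"far-field  (>= 0.6 m) mean EER: {rep['far_field_mean_eer']}")
print("\nAt full scale the curves coincide beyond ~0.6 m from the source and "
      "separate below it, with the disturbed batch exploring more.")
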