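"""One call that runs everything and writes a reproducible artifact set.

Simulation -> exposures -> both scoring schemes -> misreporting ->
confounder screen -> conditional/unconditional models -> report, with a
manifest of SHA-256 hashes so a rerun with the same seed is verifiably
identical.
"""

import safbdg as sb

config = sb.PipelineConfig(
    out_dir="scratch/pipeline_demo",
    simulation=sb.SimulationConfig(n_pairs=396),
    seed=3,
)
bundle = sb.run_pipeline(config)

print("Artifacts written:")
for name in sorted(bundle["paths"]):
    print(f"  {name}")
q33, q66 = bundle["boundaries"]
print(f"\nControl tertile boundaries: low <= {q33:.2f}, high > {q66:.2f}")
models = bundle["models"]
row = models[(models["model"] == "adjusted")
             & (models["stratum"] == "overall")
             & (models["term"] == "high_vs_low")].iloc[0]
print(f"Adjusted overall OR (high vs low adherence): {row['or']:.2f} "
      f"(95 % CI {row['ci_low']:.2f}, {row['ci_high']:.2f}), "
      f"p = {row['p']:.4f}")
print("\nThe manifest in scratch/pipeline_demo/manifest.json hashes every "
      "artifact; rerunning with the same seed reproduces them byte for "
      "byte.")
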