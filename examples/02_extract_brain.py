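"""Full automated brain extraction on the synthetic head, scored vs truth.

Runs the complete pipeline — intensity estimation, automatic circle
initialization on the middle slice, outward slice sweep with contour
propagation, leakage monitoring — and reports the five overlap indices
against the phantom's ground-truth brain mask.
"""

from braingac import PhantomSpec, evaluate, generate_phantom, run_extraction

vol, truth = generate_phantom(PhantomSpec(seed=1))
mask, traces, log = run_extraction(vol)

report = evaluate(mask, truth)
print("slice log excerpt:")
for line in log[2:4]:
    print("  " + line)
iters = [t.iterations_run for t in traces.values() if t.iterations_run]
print(f"segmented {len(iters)} slices, "
      f"{sum(iters) / len(iters):.1f} iterations per slice on average")
for name, value in report.as_dict().items():
    print(f"  {name:12s} {value:.4f}")
# Dice ~0.99 means near-voxel-perfect agreement with the known brain; a
# sensitivity below 1 reflects the deliberately unsegmented outermost slices.
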