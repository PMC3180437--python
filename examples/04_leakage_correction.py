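"""Weak-boundary leakage and its local-threshold correction.

Builds a phantom with narrow sectors where CSF is missing and muscle-like
tissue at near-brain intensity bridges brain to scalp, then compares three
pipelines: corrected (leakage detection + local thresholds), uncorrected
(single threshold), and the classic edge-potential contour baseline.
"""

from braingac import (
    ExtractionConfig,
    evaluate,
    generate_phantom,
    weak_boundary_spec,
)
from braingac.pipeline import run_extraction

vol, truth = generate_phantom(weak_boundary_spec(seed=1))
configs = {
    "corrected": ExtractionConfig(correct_leakage=True),
    "uncorrected": ExtractionConfig(correct_leakage=False),
    "classic": ExtractionConfig(model="edge", correct_leakage=False,
                                restrict_to_head=False),
}
for name, cfg in configs.items():
    mask, traces, _ = run_extraction(vol, cfg)
    rep = evaluate(mask, truth)
    fired = sum(t.leakage_flag for t in traces.values())
    print(f"{name:12s} dice={rep.dice:.4f} fp_rate={rep.fp_rate:.4f} "
          f"(leakage detected on {fired} slices)")
# the uncorrected region contour escapes through the bridges into the bright
# scalp; the high-curvature detector stops those slices and re-segments them
# with a higher threshold in the leak-prone lower-lateral parts; the classic
# edge-based contour leaks far more.
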