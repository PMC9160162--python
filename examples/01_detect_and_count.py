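"""Generate a synthetic bacteriocyte scene and count its endosymbionts.

Builds a 512-px DAPI-like scene with 40 toroidal objects, runs the full
tile -> detect -> stitch -> filter -> dedup pipeline with the classical
baseline detector, and compares the recovered count with the truth.
"""

from endoquant import BaselineDetector, PipelineConfig, SceneSpec, generate_scene, run_pipeline

annotated, record = generate_scene(SceneSpec(n_objects=40, noise_sd=0.0, seed=7))
result = run_pipeline(
    annotated.image,
    BaselineDetector(),
    PipelineConfig(seed=7),
    identifier=annotated.identifier,
    pixel_per_micron=annotated.pixel_per_micron,
)

print(f"ground-truth objects : {len(annotated.ground_truth)}")
print(f"pipeline detections  : {len(result.detections)}")
print(f"mean detection score : {sum(d.score for d in result.detections)/len(result.detections):.3f}")
# On a noiseless, non-overlapping scene the count matches the truth exactly;
# scores near 1 mean strong ring-likeness of each detected object.
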