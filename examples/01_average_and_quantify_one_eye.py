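"""Simulate one eye, run the imaging chain, and compare with ground truth.

Builds a 3 × 3 mm choriocapillaris scene with a 13 % flow-void fraction,
renders nine speckled OCTA acquisitions with fixation jitter, registers
them on the superficial-plexus reference frames, averages, binarizes with
the Phansalkar rule, and measures the flow voids.
"""

from ccflow import analyze_eye
from ccflow.synthetic import AcquisitionParams, generate_scene, render_octa_stack

scene = generate_scene(pixel_count=300, pixel_pitch_um=10.0,
                       target_void_fraction=0.13, mean_void_size_um2=790.0,
                       pachyvessel_fraction=0.0, seed=1)
stack = render_octa_stack(scene, AcquisitionParams(n_frames=9, seed=2))

result = analyze_eye([p.cc for p in stack.frames], [p.scp for p in stack.frames])

truth_area = scene.void_fraction * 9.0
print(f"true void area:      {truth_area:.3f} mm^2 (fraction {scene.void_fraction:.3f})")
print(f"measured void area:  {result.flow_voids.total_area_mm2:.3f} mm^2 "
      f"({result.flow_voids.n_voids} voids, mean {result.flow_voids.mean_size_um2:.0f} um^2)")
print(f"frames averaged:     {result.n_frames_used} of {len(stack.frames)}")
print(f"registration quality: {min(result.registration_qualities):.2f}"
      f"-{max(result.registration_qualities):.2f} (normalized correlation)")
# The measured area should sit within a few percent of truth: averaging has
# suppressed speckle ~9-fold and the local threshold tracks the meshwork.
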