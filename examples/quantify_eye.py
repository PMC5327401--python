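"""Segment a synthetic eye image and quantify its pigment proportions.

Renders an eye whose iris is 20% non-pigmented, 30% pheomelanin and 50%
eumelanin, locates the iris annulus with the Canny/Hough detector, classifies
every iris pixel with the quadratic-kernel SVM, and prints the recovered
areal proportions next to the ground truth, plus the legacy quantifiers
computed on the same pixels.
"""

from irisquant import quantify_eye, segment_iris
from irisquant.quantification import default_classifier
from irisquant.synthetic import SyntheticEyeSpec, render_synthetic_eye

spec = SyntheticEyeSpec(proportions=(0.2, 0.3, 0.5), seed=42, sample_id="demo")
image, truth = render_synthetic_eye(spec)

seg = segment_iris(image)
print(f"limbus: r={seg.limbus.radius:.1f} px at ({seg.limbus.center_row:.1f}, "
      f"{seg.limbus.center_col:.1f});  true r={truth.limbus.radius:.1f}")
print(f"pupil:  r={seg.pupil.radius:.1f} px;  true r={truth.pupil.radius:.1f}")

q = quantify_eye(image, default_classifier())
print("\nproportions (non-pigmented, pheomelanin, eumelanin):")
print(f"  recovered: {q.p_non:.3f}  {q.p_pheo:.3f}  {q.p_eu:.3f}")
print(f"  truth:     {truth.proportions[0]:.3f}  {truth.proportions[1]:.3f}  "
      f"{truth.proportions[2]:.3f}")
print(f"  closure:   sum = {q.p_non + q.p_pheo + q.p_eu:.12f}")

print("\nlegacy quantifiers on the same iris pixels:")
print(f"  mean hue {q.mean_h:.3f}  mean saturation {q.mean_s:.3f}")
print(f"  melanin index (1 - luminance) {q.lum_l:.3f}  colour score (chroma) {q.colour_c:.1f}")
print(f"  L* {q.l_star:.1f}  a* {q.a_star:.1f}  b* {q.b_star:.1f}")
print(f"  PIE score {q.pie:.3f}  T-index {q.t_index:.3f}")
# The three proportions sum to one by construction; PIE, T-index and the
# melanin index all rise with the eumelanin share of the iris.
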