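"""Decompose a bicondylar facet into its radial and ulnar condyles.

The fifth carpometacarpal joint surface is best described by two
overlapping spheres.  This builds such a surface at the published mean
condylar radii, then recovers both radii, the area split, and the angle of
divergence with the alternating two-sphere fit.
"""
import numpy as np

from facetmorph import (
    AnatomicalFrame, BicondylarSpec, generate_bicondylar, partition_bicondylar,
)

spec = BicondylarSpec(radial_radius=7.92, ulnar_radius=11.63,
                      divergence=21.4, ulnar_area_target=30.21,
                      noise_sd=0.1, resolution=0.3, sense="concave", seed=3)
mesh, truth = generate_bicondylar(spec)
frame = AnatomicalFrame(mesh.area_weighted_centroid(),
                        np.array([1.0, 0, 0]),   # sagittal
                        np.array([0, 1.0, 0]),   # coronal (+y = ulnar)
                        np.array([0, 0, 1.0]))   # normal
res = partition_bicondylar(mesh, frame)

print(f"radial condyle ROC : {res.radial_fit.radius:6.2f} mm  (generated 7.92)")
print(f"ulnar  condyle ROC : {res.ulnar_fit.radius:6.2f} mm  (generated 11.63)")
print(f"ulnar area fraction: {res.ulnar_area_fraction:6.2f} %   "
      f"(generated {truth.extras['ulnar_area_fraction']:.2f})")
print(f"angle of divergence: {res.divergence_angle:6.2f} deg (generated "
      f"{truth.extras['divergence']:.2f})")
print(f"converged in {res.n_iterations} alternating-fit iterations; "
      f"label agreement with ground truth "
      f"{100 * np.mean(res.assignment == truth.condyle_labels):.1f} %")
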