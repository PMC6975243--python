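"""Angle between two neighbouring facets at the mid-coronal plane.

Builds two planar facet patches hinged at a known dihedral (33.94 deg, the
published mean angle between the fourth and fifth carpometacarpal joint
surfaces on the hamate) and recovers it from mid-coronal cross-sections.
"""
import numpy as np

from facetmorph import AnatomicalFrame, generate_interfacet_pair, interfacet_angle

frame = AnatomicalFrame(np.zeros(3), np.array([1.0, 0, 0]),
                        np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))
for built in (0.0, 33.94, 90.0):
    facet4, facet5 = generate_interfacet_pair(built, noise_sd=0.05, seed=4)
    got = interfacet_angle(facet4, facet5, frame)
    print(f"constructed {built:6.2f} deg -> measured {got:6.2f} deg")
# each facet is cut by the shared mid-coronal plane; a total-least-squares
# line through each section gives the two directions whose angle is reported
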