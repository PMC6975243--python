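#!/bin/sh
# Simulated study end to end from the shell:
#   1. simulate a 10-specimen cohort (meshes + manifest + ground truth)
#   2. measure every facet
#   3. render the mean (range) summary table
set -e
facetmorph simulate --cohort 10 --seed 7 --out cohort --resolution 0.35
facetmorph measure --input cohort --out measured
facetmorph report --measurements measured/measurements.json --out measured
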