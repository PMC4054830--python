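"""Encode one peptide window into the 346-D feature vector.

Shows the fixed segment schema (220 profile + 60 grey + 55 physicochemical
+ 11 disorder components) and a few representative values.
"""

import numpy as np

from methylsite import encode_peptide, schema_segments, sigmoid_normalize
from methylsite.physchem import PropensityDisorderProvider, disorder_features
from methylsite.profiles import fallback_profile

protein = "MSGRGKGGKGLGKGGAKRHRKVLRDNIQGIT"  # histone-like N-terminus
center = 18  # an Arg in a Gly/Lys-rich context
window = protein[center - 6 : center + 5]

profile = sigmoid_normalize(fallback_profile(window))
track = PropensityDisorderProvider().track(protein)
disorder = disorder_features(track, center - 5, xi=5)
vec = encode_peptide(window, profile, disorder)

schema = schema_segments()
print(f"window around position {center}: {window}")
print(f"feature vector length: {vec.values.shape[0]}")
print(f"segments (1-based, half-open): {schema.segments}")
for name in schema.segments:
    part = vec.values[schema.slice_for(name)]
    print(f"  {name:8s} n={part.size:3d}  mean={part.mean():+.3f}  "
          f"first={part[0]:+.3f}")
print()
print("The profile segment holds sigmoid-squashed substitution scores in")
print("(0,1); grey components are GM(1,1) trend coefficients per profile")
print("column; the physicochemical segment holds five Atchley factors per")
print("residue; the final 11 values are per-residue disorder scores.")
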