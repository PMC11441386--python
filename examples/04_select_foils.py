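"""Select shape-similar foil answers from a concept embedding.

Builds a small synthetic concept embedding (stand-in for a real
49-dimensional similarity embedding), projects it onto the 13
shape-related dimensions and picks the three nearest Euclidean
neighbours of a query concept as foils for a four-alternative
identification task.
"""

import numpy as np
import pandas as pd

import mooneygen as mg

rng = np.random.default_rng(0)
concepts = ["ball", "orange", "globe", "ladder", "rope", "pencil",
            "book", "plate", "coin", "tower"]
# synthetic embedding: 13 shape dimensions + 3 non-shape dimensions
columns = list(mg.SHAPE_DIMENSIONS) + ["colorful", "edible", "man-made"]
table = pd.DataFrame(rng.random((len(concepts), len(columns))),
                     index=concepts, columns=columns)
# make the round things loaded on the 'spherical' dimension
table.loc[["ball", "orange", "globe", "coin", "plate"], "spherical"] += 2.0

shape_space = mg.project_shape(table)
print(f"embedding: {table.shape[1]} dimensions -> "
      f"{shape_space.shape[1]} shape-related dimensions\n")

for query in ("ball", "ladder"):
    foils = mg.select_foils(query, shape_space, k=3)
    print(f"foils for {query!r}: {', '.join(foils)}")

print()
print("Foils are the concepts closest to the query in the shape subspace,")
print("so the wrong answers of the identification task share the target's")
print("coarse shape (here: the round concepts cluster together), which")
print("makes the task genuinely hard for two-tone images.")
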