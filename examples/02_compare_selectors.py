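"""Compare the four global threshold selectors on one scene.

Runs mean, Otsu, max-edge and edge-similarity selection on the same
smoothed 8-bit image and prints each selected threshold together with
the optimum of its objective, then the pairwise dissimilarity between
the resulting two-tone images.
"""

import itertools

import mooneygen as mg

template = mg.make_fixture(mg.FixtureSpec("nested_rects", shape=(64, 64)))
gray8 = mg.preprocess(template, mg.SmoothingConfig(sigma=2.0))

mooneys = {}
print(f"{'technique':<16} {'threshold':>9}   objective at optimum")
for technique in mg.TECHNIQUES:
    result = mg.select_threshold(gray8, technique)
    mooneys[technique] = mg.apply_threshold(gray8, result.value)
    curve = result.objective_curve
    opt = "-" if curve is None else f"{curve[int(result.value)]:.3f}"
    print(f"{technique:<16} {result.value:>9.1f}   {opt}")

print()
print("Pairwise dissimilarity ratio (fraction of pixels that disagree):")
for a, b in itertools.combinations(mg.TECHNIQUES, 2):
    d = mg.dissimilarity_ratio(mooneys[a], mooneys[b])
    print(f"  {a} vs {b}: {d:.3f}")
print()
print("Selectors that pick thresholds in different intensity gaps of the")
print("nested-rectangle scene produce visibly different two-tone images;")
print("a ratio of 0 means the two selectors cut the same population split.")
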