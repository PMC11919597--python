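"""Encode an RNA window as a chaos-game (FCGR) grayscale matrix.

Each base pulls the trajectory halfway toward its corner of the unit
square; binning the trajectory on a 2^k x 2^k grid counts k-mer suffixes.
"""

import numpy as np

import capm7g as c

# a 501-nt window centered on a G, with a few GGG runs planted
rng = np.random.default_rng(0)
seq = list(rng.choice(list("AUCG"), 501))
seq[250] = "G"
for start in (120, 240, 300):
    seq[start : start + 3] = "GGG"
seq[340:348] = "GGGGGGGG"  # one longer G-run to light up the corner cell
window = c.RnaWindow(id="demo", sequence="".join(seq), label=1, center_index=250)

image = c.encode_window(window, grid_size=64)
print(f"matrix shape: {image.counts.shape}")
print(f"total counts: {image.counts.sum()} (= window length, every point binned)")
print(f"grayscale range: [{image.normalized.min():.2f}, {image.normalized.max():.2f}]")

# the cell of any 6-mer can be located arithmetically; G-rich 6-mers sit
# toward the bottom-right corner (the G vertex)
row, col = c.kmer_cell("GGGGGG", 64)
print(f"cell of GGGGGG: row {row}, col {col} (bottom-right corner)")
print(f"counts there: {image.counts[row, col]}")
# Meaning: the FCGR is a k-mer-frequency image; planted G-runs brighten
# the G-corner cells that the classifier later attends to.
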