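"""Published reference statistics for DAPI-stained M. truncatula root nuclei.

These are the printed summary numbers from the original confocal study of
nuclear size in uninoculated vs. mycorrhizal roots (the raw stacks were never
deposited, so only these summaries are available). They serve as *inputs* for
analytic cross-checks — Sturges class structure, the treatment volume ratio —
not as outputs of this package.

Units: areas μm², volumes μm³. "ctr" = uninoculated, "myc" = mycorrhizal.
"""

MANUAL_AREA = {
    "ctr": {"mean": 32.7, "sem": 0.33, "range": (15.0, 62.0), "n": 1020},
    "myc": {"mean": 35.9, "sem": 0.48, "range": (15.0, 142.0), "n": 1150},
}

# 3D voxel volumetry on the same stacks
OC3D_VOLUME = {
    "ctr": {"mean": 40.3, "sem": 0.68, "range": (15.0, 118.0), "n": 594},
    "myc": {"mean": 50.7, "sem": 1.13, "range": (20.0, 220.0), "n": 893},
}

# Adopted volume classing (width chosen in the original analysis; the
# bare Sturges formula on the printed ranges gives ~10–18.5 μm³ instead —
# both are exposed, see ploidy.sturges_width).
CLASS_WIDTH = 25.0  # μm³
CLASS_ANCHOR = 20.0  # μm³

# Printed per-class mean volumes (μm³), classes I..IV (ctr) and I..VIII (myc)
CLASS_MEANS = {
    "ctr": (30.3, 54.6, 77.6, 107.0),
    "myc": (29.6, 55.2, 81.0, 105.9, 131.8, 155.3, 181.0, 210.2),
}

# Bootstrap moment statistics of volume distributions (mean ± sd over
# 1000 iterations of size 500)
BOOTSTRAP_SKEWNESS = {"ctr": (1.14, 0.22), "myc": (1.47, 0.15)}
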