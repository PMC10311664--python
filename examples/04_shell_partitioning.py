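"""Split a particle into equal-volume core/bulk/surface shells.

The minimum-volume enclosing ellipsoid (Khachiyan's algorithm on the convex
hull) defines a dimensionless coordinate u that is 0 at the centre and 1 on
the surface. Scaling the ellipsoid by (1/3)^(1/3) and (2/3)^(1/3) cuts the
body into three shells of exactly equal volume; the per-class mass table
shows where each component lives.
"""

from aeromorph.composition import build_composition
from aeromorph.ellipsoid import (
    assign_regions,
    fit_bounding_ellipsoid,
    region_mass_fractions,
)
from aeromorph.generate import generate_particle

comp, counts = build_composition("B", diameter=200.0)
frame = generate_particle(comp, counts, seed=1)

ellipsoid = fit_bounding_ellipsoid(frame)
a, b, c = ellipsoid.semi_axes
print(f"bounding ellipsoid semi-axes: {a:.1f} x {b:.1f} x {c:.1f} Å")

labels = assign_regions(frame, ellipsoid)
partition = region_mass_fractions(frame, labels)
print("\nmass percentage per region (rows sum to 100):")
print(partition.table.to_string(float_format=lambda v: f"{v:6.1f}"))
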