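"""Track particle shape with gyration-tensor descriptors.

The mass-weighted gyration tensor's eigenvalues give the asphericity phi
(0 for a sphere, large for elongated bodies, units of Å²) and the relative
shape anisotropy kappa² (0 isotropic, 1 collinear). Here a generated particle
is progressively stretched along x, and phi rises while kappa² stays small.
"""

import numpy as np

from aeromorph.composition import build_composition
from aeromorph.frames import Trajectory
from aeromorph.generate import generate_particle
from aeromorph.shape import shape_series, shape_table

comp, counts = build_composition("A", diameter=200.0)
frame = generate_particle(comp, counts, seed=0)

frames = []
for k, stretch in enumerate(np.linspace(1.0, 1.8, 5)):
    coords = frame.coordinates * np.array([stretch, 1.0, 1.0])
    frames.append(frame.with_coordinates(coords, time=0.1 * k))

series = shape_series(Trajectory(frames=frames, dt=0.1))
print(shape_table(series).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
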