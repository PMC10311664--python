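"""Quantify the organic film: coverage, surface excess, raft curvature.

Surface rafts are clusters that sit near the bounding ellipsoid (u above
(2/3)^(1/3)) with outward-aligned lipids. Dividing the ellipsoid area by the
area per lipid (21 Å²) gives the available sites; coverage and surface excess
compare the raft population against that capacity, and the analytic mean
curvature of the ellipsoid is averaged over each raft's footprint.
"""

from aeromorph.clustering import cluster_lipids, identify_surface_rafts, lipid_features
from aeromorph.ellipsoid import fit_bounding_ellipsoid
from aeromorph.generate import generate_raft_fixture
from aeromorph.surface import build_surface_report

fixture = generate_raft_fixture(
    n_patches=2, lipids_per_patch=40, n_core_aggregate=25, seed=19, n_water=1500
)
features = lipid_features(fixture.frame)
assignment = cluster_lipids(features, eps=12.0, min_samples=5)
ellipsoid = fit_bounding_ellipsoid(fixture.frame)
rafts = identify_surface_rafts(assignment, features, ellipsoid)

report = build_surface_report(rafts, features, ellipsoid, assignment.labels)
print(f"surface area      {report.A_surface:,.0f} Å²  "
      f"({report.n_sites:,.0f} sites at {report.a_lipid} Å²/lipid)")
print(f"surface rafts     {len(report.raft_sizes)} "
      f"({report.n_surface_fa}/{report.n_total_fa} lipids at the surface)")
print(f"coverage          {report.coverage_percent:.2f} %")
print(f"surface excess    predicted {report.excess_predicted:.3f}  "
      f"measured {report.excess_measured:.3f}")
print(f"mean curvature    {report.weighted_mean_curvature:.5f} Å⁻¹ "
      f"(~1/{1 / report.weighted_mean_curvature:.0f} Å sphere)")
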