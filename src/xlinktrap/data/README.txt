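Synthetic trapping-profile source-data tables
=============================================

These CSVs are SYNTHETIC reconstructions, not measured data.  The original
per-patch source-data supplements of the trapping figures are not
redistributed here; instead, each table places the per-linker mean active
fractions exactly on the published parabola summary of the corresponding
condition, with realistic SEM/n columns:

  v666c_desensitized: minimum (11 A, 0.10); curvature anchored at the
      reported ~70% peak-current inhibition by the 18-A linker
      (K1 = 0.2/49 per A^2).
  v666c_active:       minimum (13 A, 0.30); curvature anchored at the
      reported 0.65 final active fraction for the 7-A linker
      (K1 = 0.35/36 per A^2).
  v666c_stg:          minimum (11 A, 0.30); curvature identical to the
      desensitized profile, as reported for that comparison.

They exercise the SEM-weighted parabola fit (layout: linker, span_angstrom,
mean, sem, n) and round-trip the published fit minima; they cannot stand in
for the raw per-patch measurements.
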