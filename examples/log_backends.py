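"""Profile the natural-log approximations against the reference log.

Builds the 16-segment piecewise-Chebyshev table over [1e-32, 1], reports
its per-segment maximum error (identical across segments because each
segment is an exact 100x rescaling of the same fitting problem), and
profiles the de Soras fast log over its usable range.
"""

import plfkit as pk

table = pk.build_segment_table()
print(f"segment table: {table.n_segments} segments x {table.n_coeffs} "
      f"coefficients over [{table.boundaries[0]:g}, {table.boundaries[-1]:g}]")
print(f"x = 1e-3 resolves to segment {pk.select_segment(1e-3, table)}")

prof = pk.segment_error_profile(table)
print("\nper-segment max |chebyshev - ln| (nats):")
print(prof.to_string(index=False,
                     formatters={"x_lo": "{:.0e}".format,
                                 "x_hi": "{:.0e}".format,
                                 "max_abs_error": "{:.5f}".format,
                                 "mean_abs_error": "{:.5f}".format}))

df = pk.error_profile("desoras", 1e-9, 1.0, 100_000)
print(f"\nde Soras fast log over [1e-9, 1]: max abs error "
      f"{df.attrs['max_abs_error']:.5f} nats (inputs below 1e-10 return 0, "
      "which is what destabilizes tree searches)")
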