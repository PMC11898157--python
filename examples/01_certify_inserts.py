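"""Certify the calibration-phantom insert densities from mass and volume.

Each polymer insert is weighed once and its volume measured by two
independent methods (laser scan and CT scan); density = mass / volume.  The
mean of the two per-method densities is the certified value used on the
calibration line.
"""

import phantomcal as pc

table = pc.default_insert_table()
print(table.round(2))
print()
print("Certified (mean) densities in g/cc — these are the y-values of the")
print("intensity-to-density calibration line:")
for mat, rho in table["density_mean_gcc"].items():
    print(f"  {mat:8s} {rho:.2f}")
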