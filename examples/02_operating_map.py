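"""Map pump flow rates to wall shear, shear gradient and wall stress.

The stenosed-channel network turns an applied flow rate into a wall shear
rate (parallel-plate estimate per channel) and, through the fitted linear
mapping (slope 3.49 mm^-1), into the post-stenosis shear-rate gradient that
triggers clotting.  The printed table is the device's operating map over
its working flow range; the last line shows the stenosis severity the
shear change corresponds to.
"""
from thromboflow import operating_table, stenosis_severity

table = operating_table([5.0, 25.0, 75.0, 150.0, 300.0])
print(table.to_string(index=False, float_format=lambda v: f"{v:,.1f}"))

sev = stenosis_severity(275.0, 125.0)
print(f"\nequivalent arteriolar stenosis (275 -> 125 um): {sev:.1f}% (~55%)")
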