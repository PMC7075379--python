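"""Dose-response basics: EQD2 correction, voxel response, TCP and NTCP.

Builds a small heterogeneous DVH by hand, applies the fractionation
correction, and scores it with the Poisson TCP model and the
relative-seriality NTCP model using bundled prostate parameters.
"""

import numpy as np

import radbioqa as rb
from radbioqa import param_db

table = param_db.load_site("prostate")
ptv_params = table.lookup("PTV7920")       # D50=63 Gy, gamma=5, a/b=3
rectum_params = table.lookup("Rectum")     # D50=80 Gy, gamma=2.2, s=0.7

schedule = rb.FractionSchedule(26)         # 70.2 Gy in 26 fractions: 2.7 Gy/fx
print("EQD2 of 70.2 Gy at 2.7 Gy/fx (a/b=3):",
      round(rb.eqd2(70.2, schedule, 3.0), 2), "Gy")
print("Voxel response at D50 (always 50%):",
      rb.voxel_response(ptv_params.d50, ptv_params))

# target DVH: most volume at prescription, a small cold spot
ptv = rb.DVH("PTV", "differential",
             bin_doses=np.array([66.0, 69.5, 70.2]),
             volumes=np.array([0.05, 0.35, 0.60]))
# rectum DVH: typical cumulative curve, converted before scoring
rectum = rb.cumulative_to_differential(
    rb.DVH("Rectum", "cumulative",
           bin_doses=np.array([0.0, 20.0, 40.0, 60.0, 70.0]),
           volumes=np.array([1.0, 0.55, 0.25, 0.08, 0.01]))
)

tcp = rb.tcp(ptv, schedule, ptv_params)
ntcp = rb.ntcp(rectum, schedule, rectum_params)
print(f"TCP(PTV)      = {tcp:.4f}   probability the target is controlled")
print(f"NTCP(rectum)  = {ntcp:.4f}   probability of the rectal endpoint")
print(f"P+            = {rb.p_plus(tcp, ntcp):.4f}   control without complication")
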