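"""Most likely path of a single proton through 20 cm of water.

Simulates one multiple-Coulomb-scattered track, then reconstructs its
interior trajectory from the entry/exit states alone and compares the
estimate (with its 3-sigma envelope) against the true simulated path.
"""

import numpy as np

from pctpath import Beam, mlp_for_tracks, simulate_tracks, water_phantom

phantom = water_phantom(20.0)
tracks = simulate_tracks(phantom, Beam(200.0, 1), seed=12345)
res = mlp_for_tracks(tracks, phantom, 200.0, method="mlpx")

print("200 MeV proton, 20 cm water; path reconstructed from endpoints only\n")
print(f"{'depth [cm]':>10s} {'true t [mm]':>12s} {'MLP t [mm]':>11s} "
      f"{'3*sigma [mm]':>13s}")
for k in range(0, tracks.query_u.size, 5):
    u = tracks.query_u[k]
    print(f"{u:10.1f} {10*tracks.true_t[0,k]:12.3f} {10*res.t[0,k]:11.3f} "
          f"{30*res.sigma_t[0,k]:13.3f}")

err = 10 * np.abs(tracks.true_t[0] - res.t[0])
print(f"\nmax |error| along this track: {err.max():.3f} mm "
      f"(exit energy {tracks.E_out[0]:.1f} MeV)")
print("The envelope is widest mid-phantom and pinches to zero at the faces,")
print("where the path is pinned by the tracker measurements.")
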