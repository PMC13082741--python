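"""Per-band spectral discrimination of white-blood-cell classes.

Runs the 15-versus-15 granulocyte/lymphocyte study: per-cell mean spectra of
S0, DOP and DOLP over ground-truth ROIs, then a two-sided Welch t-test at
each of the 29 bands. DOP/DOLP separate the classes far better than raw
intensity when the contrast is in depolarization.
"""

import numpy as np

from stokescope import find_spectral_extrema, normalize_spectrum
from stokescope.experiments import two_class_study

res = two_class_study(seed=1)
print("per-band Welch t-test, 15 granulocyte-like vs 15 lymphocyte-like cells")
print(f"{'parameter':10s} {'median p':>12s} {'bands with p<0.05':>20s}")
for param in ("S0", "DOP", "DOLP"):
    frac = res.fraction_significant(param)
    n = res.pvalues[param].p_values.size
    print(f"{param:10s} {res.median_p(param):12.3g} {frac * n:10.0f} / {n}")
# DOP and DOLP reach p << 0.05 at every band; S0 discriminates at fewer
# bands because absorption contrast is weaker than depolarization contrast.

# spectral shape of one granulocyte's S0 signature, max-normalized
s0_spec = normalize_spectrum(res.spectra["S0"]["granulocyte"][0], "max")
extrema = find_spectral_extrema(s0_spec)
print("\nS0 spectrum extrema of one granulocyte (max-normalized):")
for wl, val, kind in extrema:
    print(f"  {kind:6s} at {wl:.0f} nm (value {val:.3f})")
trough = [wl for wl, _, k in extrema if k == "trough"]
if trough:
    print(f"stain transmission minimum near {trough[0]:.0f} nm, "
          "as expected for a Romanowsky-stained smear")
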