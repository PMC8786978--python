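#!/usr/bin/env python
"""Calibrate the collagen fibril Young's modulus.

The network's bulk modulus is exactly linear in the fibril modulus (the
relaxed configuration minimizes E * f(x) and is therefore independent of
E), so a single sweep at a reference modulus fixes the scale.  The
resulting value ships as the EcmParams.youngs default.

Usage:  python scripts/calibrate_ecm.py [--target 2558] [--seeds 12]
"""

import argparse

import numpy as np

from invadosim import ecm
from invadosim.params import EcmParams


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--target", type=float, default=2558.0,
                    help="target bulk modulus, Pa")
    ap.add_argument("--seeds", type=int, default=32)
    ap.add_argument("--e-ref", type=float, default=100.0,
                    help="reference fibril modulus, pN/nm^2")
    ap.add_argument("--box", type=float, default=15000.0,
                    help="cubic test box edge, nm")
    args = ap.parse_args()

    ks = []
    for seed in range(1, args.seeds + 1):
        p = EcmParams(youngs=args.e_ref)
        net = ecm.generate_network((args.box,) * 3, p.pore_size,
                                   p.fiber_diameter, seed, p)
        r = ecm.bulk_modulus_stretch_test(net)
        ks.append(r["bulk_modulus_pa"])
        print(f"seed {seed:2d}: K = {ks[-1]:7.1f} Pa "
              f"(pore {net.pore_size:.0f} nm)")
    mean = float(np.mean(ks))
    e_cal = args.e_ref * args.target / mean
    print(f"\nmean K(E={args.e_ref}) = {mean:.1f} Pa "
          f"(cv {np.std(ks) / mean:.1%})")
    print(f"calibrated fibril modulus: {e_cal:.1f} pN/nm^2 "
          f"({e_cal * 1e6 / 1e6:.1f} MPa)")


if __name__ == "__main__":
    main()
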