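"""Microtubule-bundle morphometrics on synthetic hexagonal bundles.

Measures edge-to-edge spacings (log-normal summary), inter-MT angle modes,
and the helical pitch profile of a twisted bundle recovered by PIV between
serial sections.
"""

import argparse
from pathlib import Path

import numpy as np


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    from axonmech.bundle import (
        edge_distances,
        lognormal_summary,
        pitch_profile,
        piv_displacement,
        triplet_angles,
        twist_from_field,
    )
    from axonmech.io import save_table
    from axonmech.synthetic import gen_bundle_stack, render_section_image

    # wild-type-like bundle: ~35 nm lattice (10 nm edge gaps), mild jitter
    secs, truth = gen_bundle_stack(37, 35.0, 2.0, 0.0, n_sections=1, seed=args.seed)
    d = edge_distances(secs[0])
    gm, var = lognormal_summary(d)
    ang = triplet_angles(secs[0])
    hist, edges = np.histogram(ang, bins=np.arange(0, 181, 10))
    modes = edges[:-1][np.argsort(hist)[-3:]] + 5
    print(f"Edge-to-edge spacing: geometric mean {gm:.1f} nm, variance {var:.1f} nm^2")
    print(f"Dominant inter-MT angle bins near: {sorted(modes.tolist())} deg (hexagonal order)")

    # twisted bundle: recover the imposed rotation per section pair via PIV
    twist = 4.0
    secs_t, truth_t = gen_bundle_stack(37, 35.0, 3.0, twist, n_sections=3, seed=args.seed)
    c = tuple(truth_t["centroid_nm"])
    rows = []
    for k in range(2):
        A = render_section_image(secs_t[k], px_size_nm=2.0, image_px=256, center_nm=c)
        B = render_section_image(secs_t[k + 1], px_size_nm=2.0, image_px=256, center_nm=c)
        vf = piv_displacement(A, B)
        est = twist_from_field(vf, (127.5, 127.5))
        r, th = pitch_profile(vf, (127.5, 127.5), z_nm=100.0, px_size_nm=2.0, n_bins=5)
        print(f"pair {k}->{k + 1}: recovered rotation {est:.2f} deg (imposed {twist})")
        for ri, ti in zip(r, th):
            rows.append({"pair": k, "r_nm": ri, "theta_deg": ti, "twist_est_deg": est})
    save_table(args.out / "bundle_morphometrics.csv", rows)
    print(f"Wrote {args.out / 'bundle_morphometrics.csv'}")


if __name__ == "__main__":
    main()
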