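"""Spectrin-lattice periodicity from synthetic STED-like line profiles.

Recovers wild-type (~197 nm) and mutant (~188 nm) periods from noisy,
PSF-blurred profiles and confirms the null result on structureless input.
"""

import argparse
from pathlib import Path


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    from axonmech.io import save_table
    from axonmech.periodicity import estimate_period
    from axonmech.synthetic import gen_periodic_profile

    rows = []
    cases = [("wild-type", 197.0), ("beta-spectrin mutant", 188.0), ("actin-depolymerized", 0)]
    for label, period in cases:
        x, y, tru = gen_periodic_profile(
            period, psf_fwhm_nm=80.0, noise_sd=0.1, seed=args.seed
        )
        est = estimate_period(y, tru["sample_nm"])
        rows.append(
            {
                "condition": label,
                "true_period_nm": period or None,
                "est_period_nm": est.period_nm,
                "significance": est.significance,
            }
        )
        if est.is_significant:
            print(f"{label:22s}: period {est.period_nm:6.1f} nm (significance {est.significance:.0f})")
        else:
            print(f"{label:22s}: no significant period (as expected)" if not period else
                  f"{label:22s}: MISSED period {period}")
    save_table(args.out / "spectrin_period.csv", rows)
    print(f"Wrote {args.out / 'spectrin_period.csv'}")


if __name__ == "__main__":
    main()
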