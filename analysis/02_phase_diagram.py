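"""Coil/no-coil phase diagram over tension and bending stiffness.

Sweeps a 5x5 grid in the constant-tension boundary mode and compares the
simulated coil boundary with the analytic criterion k_crit = C^2 tau^2/(4B).
"""

import argparse
from pathlib import Path


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-grid", type=int, default=5)
    args = ap.parse_args()

    from axonmech.pipeline import run_experiment

    man = run_experiment(
        "phase_diagrams", args.out, seed=args.seed, overrides={"n_grid": args.n_grid}
    )
    if not man.success:
        raise SystemExit(f"sweep failed: {man.failure}")
    print(
        f"{man.results['n_coil_cells']} of {args.n_grid**2} grid cells coiled; "
        f"{man.results['n_failed']} failed."
    )
    print(f"Grid table: {man.outputs['phase_csv']}")


if __name__ == "__main__":
    main()
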