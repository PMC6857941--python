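#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes one docking campaign (100 substrate poses, 30% planted inside the
3.8 A orientation cutoff, plus the coenzyme pose and receptor stub) and two
20-variant capacity panels drawn from the sigmoid model at sigma=50,
gamma=8, mu=0.4, beta=2.5 — one noise-free, one with Gaussian noise at 5%
of the wild-type capacity — in the CSV/PDBQT dialects the pipeline reads.
"""

from pathlib import Path

from ugtcap import io as uio
from ugtcap.model import ModelParams
from ugtcap.simulate import (
    PanelSpec,
    PoseFixtureSpec,
    generate_pose_fixture,
    generate_variant_panel,
)

SEED = 17
RESULTS = Path(__file__).resolve().parents[1] / "results" / "synthetic"
TRUTH = ModelParams(sigma=50.0, gamma=8.0, mu=0.4, epsilon=0.0, beta=2.5)
WILD_CAPACITY = TRUTH.sigma * 0.5**TRUTH.beta  # sigmoid at its midpoint


def main() -> None:
    pose_spec = PoseFixtureSpec(n_poses=100, frac_oriented=0.3, seed=SEED)
    paths, labels, _, _ = generate_pose_fixture(
        pose_spec, out_dir=RESULTS / "poses"
    )
    print(
        f"docking campaign: {len(labels)} poses, "
        f"{int(labels['oriented'].sum())} planted oriented -> "
        f"{paths['substrate_poses']}"
    )

    for tag, noise_sd in (("panel_noise_free", 0.0),
                          ("panel_noisy", 0.05 * WILD_CAPACITY)):
        spec = PanelSpec(
            n_variants=20, true_params=TRUTH, noise_sd=noise_sd, seed=SEED
        )
        panel, truth_table = generate_variant_panel(spec)
        out = RESULTS / tag
        out.mkdir(parents=True, exist_ok=True)
        uio.write_summaries(
            out / "summaries.csv", [s for s, _ in panel.members], seed=SEED,
            noise_sd=noise_sd,
        )
        uio.write_capacities(
            out / "capacities.csv", [r for _, r in panel.members], seed=SEED,
            noise_sd=noise_sd,
        )
        uio.write_csv(out / "truth.csv", truth_table, seed=SEED)
        print(
            f"{tag}: {len(panel.members)} variants "
            f"(noise sd {noise_sd:.3g} capacity units) -> {out}"
        )


if __name__ == "__main__":
    main()
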