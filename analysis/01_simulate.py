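#!/usr/bin/env python
"""Generate the synthetic asynchronous SPB population.

Emulates an asynchronous cell population imaged by SIM: a mix of
unduplicated, side-by-side, short-spindle, medium-spindle and elongated
scenes, with 12% top-view orientations, a 10-fold old:new outer-plaque
asymmetry of the query label and an inner:outer ratio of 2.5.  Stacks and
ground-truth sidecars go to scratch/sim (bulky, regenerable); the
population summary table goes to results/.
"""

from pathlib import Path

import pandas as pd

from spbquant import image_io, synth
from spbquant.config import AsymmetryConfig, GeometryConfig, RunConfig, \
    save_config

ROOT = Path(__file__).resolve().parents[1]
SEED = 7
N = 40

config = RunConfig(
    seed=SEED, n=N,
    stage_mix={"unduplicated": 0.15, "side_by_side": 0.2,
               "short_spindle_lt1": 0.3, "spindle_1_2p5": 0.25,
               "elongated": 0.1},
    asymmetry=AsymmetryConfig(old_new_fold=10.0, ip_op_ratio=2.5),
    geometry=GeometryConfig(top_view_fraction=0.12),
)


def main() -> None:
    out = ROOT / "scratch" / "sim"
    out.mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    save_config(config, results / "01_config.yaml")

    scenes = synth.sample_population(
        config.stage_mix, config.n, seed=config.seed,
        asymmetry=config.asymmetry, geometry=config.geometry,
        optics=config.optics, noise=config.noise, channels=config.channels)

    rows, seed_groups = [], []
    for stack, truth in scenes:
        image_io.write_stack(stack, out / f"{truth.source_id}.tif")
        truth.save_json(out / f"{truth.source_id}.truth.json")
        pts = [stack.to_stack_coords(truth.old_position)]
        if truth.new_position is not None:
            pts.append(stack.to_stack_coords(truth.new_position))
        seed_groups.append(image_io.SeedGroup(truth.source_id, "p0", pts))
        rows.append({"source_id": truth.source_id,
                     "stage": truth.stage_label,
                     "inter_distance_nm": truth.inter_distance,
                     "top_view": truth.top_view})
    image_io.write_seeds(seed_groups, out / "seeds.csv")

    df = pd.DataFrame(rows)
    image_io.write_result_table(df, results / "01_population.csv")
    print(f"wrote {len(df)} scenes to {out}")
    print("stage counts:")
    print(df.stage.value_counts().to_string())
    print(f"top views: {int(df.top_view.sum())} "
          f"({df.top_view.mean():.0%} of scenes)")


if __name__ == "__main__":
    main()
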