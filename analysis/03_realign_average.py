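#!/usr/bin/env python
"""Realign retained SPB pairs, build per-stage averages and linescans.

Each retained pair is rotated so the inter-SPB axis runs along +x with the
old (brighter) SPB on the left; realigned stacks are averaged per stage,
4x4 upscaled display versions and spindle-axis linescans are written.
Bulky images go to scratch/, the tidy profile table to results/.
"""

from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from spbquant import image_io, linescan, realign, spotfit
from spbquant.average import average_class, to_8bit, upscale_display

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sim = ROOT / "scratch" / "sim"
    out = ROOT / "scratch" / "aligned"
    out.mkdir(parents=True, exist_ok=True)
    fits = image_io.read_result_table(ROOT / "results" / "02_fits.csv")
    stacks = {s.source_id: s for s in
              (image_io.read_stack(p) for p in sorted(sim.glob("*.tif")))}

    by_stage = defaultdict(list)
    profile_rows = []
    for (src, pid), sub in fits.groupby(["source_id", "pair_id"]):
        if sub.excluded.any() or len(sub) != 2:
            continue
        spots = {}
        for r in sub.itertuples():
            spots[r.spb] = spotfit.SpotFit(
                center=np.array([r.x_nm, r.y_nm, r.z_nm]),
                sigma_xy=r.sigma_xy, sigma_z=r.sigma_z,
                amplitude=r.amplitude, background=r.background,
                rss=r.rss, converged=bool(r.converged))
        img = realign.realign_stack(stacks[src], spots["old"], spots["new"])
        by_stage[sub.stage.iloc[0]].append(img)

        proj = img.projection
        c = img.center_out
        half = img.inter_distance / 2.0 + 400.0
        prof = linescan.profile(proj, np.array([c[0] - half, c[1]]),
                                np.array([c[0] + half, c[1]]),
                                3, img.voxel_xy, channels=img.channels)
        prof = linescan.normalize_profile(prof, "internal")
        for ci, name in enumerate(prof.channels):
            for pos, val in zip(prof.positions, prof.values[ci]):
                profile_rows.append({"source_id": src, "channel": name,
                                     "stage": sub.stage.iloc[0],
                                     "position_nm": pos, "value": val})

    for stage, imgs in sorted(by_stage.items()):
        shapes = defaultdict(list)
        for im in imgs:
            shapes[im.pixels.shape].append(im)
        group = max(shapes.values(), key=len)
        avg = average_class(group, class_key=(stage,))
        stack = image_io.ImageStack(pixels=avg.mean_image,
                                    channels=avg.channels,
                                    voxel_xy=avg.voxel_xy,
                                    voxel_z=avg.voxel_z,
                                    source_id=f"avg_{stage}_n{avg.n}")
        image_io.write_stack(stack, out / f"avg_{stage}.tif")
        disp = to_8bit(upscale_display(
            realign.max_project(avg.mean_image), factor=4))
        image_io.write_stack(
            image_io.ImageStack(pixels=disp[:, None], channels=avg.channels,
                                voxel_xy=avg.voxel_xy / 4,
                                voxel_z=avg.voxel_z,
                                source_id=f"avg_{stage}_display"),
            out / f"avg_{stage}_display.tif")
        print(f"{stage}: averaged {avg.n} realigned pairs")

    df = pd.DataFrame(profile_rows)
    image_io.write_result_table(df, ROOT / "results" / "03_profiles.csv")
    print(f"wrote {df.source_id.nunique()} spindle linescans "
          f"({len(df)} samples) to results/03_profiles.csv")


if __name__ == "__main__":
    main()
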