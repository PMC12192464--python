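#!/usr/bin/env python
"""Between-task contrasts at the region level.

For the first two tasks of the session: (1) classifies every directed
region link by comparing its per-window weight distributions with the
Wasserstein distance and median thresholds; (2) contrasts per-region
in/out-degree with one-sided Mann-Whitney U tests and the median-threshold
highlight rule (alpha 0.001, medians 0.5 / 0.8).  Writes link classes and
degree contrasts as CSV.
"""

import argparse
from pathlib import Path

import pandas as pd

from fcdyn.dynamics import WindowedFC
from fcdyn.io import read_windowed_fc
from fcdyn.netprofiles import RegionAtlasMap, region_windowed_fc
from fcdyn.taskcompare import (classify_links, contrasts_to_frame,
                               highlight_regions, links_to_frame)


def task_subset(wfc: WindowedFC, task: str) -> WindowedFC:
    keep = [i for i, lab in enumerate(wfc.task_labels) if lab == task]
    return WindowedFC([wfc.windows[i] for i in keep], wfc.matrices[keep],
                      [wfc.task_labels[i] for i in keep], wfc.channel_labels)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--wfc", type=Path, default=Path("results/wfc.npz"))
    ap.add_argument("--atlas", type=Path, default=Path("results/atlas.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    wfc = read_windowed_fc(args.wfc)
    atlas = RegionAtlasMap.from_tsv(args.atlas)
    rwfc = region_windowed_fc(wfc, atlas)
    tasks = [t for t in dict.fromkeys(rwfc.task_labels) if t != "mixed"]
    ta, tb = tasks[:2]
    wa, wb = task_subset(rwfc, ta), task_subset(rwfc, tb)

    links = classify_links(wa, wb)
    links_to_frame(links).to_csv(args.out / "link_classes.csv", index=False)
    counts = pd.Series([l.cls for l in links]).value_counts()
    print(f"link classes ({ta} = A vs {tb} = B):")
    for cls, c in counts.items():
        print(f"  {cls:15s} {c}")

    frames = []
    for metric in ("in_degree", "out_degree"):
        contrasts = highlight_regions(wa, wb, metric=metric)
        frames.append(contrasts_to_frame(contrasts))
        hl = pd.Series([c.highlight for c in contrasts]).value_counts()
        print(f"{metric} highlights: " +
              ", ".join(f"{k}={v}" for k, v in hl.items()))
    pd.concat(frames).to_csv(args.out / "degree_contrasts.csv", index=False)
    print(f"wrote {args.out / 'link_classes.csv'}, "
          f"{args.out / 'degree_contrasts.csv'}")


if __name__ == "__main__":
    main()
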