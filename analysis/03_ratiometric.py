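"""Re-measure the rendered neuromast stack: max-project, estimate the
background from the cell-free 30x30 um square, compute per-cell
background-subtracted red:green ratios, normalize to the neuromast
median, and check closure against the generator's true ratios.

Reads scratch/sim/{stack.ome.tif,labels.tif}; writes
results/cells_measured.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hcmito.io import read_channel_stack, read_label_map, write_cell_table
from hcmito.ratiometric import measure_stack, normalize_to_neuromast_median

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    scratch = ROOT / "scratch" / "sim"
    stack = read_channel_stack(scratch / "stack.ome.tif",
                               ("red", "green", "nuclear"))
    side = int(round(30.0 / stack.pixel_size_xy))
    origin = (stack.shape[1] - side - 2, stack.shape[2] - side - 2)
    regions = read_label_map(scratch / "labels.tif", origin,
                             stack.pixel_size_xy)
    cells = measure_stack(stack, regions)
    cells["neuromast_id"] = "nm1"
    cells["fish_id"] = "fish01"
    cells["normalized_ratio"] = normalize_to_neuromast_median(cells)
    write_cell_table(cells, ROOT / "results" / "cells_measured.csv")

    truth = pd.read_csv(ROOT / "results" / "sim" / "stack_truth.csv")
    merged = cells.merge(truth, on="cell_id")
    rel = np.abs(merged.ratio / merged.true_ratio - 1.0)
    hoechst_ok = (merged.hoechst_x == merged.hoechst_y).mean()
    print(f"measured {len(cells)} cells; max relative ratio error vs truth "
          f"{rel.max():.2e}; Hoechst label-retention calls correct for "
          f"{hoechst_ok:.0%} of cells")
    print("the per-neuromast median of normalized ratios is "
          f"{np.median(cells.normalized_ratio):.3f} (1 by construction)")


if __name__ == "__main__":
    main()
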