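"""Generate the synthetic study data: stimulus-response traces, a
neomycin-exposure cell cohort, and one rendered neuromast stack.

Tables go to results/sim/; the (large, binary) image stack and raw trace
table go to scratch/sim/ where the later drivers pick them up.
"""

from pathlib import Path

from hcmito.config import SimulationConfig
from hcmito.io import (simulation_manifest, write_cell_table, write_json,
                       write_label_map, write_ome_stack, write_trace_table)
from hcmito.synth import (generate_cell_cohort, generate_neuromast_stack,
                          generate_traces)
from hcmito import __version__

RESULTS = Path(__file__).resolve().parent.parent / "results" / "sim"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "sim"


def main(seed: int = 0) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed)

    traces, trace_truth = generate_traces(cfg)
    write_trace_table(traces, SCRATCH / "traces.csv")
    trace_truth.drop_duplicates("channel").to_csv(
        RESULTS / "trace_truth_by_channel.csv", index=False)

    cohort, truth = generate_cell_cohort(cfg)
    write_cell_table(cohort.rename(columns={"true_ratio": "ratio"}),
                     RESULTS / "cohort.csv")

    stack, regions, stack_truth = generate_neuromast_stack(cfg, cohort)
    write_ome_stack(stack, SCRATCH / "stack.ome.tif")
    write_label_map(regions, SCRATCH / "labels.tif")
    stack_truth.placements.to_csv(RESULTS / "stack_truth.csv", index=False)

    manifest = simulation_manifest(cfg, __version__)
    manifest.record_stage("simulate", len(cohort), len(cohort))
    write_json(manifest.as_dict(), RESULTS / "manifest.json")

    print(f"simulated {len(traces)} traces across "
          f"{len(cfg.trace_params)} channels, {len(cohort)} cells "
          f"({cohort.outcome.eq('die').sum()} dying), and rendered "
          f"{len(stack_truth.placements)} cells into {stack.shape} voxels")


if __name__ == "__main__":
    main()
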