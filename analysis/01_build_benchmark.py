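#!/usr/bin/env python
"""Build the synthetic two-species benchmark community.

Generates the target/competitor pair with an 85%/10%/5% uptake-niche split,
8 planted precision prebiotics (1.5x yield advantage for the target), two
growth-inert dead-end compounds, an NGM-like medium, a Biolog-style
phenotype table, and HMDB-style class annotations, then writes everything
under results/benchmark/ together with the planted ground truth.
"""

import json
from pathlib import Path

from prebioscreen.synthetic_data import BenchmarkSpec, write_benchmark

OUT = Path(__file__).resolve().parent.parent / "results" / "benchmark"
SEED = 1


def main() -> None:
    spec = BenchmarkSpec(seed=SEED)
    write_benchmark(OUT, spec)
    truth = json.loads((OUT / "ground_truth.json").read_text())
    print(f"benchmark written to {OUT}")
    print(f"  target species:      {truth['target']}")
    print(f"  competitor species:  {truth['competitor']}")
    print(f"  shared compounds:    {len(truth['shared_compounds'])}")
    print(f"  target-unique:       {len(truth['target_unique'])}")
    print(f"  competitor-unique:   {len(truth['competitor_unique'])}")
    print(f"  planted prebiotics:  {sorted(truth['planted_prebiotics'])}")


if __name__ == "__main__":
    main()
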