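#!/usr/bin/env python
"""Uptake-niche analysis: pairwise overlap and the unique-fraction curve.

Computes the uptake profiles of the benchmark pair under the NGM-like
medium (expected overlap: 85% shared, 10% target-private, 5%
competitor-private), the pair's unique uptake compounds, and — on a larger
synthetic community pool with 70% expected niche overlap — the fraction of
species with at least one unique uptake compound in random subcommunities
of increasing size. The curve falls towards zero well before the pool size
is reached: in any realistically sized community, single-species metabolic
niches are rare, which is why the supplementation screen (03) works with
shared compounds instead.
"""

import json
import logging
from pathlib import Path

from prebioscreen.model_core import Medium, read_medium_tsv, read_model
from prebioscreen.niche_analysis import (
    profiles_to_frame,
    unique_fraction_curve,
    unique_uptake_compounds,
    uptake_profile,
)
from prebioscreen.synthetic_data import generate_community_pool

ROOT = Path(__file__).resolve().parent.parent
BENCH = ROOT / "results" / "benchmark"
OUT = ROOT / "results"
SEED = 1


def main() -> None:
    logging.getLogger("prebioscreen").setLevel(logging.ERROR)
    truth = json.loads((BENCH / "ground_truth.json").read_text())
    models = [read_model(BENCH / f"{sid}.json") for sid in (truth["target"], truth["competitor"])]
    medium = read_medium_tsv(BENCH / "medium.tsv")

    profiles = [uptake_profile(m, medium) for m in models]
    profiles_to_frame(profiles).to_csv(OUT / "uptake_profiles.tsv", sep="\t", index=False)
    a, b = (p.uptake_compounds for p in profiles)
    union = a | b
    print(f"uptake compounds: {len(a)} (target), {len(b)} (competitor), union {len(union)}")
    print(f"  shared:            {len(a & b) / len(union):.0%}")
    print(f"  target-private:    {len(a - b) / len(union):.0%}")
    print(f"  competitor-private:{len(b - a) / len(union):.1%}")
    report = unique_uptake_compounds(profiles)
    print(f"unique uptake compounds: { {k: sorted(v) for k, v in report.unique_compounds.items()} }")

    pool = generate_community_pool(n_species=12, overlap=0.7, n_compounds=14, seed=SEED)
    pool_profiles = [uptake_profile(m, Medium({}), probe_availability=10.0) for m in pool]
    curve = unique_fraction_curve(pool_profiles, list(range(2, 13)), iterations=50, seed=SEED)
    curve.to_csv(OUT / "unique_fraction_curve.tsv", sep="\t", index=False)
    means = curve.groupby("size")["fraction_with_unique"].mean()
    print("mean fraction of species with a unique uptake compound, by community size:")
    for size, frac in means.items():
        print(f"  size {size:2d}: {frac:.3f}")


if __name__ == "__main__":
    main()
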