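#!/usr/bin/env python
"""Compound-class enrichment of the confirmed candidates and the host
colonization-proportion analysis.

Enrichment: one-sided Fisher exact tests of each annotation class among the
Biolog-confirmed candidates against the background of all medium compounds
(BH-corrected). The benchmark plants most prebiotics in the "amino acid"
class, which should therefore surface with the smallest p-value.

Host analysis: given target proportions on supplemented/unsupplemented
lawns and inside unsupplemented hosts, the expected in-host proportion
under supplementation is the supplemented lawn proportion times the
host-filtering ratio (in-host / on-lawn without supplement). Observed
in-host counts are compared to that expectation with a Pearson chi-square.
The colonization table used here is synthetic (values chosen near a
60% -> 75% lawn shift); it illustrates the calculation, not a measured
experiment.
"""

import json
from pathlib import Path

import pandas as pd

from prebioscreen import screening as sc
from prebioscreen.model_core import read_annotation_tsv, read_medium_tsv

ROOT = Path(__file__).resolve().parent.parent
BENCH = ROOT / "results" / "benchmark"
OUT = ROOT / "results"


def main() -> None:
    screen = json.loads((OUT / "screen_result.json").read_text())
    confirmed = set(screen["biolog_confirmed"])
    annotation = read_annotation_tsv(BENCH / "annotation.tsv")
    background = set(read_medium_tsv(BENCH / "medium.tsv").availabilities)

    enrich = sc.class_enrichment(confirmed, annotation, background)
    enrich.to_csv(OUT / "class_enrichment.tsv", sep="\t", index=False)
    print("class enrichment among confirmed candidates:")
    print(enrich.to_string(index=False))

    # synthetic colonization proportions (condition, compartment, species)
    colonization = pd.DataFrame(
        [
            {"condition": "control", "compartment": "lawn", "species": "target", "proportion": 0.60},
            {"condition": "supplemented", "compartment": "lawn", "species": "target", "proportion": 0.75},
            {"condition": "control", "compartment": "worm", "species": "target", "proportion": 0.50},
            {"condition": "supplemented", "compartment": "worm", "species": "target", "proportion": 0.80},
        ]
    )
    colonization.to_csv(OUT / "synthetic_colonization.tsv", sep="\t", index=False)
    get = lambda cond, comp: float(
        colonization.query("condition == @cond and compartment == @comp")["proportion"].iloc[0]
    )
    host = sc.HostColonizationData(
        prop_lawn_base=get("control", "lawn"),
        prop_lawn_suppl=get("supplemented", "lawn"),
        prop_worm_base=get("control", "worm"),
        prop_worm_suppl=get("supplemented", "worm"),
    )
    expected = sc.expected_worm_proportion(host)
    n_worm_colonies = 100
    observed = [
        round(host.prop_worm_suppl * n_worm_colonies),
        round((1 - host.prop_worm_suppl) * n_worm_colonies),
    ]
    chi2, df, p = sc.chisq_observed_vs_expected(observed, [expected, 1 - expected])
    print(f"\nexpected in-host target proportion under supplementation: {expected:.4f}")
    print(f"observed {host.prop_worm_suppl:.0%} vs expected {expected:.1%}: "
          f"chi2 = {chi2:.3f}, df = {df}, p = {p:.4g}")
    if host.prop_worm_suppl > expected:
        print("the host amplifies the supplement's effect beyond the change in diet")


if __name__ == "__main__":
    main()
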