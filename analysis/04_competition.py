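"""Simulated competition immunoprecipitations and fold-enrichment tests.

Three conditions over an equimolar 5-aptamer mixture (RF000-RF004 +
scr50), 3 replicates each at 10k retained reads:

* beads-only control - no specific retention (all ratios ~1);
* protein - the four G2-rich aptamers retained 8-15x over scr50;
* Li+ buffer - quadruplex-destabilizing: RF000/RF001 collapse toward
  background while RF002/RF004 stay enriched.

FE = count(RF00x)/count(scr50) per replicate; conditions are compared
with the exact two-tailed Mann-Whitney U test on the pooled ratios.
"""

from pathlib import Path

import numpy as np

from selexg4.competition import (
    TestKind,
    compare_fe,
    condition_fe_table,
    retention_frequencies,
)
from selexg4.simulate import simulate_competition

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 1

TARGETS = ["RF000", "RF001", "RF002", "RF004"]
CONDITIONS = {
    "beads_only": {"RF000": 1.0, "RF001": 1.0, "RF002": 1.0, "RF004": 1.0, "scr50": 1.0},
    "protein": {"RF000": 8.0, "RF001": 10.0, "RF002": 15.0, "RF004": 12.0, "scr50": 1.0},
    "licl": {"RF000": 1.5, "RF001": 1.5, "RF002": 10.0, "RF004": 8.0, "scr50": 1.0},
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    tables = []
    for condition, retention in CONDITIONS.items():
        cond_tables, _ = simulate_competition(
            retention, replicates=3, depth=10_000, seed=rng, condition=condition
        )
        tables.extend(cond_tables)

    fe = condition_fe_table(tables, TARGETS)
    with open(RESULTS / "competition_fe.tsv", "w") as fh:
        fh.write("condition\taptamer_id\tmean_fe\tpvalue_vs_beads_only\n")
        for condition in CONDITIONS:
            for target in TARGETS:
                fes = fe[condition][target]
                mean_fe = sum(fes) / len(fes)
                p = compare_fe(
                    fe["beads_only"][target], fes, TestKind.MANN_WHITNEY_TWO_TAILED
                )
                fh.write(f"{condition}\t{target}\t{mean_fe:.3g}\t{p:.4g}\n")
                print(f"{condition:>10}  {target}  FE={mean_fe:7.2f}  p={p:.3g}")

    freqs = retention_frequencies(tables[-1])
    print("\nlast LiCl replicate retention fractions (sum to 1):")
    print("  " + "  ".join(f"{a}={freqs[a]:.3f}" for a in sorted(freqs)))
    pooled_p = compare_fe(
        fe["beads_only"]["pooled"], fe["protein"]["pooled"],
        TestKind.MANN_WHITNEY_TWO_TAILED,
    )
    print(
        f"\npooled protein-vs-control Mann-Whitney p = {pooled_p:.3g}: the "
        "G2-rich aptamers are specifically retained; under Li+ only "
        "RF002/RF004 remain enriched"
    )


if __name__ == "__main__":
    main()
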