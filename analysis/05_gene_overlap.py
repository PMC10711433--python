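"""Hypergeometric overlap of a DEG-style list with an rG4-gene-style list.

Simulates two gene lists at the study sizes (360 differentially
expressed genes, 3381 quadruplex-bearing genes, 114 shared) over a
20,000-gene universe and runs the overlap test: representation factor
and upper hypergeometric tail P(X >= k).
"""

import json
from pathlib import Path

from selexg4.overlap import overlap_test
from selexg4.simulate import simulate_gene_lists

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 1

UNIVERSE_N, N_DEG, N_RG4, K_PLANTED = 20_000, 360, 3381, 114


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    degs, rg4_genes = simulate_gene_lists(UNIVERSE_N, N_DEG, N_RG4, K_PLANTED, seed=SEED)
    result = overlap_test(degs, rg4_genes, UNIVERSE_N)
    (RESULTS / "overlap.json").write_text(json.dumps(result.as_dict(), indent=2) + "\n")
    for key, value in result.as_dict().items():
        print(f"{key}: {value}")
    print(
        f"\n{result.k} of {result.n1} genes overlap the {result.n2}-gene list "
        f"({result.representation_factor:.2f}x the {result.expected:.1f} expected "
        f"under independence; P(X >= {result.k}) = {result.pvalue_ge:.3g})"
    )


if __name__ == "__main__":
    main()
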