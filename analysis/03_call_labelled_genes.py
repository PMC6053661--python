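"""Beta-binomial replicate test and FDR calling of labelled genes.

Reads results/counts.tsv, tests every gene Cre+ vs Cre-, adjusts with
Benjamini-Hochberg, and writes results/results.tsv, the zero-coverage
filter report, and the p-value-ranked gene list.
"""

import json
from pathlib import Path

import pandas as pd

from slamitseq.stats import call_labelled, run_labelling_tests

RESULTS = Path(__file__).resolve().parents[1] / "results"
FDR = 0.05


def main() -> None:
    counts = pd.read_csv(RESULTS / "counts.tsv", sep="\t", na_values="NA")
    sheet = pd.read_csv(RESULTS / "experiment" / "samples.tsv", sep="\t")
    results, filt = run_labelling_tests(counts, sheet)
    results = call_labelled(results, fdr=FDR)
    results.to_csv(RESULTS / "results.tsv", sep="\t", index=False)
    (RESULTS / "filter_report.json").write_text(
        json.dumps(filt.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    (RESULTS / "ranked_genes.txt").write_text("\n".join(results["gene"]) + "\n")
    print(f"tested {filt.genes_tested} genes ({filt.genes_removed} removed); "
          f"{int(results['labelled'].sum())} labelled at FDR<{FDR}")


if __name__ == "__main__":
    main()
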