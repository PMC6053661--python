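"""Evaluate the calls against the simulator truth.

Treats the truly labelled genes as a marker panel, tabulates labelled
proportion by window T content, and writes the pseudo-counted plotting
table.  Outputs land in results/report/.
"""

import json
from pathlib import Path

import pandas as pd

from slamitseq.quant import read_reference, read_windows
from slamitseq.report import MarkerPanel, evaluate_panel, plotting_table, tcontent_bins

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    exp = RESULTS / "experiment"
    out = RESULTS / "report"
    out.mkdir(parents=True, exist_ok=True)
    results = pd.read_csv(RESULTS / "results.tsv", sep="\t")
    counts = pd.read_csv(RESULTS / "counts.tsv", sep="\t", na_values="NA")
    sheet = pd.read_csv(exp / "samples.tsv", sep="\t")
    truth = pd.read_csv(exp / "truth.tsv", sep="\t")

    labelled_truth = sorted(
        set(truth.loc[(truth["group"] == "cre_pos") & (truth["labelled_fraction"] > 0), "gene"])
    )
    panel = MarkerPanel("simulated_truth", tuple(labelled_truth))
    calls, sensitivity = evaluate_panel(results, panel)
    calls.to_csv(out / "panel_calls.tsv", sep="\t", index=False)

    fdp_genes = set(results.loc[results["labelled"], "gene"]) - set(labelled_truth)
    (out / "evaluation.json").write_text(
        json.dumps(
            {
                "panel_sensitivity": sensitivity,
                "n_panel": len(panel.genes),
                "false_positives": sorted(fdp_genes),
            },
            indent=2,
        )
        + "\n"
    )

    seqs = read_reference(exp / "reference.fa")
    windows = read_windows(exp / "windows.bed")
    t_content = pd.Series(
        {
            w.name: sum(
                1
                for b in seqs[w.contig][w.start : w.end]
                if b == ("T" if w.strand == "+" else "A")
            )
            for w in windows.itertuples(index=False)
        }
    )
    tcontent_bins(results, t_content).to_csv(out / "tcontent_bins.tsv", sep="\t", index=False)
    plotting_table(results, counts, sheet).to_csv(
        out / "plotting_table.tsv", sep="\t", index=False
    )
    print(f"panel sensitivity {sensitivity:.2f} over {len(panel.genes)} truly "
          f"labelled genes; {len(fdp_genes)} false positives")


if __name__ == "__main__":
    main()
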