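"""Simulate the demo Cre+/Cre- labelling experiment.

Writes a ground-truthed synthetic experiment (reference, windows, aligned
reads for 4 Cre+ and 3 Cre- animals, truth table) to results/experiment/.
"""

from pathlib import Path

from slamitseq.simulate import SimConfig, simulate_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"

CONFIG = SimConfig(
    seed=20,
    n_genes=300,
    n_labelled=30,
    snp_fraction=0.1,
    expression=100.0,
)


def main() -> None:
    out = simulate_experiment(CONFIG, RESULTS / "experiment", force=True)
    print(f"simulated {CONFIG.n_genes} genes ({CONFIG.n_labelled} labelled) -> {out}")


if __name__ == "__main__":
    main()
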