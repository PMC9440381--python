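"""Generate the study cohort: 11 cases vs 9 controls, 30 genes, with one
regulator gene knocked down in cases so that its five outgoing regulatory
edges are the ground-truth differential edges.

Writes counts.tsv, lengths.tsv, labels.tsv and truth.json under
results/cohort/.
"""

import argparse
from pathlib import Path

from ecvnet import simulate as sim
from ecvnet.io_formats import write_labels, write_lengths, write_matrix


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    truth = sim.knockdown_scenario(30, 0.06, 5, effect=0.0, seed=args.seed)
    counts, labels = sim.simulate_counts(truth, 11, 9, seed=args.seed + 90)

    out = args.results_dir / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(counts.counts, out / "counts.tsv")
    write_lengths(counts.gene_lengths, out / "lengths.tsv")
    write_labels(labels, out / "labels.tsv")
    sim.save_truth(truth, out / "truth.json")

    regulator = truth.perturbed_edges[0][0]
    print(f"cohort: {len(truth.network.gene_ids)} genes, "
          f"{labels.n_case} cases vs {labels.n_control} controls")
    print(f"true network: {len(truth.network.edges)} edges")
    print(f"knocked-down regulator: {regulator} "
          f"(depth {truth.knockdown_depth} log2 units in cases)")
    print(f"ablated edges: {list(truth.perturbed_edges)}")
    print(f"written to {out}/")


if __name__ == "__main__":
    main()
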