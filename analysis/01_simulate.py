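#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emulates the design of the exercise transcriptome study: 3 groups (Control,
Endurance, Resistance) x 6 subjects x 3 biopsy times (Pre, 2.5 h, 5 h),
log2-scale expression with subject random intercepts and a planted mixture
of effect classes (group-specific, exercise-general, time-regulated, null).
The default cohort is 8,000 transcripts — a demonstration scale that keeps
every downstream step interactive; pass --n-transcripts 28869 for the full
array-sized cohort.

Writes expression.tsv, design.tsv and truth.tsv under results/simulated/.
"""

import argparse
from pathlib import Path

from exanova import SimConfig, generate_dataset
from exanova.simulate import write_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    ap.add_argument("--n-transcripts", type=int, default=8000)
    ap.add_argument("--seed", type=int, default=20140041)
    args = ap.parse_args()

    cfg = SimConfig(n_transcripts=args.n_transcripts, seed=args.seed)
    matrix, design, truth = generate_dataset(cfg)
    paths = write_dataset(matrix, design, truth, args.results_dir / "simulated")

    counts = truth.table.planted_class.value_counts()
    print(f"simulated {matrix.shape[0]} transcripts x {matrix.shape[1]} samples "
          f"(seed {cfg.seed})")
    print("planted classes:")
    for cls, n in counts.items():
        print(f"  {cls:22s} {n}")
    print(f"wrote {', '.join(str(p) for p in paths.values())}")


if __name__ == "__main__":
    main()
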