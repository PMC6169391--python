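#!/usr/bin/env python
"""Generate the synthetic promoter-trap screen used by the downstream steps.

Writes genome, annotation, planted insertions (with truth set),
splinkerette flanks and paired-end reads to results/synthetic/.
"""

from pathlib import Path

from traptag.synthetic import SyntheticConfig, simulate_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1


def main():
    cfg = SyntheticConfig(seed=SEED)
    ds = simulate_dataset(cfg)
    paths = ds.write(OUT)
    n_chim = sum(1 for rid, _, _ in ds.pairs if rid.startswith("chim"))
    print(f"synthetic screen (seed {SEED}):")
    print(f"  {len(ds.genome)} scaffolds, {len(ds.genes)} genes "
          f"({sum(any(g.is_utr_intron(i) for i in g.introns) for g in ds.genes)} "
          f"with a 5'-UTR intron)")
    classes = {k: int(v) for k, v in
               ds.truth["true_feature_class"].value_counts().items()}
    print(f"  {len(ds.truth)} planted insertions ({classes})")
    print(f"  {len(ds.pairs)} read pairs, {n_chim} reporter-fusion chimeras")
    print(f"  outputs: {', '.join(sorted(p.name for p in paths.values()))}")
    print(f"  -> {OUT}")


if __name__ == "__main__":
    main()
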