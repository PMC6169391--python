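#!/usr/bin/env python
"""Build the 21-position splice-acceptor conservation matrix.

Trains on every annotated intron's terminal 21 nt, writes
results/acceptor_matrix.tsv, and scores the promoter-trap construct's
planned (TTCCCCCCTCCCAGCAG) and unplanned (ATATCGTTAGTCTTTCAACAG)
acceptors against it, alongside random genomic 21-mers.
"""

from pathlib import Path

import numpy as np

from traptag.genes import read_fasta, read_gff3
from traptag.pssm import build_matrix, extract_acceptor_windows, save_matrix, score_sequence
from traptag.synthetic import PLANNED_SA, UNPLANNED_SA_WINDOW

BASE = Path(__file__).resolve().parent.parent / "results"
SYN = BASE / "synthetic"


def main():
    genome = read_fasta(SYN / "genome.fasta")
    genes = read_gff3(SYN / "annotation.gff3")
    windows, skipped = extract_acceptor_windows(genes, genome, width=21)
    matrix = build_matrix(windows, pseudocount=1.0)
    save_matrix(matrix, BASE / "acceptor_matrix.tsv")

    print(f"trained on {len(windows)} acceptor windows "
          f"({skipped} introns shorter than 21 nt skipped)")
    print(f"max score {matrix.max_score('frequency'):.2f}; "
          f"consensus {matrix.consensus}")
    for name, seq in (("planned 3'-SA", PLANNED_SA),
                      ("unplanned 3'-SA", UNPLANNED_SA_WINDOW)):
        print(f"  {name:16s} {seq:>21s}  "
              f"score {score_sequence(matrix, seq):.2f}")
    acc = np.mean([score_sequence(matrix, w) for w in windows])
    rng = np.random.default_rng(1)
    names = sorted(genome)
    rand = np.mean([score_sequence(
        matrix, genome[names[rng.integers(0, len(names))]][i:i + 21])
        for i in rng.integers(0, min(len(genome[n]) for n in names) - 21,
                              size=500)])
    print(f"mean score: true acceptors {acc:.2f} vs random 21-mers {rand:.2f}")
    print(f"-> {BASE / 'acceptor_matrix.tsv'}")


if __name__ == "__main__":
    main()
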