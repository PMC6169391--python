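#!/usr/bin/env python
"""Screen-level statistics.

Recomputes the published remobilization-frequency table from raw counts,
tests the annotated synthetic insertions for first-intron preference, and
summarizes upstream insertion distances for 5'-UTR-intron events.
Writes results/remobilization_frequencies.tsv and results/screen_stats.txt.
"""

from pathlib import Path

import pandas as pd

from traptag.stats import (distance_summary, frequency_table,
                           intron_position_test, load_screen_counts)

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    lines = []
    freq = frequency_table(load_screen_counts())
    freq.to_csv(BASE / "remobilization_frequencies.tsv", sep="\t", index=False)
    lines.append("Remobilization frequencies (percent, exact binomial 95% CI):")
    lines.append(freq.to_string(index=False))

    calls = pd.read_csv(BASE / "insertions.tsv", sep="\t")
    intronic = calls[calls["intron_ordinal"] > 0]
    counts = intronic["intron_ordinal"].value_counts().to_dict()
    gof = intron_position_test(counts, intronic["n_introns"].tolist())
    lines.append("")
    lines.append(f"Intron-position preference ({len(intronic)} intronic events): "
                 f"chi2 = {gof.chi2:.2f}, df = {gof.df}, P = {gof.p:.3g}")
    first = (intronic["intron_ordinal"] == 1).sum()
    lines.append(f"First-intron events: {first} of {len(intronic)} "
                 f"({100 * first / len(intronic):.0f}%)")

    utr = calls[calls["feature_class"] == "five_prime_utr_intron"]
    s = distance_summary(utr["distance_to_orf_start"])
    lines.append("")
    lines.append(f"Upstream distance to the +1 ATG for {s.n} 5'-UTR-intron "
                 f"insertions: median {s.median:.0f} bp "
                 f"(range {s.min:.0f}-{s.max:.0f}, IQR {s.q1:.0f}-{s.q3:.0f})")

    report = "\n".join(lines)
    (BASE / "screen_stats.txt").write_text(report + "\n")
    print(report)
    print(f"-> {BASE / 'screen_stats.txt'}")


if __name__ == "__main__":
    main()
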