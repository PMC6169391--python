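"""Splice-acceptor conservation matrix (position-specific scoring).

The matrix is trained on fixed-width windows ending at each intron's
terminal AG. Per-position conservation is information content in bits,
``IC_i = 2 + sum_b p_i(b) log2 p_i(b)``, which is 0 for uniform base
usage and 2 for an invariant position.

Two scoring modes are supported, because "conservation by position" does
not pin down an arithmetic:

* ``frequency`` (default): score(s) = sum_i IC_i * p_i(s_i)
* ``consensus``: score(s) = sum_i IC_i * [s_i == argmax_b p_i(b)]

Under both, the per-position consensus attains the matrix maximum.
Sequences shorter than the matrix are right-aligned to the acceptor end;
uncovered positions contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genes import GeneModel

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class AcceptorMatrix:
    freqs: np.ndarray            # (width, 4) rows sum to 1
    n_training: int
    pseudocount: float

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def info_content(self) -> np.ndarray:
        """Per-position conservation in bits, in [0, 2]."""
        p = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + plogp.sum(axis=1)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    def max_score(self, mode: str = "frequency") -> float:
        ic = self.info_content
        if mode == "frequency":
            return float((ic * self.freqs.max(axis=1)).sum())
        if mode == "consensus":
            return float(ic.sum())
        raise ValueError(f"unknown scoring mode {mode!r}")


def extract_acceptor_windows(genes: list[GeneModel], genome: dict[str, str],
                             width: int = 21) -> tuple[list[str], int]:
    """The last ``width`` nt of every intron (windows end at the terminal AG).

    Returns (windows, n_skipped) where skipped introns were shorter than
    the window.
    """
    if width < 2:
        raise ValueError("width must be >= 2")
    windows, skipped = [], 0
    for g in genes:
        for iv in g.introns_5to3:
            if iv[1] - iv[0] + 1 < width:
                skipped += 1
                continue
            if g.strand == "+":
                w = genome[g.scaffold][iv[1] - width:iv[1]]
            else:
                from .dna import revcomp
                w = revcomp(genome[g.scaffold][iv[0] - 1:iv[0] - 1 + width])
            windows.append(w)
    return windows, skipped


def build_matrix(windows: list[str], pseudocount: float = 1.0) -> AcceptorMatrix:
    """Base-frequency matrix from aligned acceptor windows."""
    if not windows:
        raise ValueError("at least one training window required")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("training windows have mixed widths")
    counts = np.full((width, 4), float(pseudocount))
    for w in windows:
        for i, b in enumerate(w.upper()):
            if b not in _IDX:
                raise ValueError(f"non-ACGT base {b!r} in training window")
            counts[i, _IDX[b]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return AcceptorMatrix(freqs=freqs, n_training=len(windows),
                          pseudocount=pseudocount)


def score_sequence(matrix: AcceptorMatrix, seq: str,
                   mode: str = "frequency") -> float:
    """Score a candidate acceptor, right-aligned to the window's 3' end."""
    s = seq.upper()
    if len(s) > matrix.width:
        raise ValueError("sequence longer than the matrix")
    bad = [b for b in s if b not in _IDX]
    if bad:
        raise ValueError(f"non-ACGT base {bad[0]!r} in sequence")
    ic = matrix.info_content
    offset = matrix.width - len(s)
    total = 0.0
    for i, b in enumerate(s):
        pos = offset + i
        if mode == "frequency":
            total += ic[pos] * matrix.freqs[pos, _IDX[b]]
        elif mode == "consensus":
            total += ic[pos] * (matrix.freqs[pos].argmax() == _IDX[b])
        else:
            raise ValueError(f"unknown scoring mode {mode!r}")
    return float(total)


def save_matrix(matrix: AcceptorMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.freqs, columns=list(BASES))
    df.insert(0, "position", np.arange(1, matrix.width + 1))
    df["info_content"] = matrix.info_content
    with open(path, "w") as fh:
        fh.write(f"# acceptor matrix; n_training={matrix.n_training} "
                 f"pseudocount={matrix.pseudocount}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_matrix(path: str | Path) -> AcceptorMatrix:
    """Load a matrix TSV (per-position A/C/G/T frequencies or weights).

    Rows are normalized to frequencies, so an externally published
    per-base scoring table can be loaded and used with either mode.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c for c in df.columns if c.upper() in set(BASES)]
    if len(cols) != 4:
        raise ValueError("matrix file must carry A/C/G/T columns")
    vals = df[sorted(cols, key=lambda c: _IDX[c.upper()])].to_numpy(dtype=float)
    freqs = vals / vals.sum(axis=1, keepdims=True)
    return AcceptorMatrix(freqs=freqs, n_training=0, pseudocount=0.0)
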