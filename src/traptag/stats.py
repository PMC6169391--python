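"""Screen-level statistics for a promoter-trap remobilization screen.

Remobilization frequency (reporter-positive individuals / screened, as a
percentage), chi-square goodness of fit for chromosomal distribution
(local hopping) and intron-position preference, and five-number distance
summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ScreenCounts:
    line_id: str
    locus_label: str
    n_screened: int
    n_events: int

    def __post_init__(self):
        if not 0 <= self.n_events <= self.n_screened:
            raise ValueError("need 0 <= n_events <= n_screened")


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    p: float
    observed: tuple[float, ...]
    expected: tuple[float, ...]
    low_expected_warning: bool = False


@dataclass(frozen=True)
class DistanceSummary:
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float


def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal(10) ** -ndigits,
                                                  rounding=ROUND_HALF_UP))


def remobilization_frequency(counts: ScreenCounts
                             ) -> tuple[float, tuple[float, float]]:
    """Percent of screened individuals with a reporter-positive event.

    Returns (percent rounded half-up to 2 decimals, exact binomial 95% CI
    on the percent scale).
    """
    if counts.n_screened == 0:
        raise ValueError("n_screened must be > 0")
    pct = 100.0 * counts.n_events / counts.n_screened
    ci = sps.binomtest(counts.n_events, counts.n_screened).proportion_ci(
        confidence_level=0.95, method="exact")
    return round_half_up(pct, 2), (100.0 * ci.low, 100.0 * ci.high)


def load_screen_counts(path: str | Path | None = None) -> list[ScreenCounts]:
    """Screen count table; defaults to the published five-line screen."""
    if path is None:
        ref = resources.files("traptag").joinpath("data/screen_counts.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#", keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    return [ScreenCounts(r.line_id, str(r.locus_label), int(r.n_screened),
                         int(r.n_events)) for r in df.itertuples()]


def frequency_table(counts: list[ScreenCounts]) -> pd.DataFrame:
    rows = []
    for c in counts:
        pct, (lo, hi) = remobilization_frequency(c)
        rows.append({"line_id": c.line_id, "locus": c.locus_label,
                     "n_screened": c.n_screened, "n_events": c.n_events,
                     "frequency_pct": pct, "ci95_low_pct": lo, "ci95_high_pct": hi})
    df = pd.DataFrame(rows)
    total = pd.DataFrame([{
        "line_id": "TOTAL", "locus": "",
        "n_screened": int(df["n_screened"].sum()),
        "n_events": int(df["n_events"].sum()),
        "frequency_pct": round_half_up(
            100.0 * df["n_events"].sum() / df["n_screened"].sum(), 2),
        "ci95_low_pct": np.nan, "ci95_high_pct": np.nan}])
    return pd.concat([df, total], ignore_index=True)


def chisq_gof(observed, expected_proportions) -> GofResult:
    """Pearson chi-square goodness of fit, df = k - 1."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two categories")
    if obs.size != props.size:
        raise ValueError("observed and expected_proportions differ in length")
    if obs.sum() <= 0:
        raise ValueError("observed counts sum to zero")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"expected proportions sum to {props.sum()}, not 1")
    exp = props * obs.sum()
    low = bool((exp < 5).any())
    if low:
        warnings.warn("some expected counts < 5; chi-square approximation is weak",
                      stacklevel=2)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(sps.chi2.sf(chi2, df))
    return GofResult(chi2=chi2, df=df, p=p, observed=tuple(obs),
                     expected=tuple(exp), low_expected_warning=low)


def intron_position_null(n_by_gene, categories: int) -> np.ndarray:
    """Null ordinal proportions when every intron of each hit gene is equally likely.

    A gene with n introns contributes probability 1/n to each ordinal
    1..n; ordinals >= ``categories`` are pooled into the last category.
    """
    props = np.zeros(categories)
    for n in n_by_gene:
        share = 1.0 / n
        for ordinal in range(1, n + 1):
            props[min(ordinal, categories) - 1] += share
    return props / props.sum()


def intron_position_test(ordinal_counts: dict[int, int], n_by_gene,
                         layout: str = "per_ordinal",
                         categories: int | None = None) -> GofResult:
    """Goodness of fit of intron-ordinal counts against the equal-intron null.

    ``layout='per_ordinal'`` tests one category per ordinal (pooling
    above ``categories``); ``layout='first_vs_rest'`` collapses to first
    intron vs all others.
    """
    total = sum(ordinal_counts.values())
    if total == 0:
        raise ValueError("no intronic events")
    max_ord = max(ordinal_counts)
    if layout == "first_vs_rest":
        props = intron_position_null(n_by_gene, max(2, max_ord))
        obs = [ordinal_counts.get(1, 0), total - ordinal_counts.get(1, 0)]
        exp_props = [props[0], props[1:].sum()]
        return chisq_gof(obs, exp_props)
    if layout != "per_ordinal":
        raise ValueError(f"unknown layout {layout!r}")
    k = categories or max_ord
    obs = [sum(v for o, v in ordinal_counts.items() if min(o, k) == c)
           for c in range(1, k + 1)]
    props = intron_position_null(n_by_gene, k)
    return chisq_gof(obs, props)


def distance_summary(distances) -> DistanceSummary:
    """Five-number summary; even-n median is the mean of the central pair."""
    arr = np.asarray(list(distances), dtype=float)
    if arr.size == 0:
        raise ValueError("no distances supplied")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return DistanceSummary(n=int(arr.size), min=float(arr.min()), q1=float(q1),
                           median=float(med), q3=float(q3), max=float(arr.max()))


def simulate_null_rejection_rate(n_events: int, n_categories: int,
                                 n_replicates: int, alpha: float = 0.05,
                                 seed: int = 0) -> float:
    """Type-I error of the chi-square test under uniform reinsertion."""
    rng = np.random.default_rng(seed)
    props = np.full(n_categories, 1.0 / n_categories)
    counts = rng.multinomial(n_events, props, size=n_replicates)
    exp = n_events * props
    chi2 = ((counts - exp) ** 2 / exp).sum(axis=1)
    p = sps.chi2.sf(chi2, n_categories - 1)
    return float((p < alpha).mean())
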