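"""End-to-end orchestration: simulate -> find junctions -> annotate -> PSSM -> stats.

Single-process, file-based staging. Every TSV output carries a header
with the tool version, config hash, and seed; a manifest records sha256
checksums so a rerun with the same config and seed can be verified
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_flanks, collapse_sides, tabulate_insertions
from .junctions import FinderParams, aggregate_hits, locate_junction, scan_read_pairs
from .pssm import build_matrix, extract_acceptor_windows, save_matrix, score_sequence
from .stats import (distance_summary, frequency_table, intron_position_test,
                    load_screen_counts)
from .synthetic import SyntheticConfig, simulate_dataset

log = logging.getLogger("traptag")


@dataclass
class RunConfig:
    outdir: str = "traptag_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    finder: FinderParams = field(default_factory=FinderParams)
    pssm_mode: str = "frequency"
    stats_null: str = "uniform"
    screen_counts: str | None = None   # TSV path; None = bundled screen table
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = SyntheticConfig(**{**raw.get("synthetic", {}),
                                 "seed": raw.get("seed", 0)})
        finder = FinderParams(**raw.get("finder", {}))
        keys = {"outdir", "seed", "pssm_mode", "stats_null",
                "screen_counts", "log_level"}
        top = {k: v for k, v in raw.items() if k in keys}
        if top.get("screen_counts") and not Path(top["screen_counts"]).exists():
            raise FileNotFoundError(
                f"screen_counts file not found: {top['screen_counts']}")
        return cls(synthetic=syn, finder=finder, **top)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        d["finder"] = dataclasses.asdict(self.finder)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths and logging excluded)."""
        d = self.to_dict()
        for k in ("outdir", "log_level"):
            d.pop(k, None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _tsv_header(config: RunConfig) -> str:
    return (f"# traptag {__version__} seed={config.seed} "
            f"config={config.config_hash()}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_tsv_header(config))
        df.to_csv(fh, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a metrics dict and writes a run directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    metrics: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    # -- stage 1: synthetic screen -----------------------------------------
    log.info("stage simulate: generating synthetic screen (seed=%d)", config.seed)
    syn_cfg = dataclasses.replace(config.synthetic, seed=config.seed)
    ds = simulate_dataset(syn_cfg)
    paths = ds.write(out)

    # -- stage 2: junction finding ------------------------------------------
    log.info("stage find-junctions: scanning %d read pairs", len(ds.pairs))
    params = dataclasses.replace(
        config.finder, ires_tag=ds.elements["IRES"].ires_tag)
    reporter = ds.elements["non_IRES"].reporter_orf
    hits = scan_read_pairs(ds.pairs, reporter, params)
    for h in hits:
        if len(h.genomic_tag) >= params.min_genomic_tag:
            locate_junction(h, ds.genome, ds.genes, params.min_genomic_tag,
                            elements=ds.elements)
    hits_table = aggregate_hits(hits)
    paths["junctions"] = out / "junctions.tsv"
    _write_tsv(hits_table, paths["junctions"], config)

    truth_chim = set()
    for ids in ds.truth["chimeric_read_ids"]:
        truth_chim.update(i for i in str(ids).split(",") if i)
    found = {h.pair_id for h in hits}
    metrics["junction_sensitivity"] = (
        len(found & truth_chim) / len(truth_chim) if truth_chim else float("nan"))
    metrics["junction_false_positives"] = len(found - truth_chim)
    metrics["n_junction_hits"] = len(hits)

    # -- stage 3: insertion annotation --------------------------------------
    log.info("stage annotate: mapping %d flanks", len(ds.flanks))
    annotated, problems = annotate_flanks(ds.flanks, ds.elements,
                                          ds.genome, ds.genes)
    calls = collapse_sides(annotated)
    paths["insertions"] = out / "insertions.tsv"
    _write_tsv(calls, paths["insertions"], config)
    for p in problems:
        log.warning("flank problem: %s", p)

    merged = calls.merge(ds.truth, on="insertion_id", suffixes=("", "_true"))
    ok = ((merged["scaffold"] == merged["scaffold_true"])
          & (merged["ttaa_start"] == merged["ttaa_start_true"])
          & (merged["element_orientation"] == merged["element_strand"])
          & (merged["feature_class"] == merged["true_feature_class"]))
    metrics["truth_recovery"] = float(ok.mean()) if len(merged) else 0.0
    metrics["n_insertions_recovered"] = int(len(merged))
    metrics["n_insertions_planted"] = int(len(ds.truth))

    tabs = tabulate_insertions(calls)
    paths["feature_counts"] = out / "feature_class_counts.tsv"
    _write_tsv(tabs["by_feature_class"], paths["feature_counts"], config)
    paths["intron_counts"] = out / "intron_ordinal_counts.tsv"
    _write_tsv(tabs["by_intron_ordinal"], paths["intron_counts"], config)

    # -- stage 4: splice-acceptor matrix -------------------------------------
    windows, skipped = extract_acceptor_windows(ds.genes, ds.genome, width=21)
    matrix = build_matrix(windows, pseudocount=1.0)
    paths["matrix"] = out / "acceptor_matrix.tsv"
    save_matrix(matrix, paths["matrix"])
    acc_scores = [score_sequence(matrix, w, mode=config.pssm_mode)
                  for w in windows]
    rng = np.random.default_rng(config.seed)
    scaf_names = list(ds.genome)
    rand_scores = []
    for _ in range(200):
        s = scaf_names[int(rng.integers(0, len(scaf_names)))]
        i = int(rng.integers(0, len(ds.genome[s]) - 21))
        rand_scores.append(score_sequence(matrix, ds.genome[s][i:i + 21],
                                          mode=config.pssm_mode))
    metrics["pssm_max_score"] = matrix.max_score(config.pssm_mode)
    metrics["pssm_mean_acceptor_score"] = float(np.mean(acc_scores))
    metrics["pssm_mean_random_score"] = float(np.mean(rand_scores))
    metrics["pssm_n_windows"] = len(windows)

    # -- stage 5: screen statistics ------------------------------------------
    freq = frequency_table(load_screen_counts(config.screen_counts))
    paths["frequencies"] = out / "remobilization_frequencies.tsv"
    _write_tsv(freq, paths["frequencies"], config)

    intronic = calls[calls["intron_ordinal"] > 0]
    gof = None
    if len(intronic) >= 2 and intronic["intron_ordinal"].nunique() >= 2:
        ordinal_counts = intronic["intron_ordinal"].value_counts().to_dict()
        gof = intron_position_test(ordinal_counts,
                                   intronic["n_introns"].tolist())
        metrics["intron_position_chi2"] = gof.chi2
        metrics["intron_position_df"] = gof.df
        metrics["intron_position_p"] = gof.p

    utr = calls[calls["feature_class"] == "five_prime_utr_intron"]
    dist = None
    if len(utr):
        dist = distance_summary(utr["distance_to_orf_start"])
        metrics["utr_intron_fraction"] = float(len(utr) / len(calls))
        metrics["median_upstream_distance_bp"] = dist.median

    # -- report + manifest ----------------------------------------------------
    paths["report"] = out / "report.md"
    paths["report"].write_text(write_report(config, metrics, freq, hits_table,
                                            tabs, dist, gof))
    manifest = {str(p.name): _sha256(p) for p in sorted(paths.values())
                if p.name != "manifest.json"}
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(
        {"version": __version__, "seed": config.seed,
         "config": config.to_dict(), "checksums": manifest}, indent=2,
        default=str))
    metrics["outputs"] = {k: str(v) for k, v in paths.items()}
    return metrics


def write_report(config: RunConfig, metrics: dict, freq: pd.DataFrame,
                 junctions: pd.DataFrame, tabs: dict, dist, gof) -> str:
    """Markdown report mirroring the screen's result structure."""
    L = [f"# traptag run report", "",
         f"version {__version__}; seed {config.seed}; "
         f"config {config.config_hash()}", ""]
    L += ["## Remobilization frequencies", "",
          freq.to_markdown(index=False, floatfmt=".2f"), ""]
    L += ["## Reporter-fusion junction events", "",
          f"sensitivity {metrics.get('junction_sensitivity', float('nan')):.3f}, "
          f"false positives {metrics.get('junction_false_positives', 0)}", "",
          junctions.to_markdown(index=False) if len(junctions) else "(none)", ""]
    L += ["## Insertion-site classification", "",
          f"truth recovery "
          f"{100 * metrics.get('truth_recovery', 0):.1f}% of "
          f"{metrics.get('n_insertions_planted', 0)} planted insertions", "",
          tabs["by_feature_class"].to_markdown(index=False), "",
          "### Intron ordinals", "",
          tabs["by_intron_ordinal"].to_markdown(index=False), ""]
    if dist is not None:
        L += ["## Upstream insertion distances (5'-UTR introns)", "",
              f"n={dist.n}; min {dist.min:.0f} bp, median {dist.median:.0f} bp, "
              f"max {dist.max:.0f} bp (Q1 {dist.q1:.0f}, Q3 {dist.q3:.0f})", ""]
    if gof is not None:
        L += ["## Intron-position goodness of fit", "",
              f"chi2 = {gof.chi2:.2f}, df = {gof.df}, P = {gof.p:.3g}", ""]
    L += ["## Splice-acceptor matrix", "",
          f"{metrics.get('pssm_n_windows', 0)} training windows; "
          f"max score {metrics.get('pssm_max_score', float('nan')):.2f}; "
          f"mean acceptor score {metrics.get('pssm_mean_acceptor_score', float('nan')):.2f} "
          f"vs mean random score {metrics.get('pssm_mean_random_score', float('nan')):.2f}",
          ""]
    return "\n".join(L)
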