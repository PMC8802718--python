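"""End-to-end orchestration: generate → preprocess → track → classify →
OPR / topics / factor analysis, with provenance and a machine-readable report.

A run is driven by a nested config dict (see ``default_run_config``); every
stage output embeds the SHA-256 hash of the canonicalized config so stale
artifacts are detected.  Rerunning with an identical config reproduces a
byte-identical ``report.json`` (all randomness is seeded from the config).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import factors as fa
from . import metrics, sentiment, synthetic, topics, tracking
from .config import (
    CorpusConfig,
    PanelConfig,
    VisitConfig,
    headline_corpus_config,
    headline_panel_config,
    headline_visit_config,
)
from .preprocess import tokenize_corpus

__all__ = ["PipelineError", "default_run_config", "config_hash", "run_all", "summarize"]

logger = logging.getLogger(__name__)

STAGES = ("corpus", "tracking", "sentiment", "opr", "topics", "panel", "visits")


class PipelineError(RuntimeError):
    pass


def default_run_config(seed: int = 0) -> dict:
    """Headline-trend run configuration with per-stage seeds derived from ``seed``."""
    return {
        "seed": seed,
        "out_dir": "out",
        "stages": {name: True for name in STAGES},
        "corpus": {"seed": seed},
        "tracking": {
            "batch_size": 15,
            "budget": 40,
            "threshold": 0.5,
            "strategy": "uncertainty",
            "seed": seed + 1,
            "n_seed_labels": 5,
        },
        "sentiment": {"seeds_per_class": 50, "seed": seed + 2},
        "opr": {"delta": 1.0, "always_smooth": False},
        "topics": {"n_topics": 10, "k": 5, "theta": 0.2, "batch_size": 256, "seed": seed + 3},
        "panel": {"seed": seed + 7},
        "visits": {"seed": seed + 4},
    }


def config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _tracking_seed_labels(
    posts: list[synthetic.Post], n_per_class: int, seed: int
) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    on = sorted(p.id for p in posts if p.on_topic)
    off = sorted(p.id for p in posts if not p.on_topic)
    labels: dict[str, int] = {}
    for pid in rng.choice(on, size=min(n_per_class, len(on)), replace=False):
        labels[str(pid)] = 1
    for pid in rng.choice(off, size=min(n_per_class, len(off)), replace=False):
        labels[str(pid)] = 0
    return labels


def headline_opr_trend(
    seed: int,
    posts_per_year: int = 2000,
    n_years: int = 10,
    delta: float = 1.0,
) -> dict:
    """Run corpus → tracking → sentiment → OPR in memory for one seed.

    Returns the yearly OPR series, its end-to-start trend ratio and the
    tracking/classification sizes.  This is the measurement behind the
    headline criticism-trend figure; all randomness derives from ``seed``.
    """
    ccfg = headline_corpus_config(seed=seed, posts_per_year=posts_per_year, n_years=n_years)
    posts = synthetic.gen_corpus(ccfg)
    tokenized = tokenize_corpus(posts, synthetic.tag_lexicon(ccfg))
    token_map = {tp.post_id: tp.tokens for tp in tokenized}
    truth_on = {p.id: int(p.on_topic) for p in posts}
    tcfg = tracking.TrackingConfig(seed=seed + 1)
    seeds = _tracking_seed_labels(posts, 5, tcfg.seed)
    on_ids, _, _ = tracking.track_topic(token_map, seeds, tcfg, truth=truth_on)
    selected = set(on_ids)
    sub = [tp for tp in tokenized if tp.post_id in selected]
    truth_sent = {p.id: p.sentiment for p in posts if p.sentiment is not None}
    scfg = sentiment.SentimentConfig()
    seed_labels = sentiment.stratified_seed_labels(
        sub, truth_sent, scfg.seeds_per_class, seed + 2
    )
    stance, _ = sentiment.classify_corpus(sub, seed_labels, scfg)
    timestamps = {p.id: p.timestamp for p in posts}
    series = metrics.opr_series(
        {pid: lab for pid, (lab, _) in stance.items()}, timestamps, delta=delta
    )
    return {
        "series": series,
        "trend_ratio": metrics.trend_ratio(series),
        "n_on_topic": len(on_ids),
        "n_posts": len(posts),
    }


def run_all(config: Mapping[str, Any], out_dir: str | Path | None = None) -> dict:
    """Execute the enabled stages in dependency order; returns the report bundle.

    A disabled upstream stage halts its dependents with a
    :class:`PipelineError` naming the missing artifact.
    """
    config = copy.deepcopy(dict(config))
    chash = config_hash(config)
    stages = config.get("stages", {})
    out_path = Path(out_dir if out_dir is not None else config.get("out_dir", "out"))
    out_path.mkdir(parents=True, exist_ok=True)

    bundle: dict[str, Any] = {
        "provenance": {
            "config_hash": chash,
            "seed": config.get("seed"),
            "stages": {k: bool(v) for k, v in stages.items()},
        }
    }

    posts = tokenized = None
    on_topic_ids: list[str] | None = None
    stance: dict[str, tuple[str, float]] | None = None

    if stages.get("corpus"):
        ccfg = headline_corpus_config(**config.get("corpus", {}))
        posts = synthetic.gen_corpus(ccfg)
        synthetic.write_posts_jsonl(posts, out_path / "posts.jsonl")
        tokenized = tokenize_corpus(posts, synthetic.tag_lexicon(ccfg))
        bundle["corpus"] = {"n_posts": len(posts), "config_hash": chash}

    if stages.get("tracking"):
        if posts is None or tokenized is None:
            raise PipelineError("tracking requires the corpus stage")
        tcfg_raw = dict(config.get("tracking", {}))
        n_seed = tcfg_raw.pop("n_seed_labels", 5)
        tcfg = tracking.TrackingConfig(**tcfg_raw)
        token_map = {tp.post_id: tp.tokens for tp in tokenized}
        truth = {p.id: int(p.on_topic) for p in posts}
        seeds = _tracking_seed_labels(posts, n_seed, tcfg.seed)
        on_topic_ids, _, state = tracking.track_topic(token_map, seeds, tcfg, truth=truth)
        bundle["tracking"] = {
            "n_on_topic": len(on_topic_ids),
            "n_labeled": len(state.labeled),
            "iterations": state.iteration,
            "config_hash": chash,
        }

    if stages.get("sentiment"):
        if on_topic_ids is None or tokenized is None or posts is None:
            raise PipelineError("sentiment requires the tracking stage")
        scfg_raw = dict(config.get("sentiment", {}))
        seed = scfg_raw.pop("seed", 0)
        per_class = scfg_raw.pop("seeds_per_class", 20)
        scfg = sentiment.SentimentConfig(seeds_per_class=per_class, **scfg_raw)
        selected = set(on_topic_ids)
        sub = [tp for tp in tokenized if tp.post_id in selected]
        truth_sent = {p.id: p.sentiment for p in posts if p.sentiment is not None}
        seed_labels = sentiment.stratified_seed_labels(sub, truth_sent, per_class, seed)
        stance, artifacts = sentiment.classify_corpus(sub, seed_labels, scfg)
        pd.DataFrame(
            [(pid, lab, score) for pid, (lab, score) in sorted(stance.items())],
            columns=["post_id", "stance", "score"],
        ).to_csv(out_path / "stances.csv", index=False)
        counts = pd.Series([lab for lab, _ in stance.values()]).value_counts().to_dict()
        bundle["sentiment"] = {"n_classified": len(stance), "counts": counts, "config_hash": chash}

    if stages.get("opr"):
        if stance is None or posts is None:
            raise PipelineError("opr requires the sentiment stage")
        ocfg = config.get("opr", {})
        timestamps = {p.id: p.timestamp for p in posts}
        series = metrics.opr_series(
            {pid: lab for pid, (lab, _) in stance.items()},
            timestamps,
            delta=ocfg.get("delta", 1.0),
            always_smooth=ocfg.get("always_smooth", False),
        )
        series.to_csv(out_path / "opr_series.csv", index=False)
        bundle["opr"] = {
            "series": series.to_dict(orient="records"),
            "trend_ratio": metrics.trend_ratio(series),
            "config_hash": chash,
        }

    if stages.get("topics"):
        if stance is None or tokenized is None:
            raise PipelineError("topics requires the sentiment stage")
        pcfg = config.get("topics", {})
        selected = {pid for pid in stance}
        sub = [tp for tp in tokenized if tp.post_id in selected]
        docs = [tp.tokens for tp in sub]
        model = topics.OnlineLda(
            n_topics=pcfg.get("n_topics", 10), seed=pcfg.get("seed", 0)
        ).fit(docs, batch_size=pcfg.get("batch_size", 256))
        report = {}
        edges = {}
        for pol in ("pos", "neg"):
            pol_docs = [tp.tokens for tp in sub if stance[tp.post_id][0] == pol]
            if not pol_docs:
                report[pol] = []
                edges[pol] = []
                continue
            report[pol] = topics.top_topics(model, pol_docs, k=pcfg.get("k", 5))
            W = topics.topic_cooccurrence(model, pol_docs, theta=pcfg.get("theta", 0.2))
            tops = [t["topic"] for t in report[pol]]
            edges[pol] = [
                {"topic_a": a, "topic_b": b, "weight": float(W[a, b])}
                for a in tops
                for b in tops
                if a < b
            ]
            pd.DataFrame(edges[pol]).to_csv(out_path / f"topic_edges_{pol}.csv", index=False)
        bundle["topics"] = {"top": report, "cooccurrence": edges, "config_hash": chash}

    if stages.get("panel"):
        pcfg = headline_panel_config(**config.get("panel", {}))
        panel = synthetic.gen_panel(pcfg)
        panel.to_csv(out_path / "panel.csv", index=False)
        table = fa.preprocess_panel(panel, pcfg.start_year, pcfg.end_year)
        fit = fa.lasso_cv(table.X, table.y, seed=config.get("panel", {}).get("seed", 0))
        fit.beta.rename("coefficient").to_csv(out_path / "lasso_coefficients.csv")
        fit.cv_curve.to_csv(out_path / "lasso_cv_curve.csv", index=False)
        disc, _ = fa.discretize(
            pd.concat([table.X, table.y_detrended.rename("visits")], axis=1)
        )
        bn = fa.learn_bn(disc)
        pd.DataFrame(bn.edges, columns=["from", "to"]).to_csv(
            out_path / "bn_edges.csv", index=False
        )
        blanket = sorted(fa.influential_factors(bn))
        (out_path / "bn_blanket.json").write_text(json.dumps(blanket))
        yearly = panel.groupby("year")["visits"].sum()
        strat = fa.stratified_visits(panel, "gdp")
        strat.to_csv(out_path / "stratified_gdp.csv", index=False)
        bundle["panel"] = {
            "n_rows": len(panel),
            "visits_by_year": {int(y): float(v) for y, v in yearly.items()},
            "visits_trend_ratio": metrics.trend_ratio(yearly.to_numpy()),
            "lasso": {
                "lambda": fit.lambda_,
                "coefficients": {k: float(v) for k, v in fit.beta.items()},
                "top_factors": fit.top_factors(2),
            },
            "bn_markov_blanket": blanket,
            "config_hash": chash,
        }

    if stages.get("visits"):
        vcfg = headline_visit_config(**config.get("visits", {}))
        records = synthetic.gen_visit_records(vcfg)
        records.to_csv(out_path / "visit_records.csv", index=False)
        hist, modal = fa.age_distribution(records["age"]) if len(records) else (
            pd.DataFrame(columns=["band", "count"]),
            "",
        )
        hist.to_csv(out_path / "age_histogram.csv", index=False)
        bundle["visits"] = {
            "n_records": len(records),
            "age_histogram": {row["band"]: int(row["count"]) for _, row in hist.iterrows()},
            "modal_band": modal,
            "config_hash": chash,
        }

    report_path = out_path / "report.json"
    report_path.write_text(json.dumps(bundle, sort_keys=True, indent=2, default=float))
    return bundle


def summarize(bundle: Mapping[str, Any], out_dir: str | Path) -> dict[str, Path]:
    """Render figures and tables from a report bundle.

    Produces (when the inputs exist): an OPR-vs-visits dual-axis figure, a
    coefficient bar chart, an age histogram and a topic table figure.
    Missing components are reported, not fatal.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    missing: list[str] = []

    if "opr" in bundle:
        series = pd.DataFrame(bundle["opr"]["series"])
        fig, ax1 = plt.subplots(figsize=(7, 4))
        ax1.plot(series["year"], series["opr"], "o-", color="tab:red", label="OPR")
        ax1.set_xlabel("year")
        ax1.set_ylabel("opinion polarity ratio", color="tab:red")
        if "panel" in bundle:
            visits = bundle["panel"]["visits_by_year"]
            ax2 = ax1.twinx()
            years = sorted(int(y) for y in visits)
            ax2.plot(years, [visits[y] for y in years], "s--", color="tab:blue", label="visits")
            ax2.set_ylabel("national visits", color="tab:blue")
        fig.tight_layout()
        p = out_path / "opr_vs_visits.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["opr_vs_visits"] = p
    else:
        missing.append("opr")

    if "panel" in bundle:
        coefs = pd.Series(bundle["panel"]["lasso"]["coefficients"]).sort_values()
        fig, ax = plt.subplots(figsize=(7, 7))
        ax.barh(coefs.index, coefs.values)
        ax.set_xlabel("impact coefficient (standardized factors, log visits)")
        fig.tight_layout()
        p = out_path / "lasso_coefficients.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["lasso_coefficients"] = p
    else:
        missing.append("panel")

    if "visits" in bundle:
        hist = bundle["visits"]["age_histogram"]
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.bar(list(hist.keys()), list(hist.values()))
        ax.set_xlabel("age band")
        ax.set_ylabel("visits")
        fig.tight_layout()
        p = out_path / "age_histogram.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["age_histogram"] = p
    else:
        missing.append("visits")

    if "topics" in bundle:
        fig, ax = plt.subplots(figsize=(9, 4))
        ax.axis("off")
        rows = []
        for pol in ("pos", "neg"):
            for t in bundle["topics"]["top"].get(pol, []):
                rows.append([pol, t["topic"], ", ".join(t["top_words"][:6])])
        if rows:
            table = ax.table(
                cellText=rows, colLabels=["polarity", "topic", "top words"], loc="center"
            )
            table.scale(1, 1.4)
        fig.tight_layout()
        p = out_path / "topic_tables.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["topic_tables"] = p
    else:
        missing.append("topics")

    if missing:
        logger.warning("summary omits missing components: %s", ", ".join(missing))
    written["missing"] = missing  # type: ignore[assignment]
    return written
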