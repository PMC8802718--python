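"""Configuration objects for the synthetic-data generators and the pipeline.

The shipped "headline-trend" configuration (``data/headline_trend.yaml``)
encodes the study conditions: a ten-year post stream whose yearly
negative/positive balance ramps log-linearly so the opinion-polarity ratio
rises 2.33-fold, and a 34-region panel whose national visit totals grow
2.41-fold over 2004-2014.  Calibration constants live in that file, not in
code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Sequence

import yaml

__all__ = [
    "ConfigError",
    "CorpusConfig",
    "PanelConfig",
    "VisitConfig",
    "load_headline_config",
    "headline_corpus_config",
    "headline_panel_config",
    "headline_visit_config",
]


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class CorpusConfig:
    """Parameters of the synthetic post-stream generator.

    ``sentiment_trend`` holds one ``(p_pos, p_neg, p_neutral)`` triple per
    year; each must sum to one.  Vocabulary sizes control the four pairwise
    disjoint token sets (topic entities, positive words, negative words,
    filler).  ``frac_on_topic`` is the marginal probability that a post
    belongs to the tracked topic.
    """

    n_years: int = 10
    start_year: int = 2004
    posts_per_year: int = 2000
    frac_on_topic: float = 0.25
    sentiment_trend: tuple[tuple[float, float, float], ...] | None = None
    n_entities: int = 120
    n_positive: int = 40
    n_negative: int = 40
    n_filler: int = 300
    emoticon_rate: float = 0.3
    punct_rate: float = 0.4
    opposite_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years <= 0 or self.posts_per_year < 0:
            raise ConfigError("n_years must be positive and posts_per_year non-negative")
        if not 0.0 <= self.frac_on_topic <= 1.0:
            raise ConfigError(f"frac_on_topic must lie in [0, 1], got {self.frac_on_topic}")
        for rate in (self.emoticon_rate, self.punct_rate, self.opposite_noise):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("per-post probabilities must lie in [0, 1]")
        if min(self.n_entities, self.n_positive, self.n_negative, self.n_filler) <= 0:
            raise ConfigError("vocabulary sizes must be positive")
        if self.sentiment_trend is not None:
            trend = tuple(tuple(float(p) for p in row) for row in self.sentiment_trend)
            if len(trend) != self.n_years:
                raise ConfigError(
                    f"sentiment_trend has {len(trend)} rows for {self.n_years} years"
                )
            for row in trend:
                if len(row) != 3 or any(p < 0 or p > 1 for p in row):
                    raise ConfigError(f"invalid proportion triple {row}")
                if abs(sum(row) - 1.0) > 1e-9:
                    raise ConfigError(f"proportions must sum to 1, got {row}")
            object.__setattr__(self, "sentiment_trend", trend)

    def trend(self) -> tuple[tuple[float, float, float], ...]:
        """Per-year sentiment proportions; uniform thirds when unset."""
        if self.sentiment_trend is not None:
            return self.sentiment_trend
        return tuple((1 / 3, 1 / 3, 1 / 3) for _ in range(self.n_years))

    def with_seed(self, seed: int) -> "CorpusConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PanelConfig:
    """Parameters of the synthetic region-year utilization panel.

    Log visits are a region baseline plus a deterministic yearly growth
    trend plus a sparse linear effect of the factor columns (``beta``) plus
    Gaussian noise.  Factors are persistent regional traits with a small
    yearly drift so the configured national growth dominates year totals.
    """

    n_regions: int = 34
    start_year: int = 2004
    end_year: int = 2014
    n_factors: int = 30
    beta: dict[str, float] = field(default_factory=lambda: {"gdp": 0.4, "education": 0.25})
    visits_growth: float = 2.41 ** 0.1
    noise_sd: float = 0.02
    region_sd: float = 0.2
    factor_drift: float = 0.3
    base_log_mean: float = 11.0
    normalize_totals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ConfigError("end_year before start_year")
        if self.n_regions <= 0:
            raise ConfigError("n_regions must be positive")
        if self.noise_sd < 0 or self.region_sd < 0 or self.factor_drift < 0:
            raise ConfigError("standard deviations must be non-negative")
        if len(self.beta) < 2:
            raise ConfigError("true beta must have support on at least 2 factors")
        if self.n_factors < len(self.beta):
            raise ConfigError(
                f"n_factors={self.n_factors} smaller than |support(beta)|={len(self.beta)}"
            )
        if self.visits_growth <= 0:
            raise ConfigError("visits_growth must be positive")

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def with_seed(self, seed: int) -> "PanelConfig":
        return replace(self, seed=seed)


#: default age mixture: dominant 25-35 band, secondary 0-8 band ("little
#: emperor" children), thinner mass elsewhere.  (low, high, weight), ages
#: drawn uniformly on the closed integer band.
DEFAULT_AGE_MIXTURE: tuple[tuple[int, int, float], ...] = (
    (25, 35, 0.32),
    (0, 8, 0.18),
    (9, 15, 0.06),
    (16, 24, 0.12),
    (36, 50, 0.16),
    (51, 65, 0.10),
    (66, 90, 0.06),
)


@dataclass(frozen=True)
class VisitConfig:
    """Parameters of the synthetic hospital visit-age records."""

    n_records: int = 50_000
    age_mixture: tuple[tuple[int, int, float], ...] = DEFAULT_AGE_MIXTURE
    start_year: int = 2004
    n_years: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ConfigError("n_records must be non-negative")
        mix = tuple((int(lo), int(hi), float(w)) for lo, hi, w in self.age_mixture)
        if any(w < 0 for _, _, w in mix):
            raise ConfigError("mixture weights must be non-negative")
        if any(lo < 0 or hi < lo for lo, hi, _ in mix):
            raise ConfigError("age bands must satisfy 0 <= low <= high")
        total = sum(w for _, _, w in mix)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mixture weights must sum to 1, got {total}")
        object.__setattr__(self, "age_mixture", mix)

    def with_seed(self, seed: int) -> "VisitConfig":
        return replace(self, seed=seed)


def load_headline_config() -> dict:
    """Parsed contents of the packaged headline-trend YAML."""
    ref = importlib.resources.files("opinionpulse.data") / "headline_trend.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def headline_corpus_config(seed: int = 0, **overrides) -> CorpusConfig:
    """Corpus config from the packaged calibration, with overrides.

    Shortening ``n_years`` keeps the first years of the calibrated trend
    (desk-scale runs still see the same early trajectory).
    """
    raw = dict(load_headline_config()["corpus"])
    raw["sentiment_trend"] = tuple(tuple(row) for row in raw["sentiment_trend"])
    raw.update(overrides)
    n_years = raw.get("n_years", len(raw["sentiment_trend"]))
    if "sentiment_trend" not in overrides and n_years < len(raw["sentiment_trend"]):
        raw["sentiment_trend"] = raw["sentiment_trend"][:n_years]
    return CorpusConfig(seed=seed, **raw)


def headline_panel_config(seed: int = 0, **overrides) -> PanelConfig:
    raw = dict(load_headline_config()["panel"])
    raw.update(overrides)
    return PanelConfig(seed=seed, **raw)


def headline_visit_config(seed: int = 0, **overrides) -> VisitConfig:
    raw = dict(load_headline_config()["visits"])
    raw.update(overrides)
    return VisitConfig(seed=seed, **raw)
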