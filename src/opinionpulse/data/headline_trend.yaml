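# Headline-trend study configuration.
# Yearly sentiment proportions follow a log-linear opinion-polarity-ratio ramp
# from 0.6 to 1.398 (a 2.33-fold rise over ten years, neutral share fixed at 0.30);
# panel visits grow 2.41-fold over 2004-2014 (growth = 2.41**(1/10) per year).
corpus:
  n_years: 10
  start_year: 2004
  posts_per_year: 2000
  frac_on_topic: 0.25
  sentiment_trend:
    - [0.437500, 0.262500, 0.300000]
    - [0.421909, 0.278091, 0.300000]
    - [0.406014, 0.293986, 0.300000]
    - [0.389878, 0.310122, 0.300000]
    - [0.373569, 0.326431, 0.300000]
    - [0.357156, 0.342844, 0.300000]
    - [0.340712, 0.359288, 0.300000]
    - [0.324309, 0.375691, 0.300000]
    - [0.308018, 0.391982, 0.300000]
    - [0.291910, 0.408090, 0.300000]
  n_entities: 120
  n_positive: 40
  n_negative: 40
  n_filler: 300
  emoticon_rate: 0.3
  punct_rate: 0.4
  opposite_noise: 0.1
panel:
  n_regions: 34
  start_year: 2004
  end_year: 2014
  n_factors: 30
  visits_growth: 1.091947
  noise_sd: 0.02
  region_sd: 0.2
  factor_drift: 0.3
  base_log_mean: 11.0
  normalize_totals: true
  beta:
    gdp: 0.4
    education: 0.25
visits:
  n_records: 50000
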