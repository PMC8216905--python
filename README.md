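# phenobee

Simulation and analysis pipeline for climate-chamber experiments on the
winter-to-spring phenology of an early flowering geophyte (*Crocus
sieberi*) and Western honey bee (*Apis mellifera*) colonies under crossed
temperature × photoperiod regimes.

Chamber studies of this kind ask whether plants and their pollinators read
the same seasonal cues: temperature regimes shift under climate warming
while photoperiod does not, so a warmed winter combined with an unchanged
(or higher-latitude) light schedule can desynchronize flowering from
colony development. `phenobee` provides, as a tested Python library:

* **scenario** — chamber temperature programs (a daily climatology averaged
  into 52 calendar weeks, a +4 °C warming offset, and a triangular daily
  cycle T(h) = w̄ − 3 + 0.5·h for h ≤ 12, mirrored after noon, so every
  day's hourly mean equals its weekly mean w̄), and photoperiod programs
  from NOAA solar sunrise/sunset at reference sites (Würzburg 49.8° N and
  Snåsa 64.25° N), with 1-h linear dawn/dusk ramps or constant darkness;
* **synthetic** — seeded generators for everything the analysis consumes:
  12-sensor comb-temperature telemetry on a 3-h grid with 0.5 °C logger
  quantization, brood episodes as low-amplitude ≥ 32 °C plateaus, colony
  death as exponential decay below 17 °C, discrete-time flowering hazards
  h(w) = 1 − exp(−h₀·e^{β_T·GDD(w) + β_P·L(w)}) driven by thermal sum and
  day length, plant heights, and daily hive weight changes;
* **detect** — the minimally invasive brood-rearing detector: per day and
  colony, select the warmest sensor; call a brood day when its maximum is
  ≥ 32 °C *and* its amplitude is ≤ 2 °C; brood onset is the first run of
  ≥ 3 consecutive brood days; an unrecovered drop to ≤ 17 °C censors the
  colony as dead/weak;
* **phenostats** — the statistical stage: Cox proportional-hazards models
  (Efron ties, sequential likelihood-ratio analysis of deviance) for
  flowering week and brood-onset day, binomial and quasibinomial (F-test)
  GLMs for flowering and brood-day proportions, a linear mixed model for
  plant height, a linear model for ln|mean daily weight change|,
  cross-species synchrony Cox models, and Tukey-adjusted contrasts of
  estimated marginal means;
* **io / cli** — CSV interchange with schema validation and a reproducible
  pipeline driver (`phenobee run --seed 1 --out DIR`) writing a manifest
  with per-file digests.

## Worked example

```sh
python examples/04_brood_detection.py
```

```
plan:     onset day 30, 25-day episode, death day 90
detected: onset day 30, death day 90
brood days 25 of 89 observed (fraction 0.281; days after death excluded)
```

A colony simulated with 0.2 °C sensor noise and 0.5 °C quantization is
recovered exactly: the detector finds brood onset on day 30 (the first of
three consecutive ≥ 32 °C, ≤ 2 °C-amplitude days), the death censor on
day 90, and counts 25 brood days among the 89 days before death.

```sh
python examples/05_phenology_models.py
```

```
== flowering_cox ==
                   term  statistic  df        p    test
            temperature   4.172497   1 0.041085 LR chi2
            photoperiod  16.967828   2 0.000207 LR chi2
temperature:photoperiod   0.790980   2 0.673350 LR chi2
```

On a seed-1 synthetic study the flowering Cox model recovers the effects
the generator encodes — warming and longer days advance flowering (p =
0.041 and p < 0.001), with no interaction — while the brood-onset model
finds no treatment pattern, matching the generator's treatment-independent
colony plans. The other examples build the temperature and light programs
and the full study bundle.

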