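# chronomove

Behaviour-based rhythmicity analysis for animal movement telemetry.

Free-ranging animals at polar latitudes spend months of the year without a
24 h light–dark cycle, which makes them a natural system for asking whether
behaviour is scheduled by a circadian clock, by shorter "interval-timer"
cycles of foraging and digestion, or not at all. `chronomove` implements
the full analysis chain used to answer that question from hourly GPS
collar data on a large Arctic ruminant:

1. **Track preprocessing** — an iterative speed filter removes physically
   impossible fixes; Euclidean step lengths, signed turning angles, and
   log-transformed hourly net displacement (`ln(d + 1)`) are derived.
2. **Behavioural states** — a hidden Markov model with zero-inflated
   gamma step lengths and von Mises turning angles (2–5 states, 3
   canonical: resting, foraging, transiting), fitted by direct numerical
   maximum likelihood with the scaled forward algorithm, decoded by
   forward–backward posteriors and Viterbi, and checked with one-step-ahead
   pseudo-residuals. Separate fits for the snow-covered and snow-free
   seasons.
3. **Periodicity** — Lomb–Scargle periodograms (tolerant of missed fixes)
   of each state-occupancy probability and of net displacement, normalized
   as raw power / (2 × total variance); peak significance by permutation
   (values shuffled over the fixed observation times). Morlet wavelet
   power spectra (1–256 h) with a white-noise bootstrap mask for
   exploratory epoch plots.
4. **Rhythm classification** — each individual-week (≥ 6 days of data) or
   individual-month (≥ 28 days) is assigned to *ultradian* (significant
   peak in [2, 18) h), *circadian* ([18, 36] h), *ultradian & circadian*
   (both), or *arrhythmic* (neither); when two significant peaks lie
   within 18 h of each other and the smaller is below one third of the
   larger's power, the smaller is rejected.
5. **Transitions** — the 4×4 Markov matrix of rhythm classes between
   consecutive windows, with individual-level bootstrap CIs.
6. **Environmental model** — a binomial GLMM (logit link, Laplace
   approximation; random intercepts for year and individual-within-year)
   of the rhythmic/arrhythmic outcome against scaled photoperiod,
   elevation, dense-vegetation use, snow depth and NDVI, plus bootstrap
   prediction curves and a growing-season (weeks 23–37) NDVI contrast
   between rhythmic and arrhythmic individuals.

Because no public muskox telemetry accompanies the analysis, the package
ships a first-class **synthetic-trajectory generator**: a
time-inhomogeneous three-state movement simulator whose transition
log-odds are forced by an ultradian (default 12 h) and a circadian (24 h)
oscillator with photoperiod-dependent seasonal amplitudes, plus
high-Arctic covariate curves (polar day/night photoperiod at 74.47° N,
NDVI, snow depth). Every fix carries its generating state, so each
downstream stage can be validated against ground truth.

## Worked example

```python
from datetime import date
from chronomove import PipelineConfig, SimulationConfig, run_pipeline, summarize_run

cfg = PipelineConfig(
    sim=SimulationConfig(n_individuals=8, start_date=date(2014, 1, 1),
                         end_date=date(2014, 12, 31),
                         summer_forced_fraction=0.25, seed=42),
    output_dir="run", n_restarts=2, n_perm=199, seed=42)
print(summarize_run(run_pipeline(cfg)))
```

On this simulated high-Arctic year the report prints (abridged):

```
rhythm classes (% of windows):
  foraging: arrhythmic 16.8%, ultradian_circadian 17.8%, circadian 15.9%, ultradian 49.5%
  resting: arrhythmic 13.0%, ultradian_circadian 14.2%, circadian 19.5%, ultradian 53.4%
  ...
probability of remaining in the same rhythm:
  foraging: arrhythmic 0.57, ultradian_circadian 0.40, circadian 0.45, ultradian 0.82
  ...
GLMM fixed-effect signs (p < 0.05 starred):
  foraging: photoperiod_h -*, elev_m -, dense_veg -, snow_m -, ndvi -*
  resting: photoperiod_h -*, elev_m -, dense_veg +, snow_m -, ndvi -
  transit: photoperiod_h +, elev_m -, dense_veg +, snow_m +, ndvi +
  displacement: photoperiod_h -*, elev_m -, dense_veg +, snow_m -, ndvi -
```

Reading this: foraging and resting behaviour is dominantly ultradian
(~12 h cycles of feeding and rumination), the ultradian class is sticky
(P ≈ 0.8 of remaining in it week to week), and the probability of being
rhythmic at all declines significantly with photoperiod — rhythmicity
collapses under the continuous light of mid-summer — exactly the structure
the generator planted. The same chain runs on real telemetry via
`PipelineConfig(input_csv="tracks.csv")` or the CLI:

```bash
chronomove run-all --seed 42 --out run
chronomove report run
```

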