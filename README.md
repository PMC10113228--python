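# batemerge

Weather-driven and residual spring emergence of hibernating bats, from
hourly activity counts at hibernaculum entrances.

Bats overwintering in caves and abandoned mines are largely cut off from
surface weather, yet their spring emergence tracks it. This package
separates the two drivers of hourly flight activity at the entrance of a
hibernaculum — measurable weather triggers and a residual, possibly
intrinsic seasonal motivation — and quantifies each species' emergence
timing and synchronization. It is written for ecologists analysing
light-barrier / camera-trap event streams, and for anyone who wants a
self-contained, fully testable reimplementation of this style of
phenology analysis: a synthetic-data module generates event streams and
weather with the exact statistical structure the analysis assumes, so
every stage runs and is validated without any field data.

## The model

Hourly movement counts $Y_k$ per species and site follow a generalized
additive Poisson model (GAPM):

$$Y_k \sim \mathrm{Poisson}(\mu_k), \qquad \log(\mu_k) = \alpha + site_k
+ \beta_1 T_{S,k} + \beta_2 T_{A,k} + \beta_3 AP_k + \beta_4 APT_k
+ \beta_5 WS_k + \beta_6 PR_k + \beta_7 CC_k
+ f_1(ST_k) + f_2(DOY_k) + f_3(ST_k, DOY_k)$$

with soil temperature $T_S$ (20 cm depth, °C), air temperature $T_A$
(°C), air pressure $AP$ (hPa), air-pressure trend
$APT_t = AP_{t+1} - AP_{t-1}$, wind speed $WS$ (m/s), precipitation $PR$
(mm) and cloud cover $CC$ (eighths) as linear terms; a site factor
(treatment coding, reference Mayen-Mauerstollen); and cyclic cubic
regression splines for the diel cycle in *sun time* $ST \in [-1, 1]$
(sunset = 0, sunrise = ±1, period 2), for the annual cycle in day of
year $DOY$ (January 1 = day 0, analysis window up to day 136), and an
optional main-effects-excluded tensor-product interaction. The response
is the *minimum* of the 3-hour moving averages of hourly entries and
exits, a robustification against one-way bulk movements; it is
non-integer, so the Poisson deviance is used as a quasi-likelihood.
Penalized IRLS fits the model; GCV chooses the smoothing parameters.

Downstream of the fit:

* **Residual activity** — the partial effect $f_2(DOY)$ on the link
  scale: seasonal activity not explained by weather, site or the diel
  cycle. Species are ranked by its median absolute value and partitioned
  into high/medium/low residual-activity groups (HRA/MRA/LRA) via
  Kruskal–Wallis + pairwise Mann–Whitney tests with Bonferroni
  correction and a compact letter display.
* **Emergence phenology** — daily full-model predicted activity defines
  a weight distribution over days; its weighted median is the emergence
  timing and its interquartile range (IQR, days holding the middle 50 %
  of activity) measures synchronization. Cross-species OLS regressions
  relate residual activity, timing and synchronization.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data and write their tables under `results/`:

```sh
python analysis/01_simulate_dataset.py   # weather + event streams, 5 sites
python analysis/02_preprocess.py         # hourly model frame
python analysis/03_fit_models.py         # one GAPM per species
python analysis/04_residual_groups.py    # residual activity, HRA/MRA/LRA
python analysis/05_emergence.py          # timing + synchronization
python analysis/06_validation.py         # recovery/calibration studies
```

Simulation truths are the published coefficient presets for six Central
European species / species pairs (e.g. $\beta_{T_A} = 0.173$ for
*M. myotis*), with intercepts calibrated so event volumes match the
published photo totals. One season, five sites gives, e.g.:

```
M_bechsteinii            n=  9861  deviance explained 0.839  beta_TA +0.184***
M_myotis                 n= 16435  deviance explained 0.817  beta_TA +0.207***
P_auritus_austriacus     n= 16435  deviance explained 0.435  beta_TA +0.166***
```

— the air-temperature effect is recovered near its generative value and
deviance explained spans the range typical of this analysis. The
emergence table orders the species by timing and synchronization:

```
              species  median_doy        iqr
 P_auritus_austriacus   89.350009  45.977971   # early, diffuse
        M_daubentonii   96.839820  39.872525
          M_nattereri   97.890219  44.436976
             M_myotis  106.587684  29.838364
M_mystacinus_brandtii  109.311231  13.806705
        M_bechsteinii  109.736087   4.281429   # late, highly synchronized
```

*M. bechsteinii* — the forest specialist whose prey appears only after
leaf-out — emerges last and most synchronously and tops the residual-
activity ranking (HRA: activity driven by season, not weather), while
the *Plecotus* pair, active in winter and mating in spring, is early and
diffuse with weather-bound activity. The regression of IQR on median
DOY explains ~80 % of the variance here (later species are more
synchronized), matching the qualitative finding of the field study this
design emulates.

## Library layout

| module | contents |
| --- | --- |
| `batemerge.config` | sites, species presets, generative truths |
| `batemerge.weather` / `.solar` | synthetic hourly weather; sunrise/sunset |
| `batemerge.simulate` | event streams and model frames from the generative model; gap injection |
| `batemerge.preprocess` | hourly aggregation, 3-h smoothing, min response, APT, sun time, model frame |
| `batemerge.splines` | cyclic cubic regression splines, penalties, constraints, tensor products |
| `batemerge.gapm` | penalized IRLS, GCV, Wald/χ² inference, prediction |
| `batemerge.residuals` | residual activity, ranking, letter display, HRA/MRA/LRA |
| `batemerge.emergence` | weighted quantiles, emergence summaries, cross-species regressions |
| `batemerge.experiments` | recovery/calibration simulation studies |
| `batemerge.io` / `.pipeline` / `.cli` | CSV formats, model bundles, end-to-end pipeline, `batemerge` CLI |

A `batemerge` console script exposes `simulate`, `preprocess`, `fit`,
`residuals`, `emergence` and `run` (YAML-configured end-to-end pipeline;
`run` without arguments executes a small bundled demo). Exit codes:
0 ok, 2 config error, 3 data error, 4 numeric failure.

See `docs/methods.md` for the statistical details, default parameters
and known limitations.
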