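# soiltrial

Soil-quality and yield-sustainability analysis for long-term fertilization
trials, built around the workflow of a 10-year randomized-block experiment
on a continuous (single-crop) cotton system: five fertilization regimes —
no fertilizer (CK), chemical fertilizer only (CF), and three blends
substituting 25 / 50 / 75 % of the fertilizer nitrogen with organic manure
(M1 / M2 / M3) — in six replicate blocks, with seed-cotton yield recorded
every year and a final-year panel of 12 soil indicators (bulk density, pH,
organic matter, total N, NH₄-N, NO₃-N, alkali-hydrolyzable N, available P,
available K, urease, catalase, alkaline phosphatase).

It is written for agronomists and soil scientists who want the standard
composite-index analysis of such trials as tested, scriptable code rather
than a spreadsheet: a soil quality index with PCA-communality weights, a
sustainability index for the yield series, and the inferential layer that
usually accompanies them (ANOVA with significance letters, starred
correlation matrices, random-forest importance, index-on-index regression).

## The indices

**Soil Quality Index (SQI).** Each indicator *Xᵢ* is scored onto [0, 1]
by direction-aware min-max scaling,

    Sᵢ = (Xᵢ − Xmin) / (Xmax − Xmin)      ("more is better")
    Sᵢ = (Xmax − Xᵢ) / (Xmax − Xmin)      ("less is better")

with the bounds taken over all plots jointly. The indicators are then
standardized and a principal-component analysis of their correlation
matrix is used to extract each indicator's *communality* cᵢ — the variance
captured by the retained components (Kaiser rule, eigenvalue ≥ 1, by
default). Weights are communality shares, Wᵢ = cᵢ / Σⱼ cⱼ, so Σ Wᵢ = 1, and

    SQI = Σᵢ Wᵢ · Sᵢ   ∈ [0, 1].

**Sustainable Yield Index (SYI).** For a plot's multi-year yield series,

    SYI = (Ȳ − σ) / Ymax,

where Ȳ is the mean yield, σ its standard deviation (sample convention by
default) and Ymax the highest yield. A high, stable series approaches 1;
SYI is computed per plot so it can be analyzed across replicates like any
other response.

Because raw plot-level data from such trials are rarely published, the
package ships a first-class synthetic generator
(`soiltrial.synthetic`) that emulates the trial design — block effects,
per-treatment yield trends, an optional single-year yield shock, and a
correlated indicator panel anchored to published treatment means and
percent changes — so the entire pipeline is reproducible end-to-end from
one seed.

## Worked example

```python
import soiltrial as st

config = st.default_config(seed=1)
trial = st.generate_trial(config)          # 30 plots × 10 years + soil panel

sqi = st.sqi_pipeline(trial)               # scores -> weights -> SQI
syi = st.per_treatment_syi(trial)
_, mean_yield = st.mean_annual_yield(trial)

merged = sqi.per_plot.merge(syi.per_plot[["plot_id", "syi"]], on="plot_id")
fit = st.fit_linear(merged["sqi"], merged["syi"])
letters = st.pairwise_letters(merged["sqi"], merged["treatment"])
```

which prints (see the docstrings for the full snippet):

```
Treatment means:
           yield_kg_ha    SQI    SYI
treatment
CK              3845.0  0.103  0.867
CF              6097.0  0.423  0.901
M1              6582.0  0.853  0.970
M2              6354.0  0.709  0.973
M3              6211.0  0.543  0.939

SYI = 0.14963 * SQI + 0.85094  (R^2 = 0.888, p = 7.64e-15)
SQI letters: {'M1': 'a', 'M2': 'b', 'M3': 'c', 'CF': 'd', 'CK': 'e'}
```

Read: every fertilized regime outyields the unfertilized control; the
25 %-organic blend (M1) has the best soil quality and the highest mean
yield; all five SQI means differ pairwise at α = 0.05 (distinct letters);
and soil quality is strongly, positively coupled to yield sustainability
(R² ≈ 0.89 across the 30 plots). Enabling the generator's 2019 yield
shock (`shock_enabled=True`) reproduces the situation where a single bad
year drops M1's SYI below M2's despite M1's higher mean yield.

## Command line

The same pipeline runs from a shell, with resumable per-stage
subcommands and a checksummed run manifest:

```sh
soiltrial run --seed 1 --out results/run1        # full pipeline
soiltrial stats --out results/run1 --config my.yaml   # rerun one stage
```

Artifacts are plain CSV (trial tables, scores, weights, indices, ANOVA
summary, letters, correlation matrices, importance tables, regression
summary) plus a markdown report; two runs from the same master seed are
byte-identical.

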