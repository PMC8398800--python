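# outlethei

Diet-quality scoring of 24-hour dietary recall data by **food outlet** —
where each reported food was obtained (grocery and convenience stores,
K–12 school cafeterias, full-service restaurants, quick-service
restaurants) — using the **Healthy Eating Index 2015 (HEI-2015)** with the
**population ratio method**, plus complex-survey variance via Fay-adjusted
balanced repeated replication (BRR).

It is aimed at nutrition epidemiologists working with What We Eat in
America–style recall microdata (item-level foods linked to USDA food
pattern equivalents), and at anyone who needs to score an arbitrary
weighted mix of foods against federal dietary guidance.

## The statistic

The HEI-2015 has 13 components, each a *density* — an amount relative to
energy. Nine adequacy components reward consumption (e.g. total fruits,
cup-eq per 1000 kcal; whole grains, oz-eq per 1000 kcal; the fatty-acid
ratio (MUFA+PUFA)/SFA) and four moderation components penalize it
(refined grains; sodium, g per 1000 kcal; added sugars and saturated fat
as percent of energy). Each density *d* is scored piecewise-linearly
between a zero-score cut-point *z* and a full-score cut-point *m*:

    adequacy:    score = max_pts · clamp((d − z) / (m − z), 0, 1)
    moderation:  score = max_pts · clamp((z − d) / (z − m), 0, 1)

and the 13 maxima sum to 100. A group of foods is scored with the
population ratio method: weighted component totals and the weighted
energy total are accumulated over **all** items in the group first,

    d_group = (Σᵢ wᵢ xᵢ) / (Σᵢ wᵢ eᵢ / 1000),

and the single ratio is scored — not the mean of per-person scores, which
is a biased estimate of a population's mean diet quality.

Standard errors of any group statistic (scores, outlet contrasts,
cross-cycle linear trend slopes) come from balanced repeated replication
over the masked two-PSU-per-stratum design with Fay's coefficient
k = 0.3: replicate weights multiply one PSU per stratum by 1.7 and the
other by 0.3 following Hadamard-matrix sign patterns, and

    SE² = (1 / (R(1−k)²)) Σᵣ (θᵣ − θ̂)².

## Worked example

Generate a synthetic recall population with known outlet-specific truth,
tabulate outlets, and score each outlet:

```sh
outlethei synth --out demo --n 400 --seed 3
outlethei tabulate --respondents demo/respondents.csv --items demo/items.csv
outlethei score --respondents demo/respondents.csv --items demo/items.csv --out demo/scores.csv
outlethei radar --respondents demo/respondents.csv --items demo/items.csv --out demo/radar.png
```

The score report (`demo/scores.csv`) reads:

```
group,total,total_fruits,whole_fruits,...,saturated_fats,total_se,grade
store,62.37,3.55,5.0,...,6.12,,D
school,64.27,5.0,4.99,...,5.89,,D
full_service,51.19,0.48,0.54,...,9.11,,F
quick_service,40.03,0.66,0.86,...,7.59,,F
all_outlets,57.84,2.9,3.93,...,6.61,,F
```

Each row is one outlet's population-ratio HEI-2015 total (of 100), its 13
component scores, and a letter grade (≥90% of maximum "A" down to <60%
"F"). Here schools and stores earn a "D" while both restaurant types earn
an "F" — the generator's default truth was configured to resemble recent
national estimates, and the pipeline recovers it from the simulated
microdata. The same functions accept real survey files (CSV or SAS
transport) through `outlethei.recall_io`, with per-cycle column names
supplied in a component dictionary file.

Library use mirrors the CLI:

```python
from outlethei import synthetic_data, outlet_mapping, hei_engine, survey_stats

config = synthetic_data.demo_config(n_respondents=2000, seed=0)
respondents, items = synthetic_data.generate(config)
standards = hei_engine.load_standards()
store = hei_engine.score_group(
    outlet_mapping.select_group(items, "store"), respondents, standards, "store"
)
replicates = survey_stats.build_replicates(respondents, fay_k=0.3)
fn = hei_engine.make_group_score_fn(items, respondents, standards)
contrast = survey_stats.pairwise_contrast(fn, None, replicates, ("store", "quick_service"))
```

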