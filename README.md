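# carescape

Layout, accessibility and demand analysis for community elder-care
facilities.

Urban planners and public-health researchers studying community-based care
for older adults face three linked questions: **where** facilities sit
(are they clustered or evenly spread?), **who can reach them** (how does
access decay with walking distance?), and **what residents actually want**
(how do care needs differ by housing type, price tier, income, education
and self-care ability?). `carescape` implements the full analysis chain
for such a study, driven by a seeded synthetic survey generator so every
stage is testable end to end without restricted microdata.

## What it computes

**Facility layout.** The Clark–Evans nearest-neighbor index

    NNI = (1/n) Σᵢ min_{j≠i} d_ij  /  0.5 √(A/n)

with its z test (NNI < 1 clustered, ≈ 1 random, > 1 uniform), and planar
kernel density surfaces `f(c) = 1/(n h²) Σᵢ K(‖c − cᵢ‖/h)` written as
ASCII grid rasters.

**Accessibility.** Two-step floating catchment area scores. The improved
variant weights each origin–destination pair with a truncated Gaussian
decay `w(d) = (e^{−(d/d₀)²/2} − e^{−1/2}) / (1 − e^{−1/2})`, normalizes
each community's weights across reachable facilities, then computes
supply–demand ratios `R_j = S_j / Σ_k ŵ_kj D_k` and scores
`A_i = Σ_j ŵ_ij R_j`. Unlike the classic form, this conserves supply:
`Σᵢ Dᵢ Aᵢ = Σⱼ Sⱼ` over facilities that serve anyone.

**Survey psychometrics.** Cronbach's α, corrected item-total
correlations, the KMO sampling-adequacy measure and Bartlett's sphericity
test, per primary indicator (life care, medical security, cultural &
entertainment — 4 + 3 + 4 Likert items).

**Demand differentiation.** Item/indicator means and walking-time
proportions, K-means tiering of commercial housing prices, one-way ANOVA
across residential types or price tiers, and logistic regression of binary
demand indicators on ordinal attributes reported as odds ratios.

## Worked example

```bash
$ carescape simulate --seed 42 --out demo
wrote 20 communities, 172 residential areas, 30 facilities, 447 survey rows to demo

$ carescape psych report --survey demo/survey.csv --out demo/rel.csv
life_care: alpha=0.793 kmo=0.792 bartlett_p=0.0000 (n=447)
medical_security: alpha=0.791 kmo=0.706 bartlett_p=0.0000 (n=447)
cultural_entertainment: alpha=0.743 kmo=0.770 bartlett_p=0.0000 (n=447)

$ carescape demand summary --survey demo/survey.csv
life_care: 2.73
medical_security: 2.88
cultural_entertainment: 3.45
overall: 3.03

$ carescape layout nni --input demo/facilities.geojson --area 1.0
{
  "nni": 0.37112743103412155,
  ...
  "classification": "clustered"
}

$ carescape access run --supplies demo/facilities.geojson \
      --demands demo/communities.geojson --d0 0.25 --out demo/acc.csv
wrote demo/acc.csv (mean accessibility 0.155366)
```

Reading the output: all three scales clear the conventional α ≥ 0.7
reliability bar and KMO ≥ 0.7 adequacy bar, so the 11-item battery hangs
together. Mean demand is moderate overall (3.03 on the 1–5 scale) and
highest for cultural & entertainment services. The default facility layout
is strongly clustered (NNI 0.37, z ≈ −6.6), and the mean accessibility of
0.155 is the average number of facility capacity units available per older
resident within the 0.25-unit catchment.

`carescape report --seed 42 --out demo` runs every stage and writes a
consolidated `study_report.json`; the same functionality is available as a
library (`carescape.generate_study`, `carescape.improved_2sfca`,
`carescape.scale_report`, `carescape.attribute_logistic`, ...).

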