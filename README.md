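# clical

Categorical risk-signature analysis of **time to relapse (TTR)** after
stereotactic body radiotherapy (SBRT) of colorectal-cancer metastases.

Patients with metastatic colorectal cancer differ widely in how long SBRT
keeps them relapse-free. This package implements, as a tested and replayable
pipeline, the clinical categorical scoring approach used to stratify such
patients before treatment:

1. **Radiobiology** — prescriptions are compared on the biologically
   effective dose scale, `BED = n·d·(1 + d/(α/β))` with α/β = 10 Gy; a
   course is *curative in intent* iff every treated lesion receives
   ≥ 95 Gy BED₁₀ and the whole active tumour burden is ablated.
2. **Survival statistics** — Kaplan–Meier `S(t) = Π (1 − dᵢ/nᵢ)`,
   Nelson–Aalen `H(t) = Σ dᵢ/nᵢ`, Greenwood confidence intervals and the
   k-group log-rank test, implemented from first principles (lifelines is
   used only as an independent oracle in the test suite).
3. **Cut-point search** — each clinical variable (age, performance status,
   number of CRC primaries, CEA, number of active metastases) is
   dichotomised or trichotomised at the split maximising the log-rank χ²
   for TTR, under a minimum-group-size constraint; variables significant at
   p ≤ 0.05 enter the score.
4. **Scoring and signatures** — each selected variable contributes an
   integer sub-score (1 = greatest risk); the patient's score is the mean
   of sub-scores (grid 1.0 … 2.2 under the reference scheme of four
   dichotomies + one trichotomy). Scores are partitioned into the largest
   number of contiguous *signature* groups whose adjacent pairs differ
   significantly by log-rank; signature I (lowest scores) marks the
   smallest benefit from SBRT.
5. **Synthetic cohorts** — because no patient-level data are published, a
   calibrated generator reproduces the study cohort's marginals (n = 85,
   median age 69, 76 % lung-only, 75 % of lesions at 17 Gy × 3, …) with a
   planted proportional-hazards relapse process (median TTR ≈ 7.3 months,
   ≈ 90 % relapsing) and 6 records with a missing score variable.

## Worked example

`examples/` contains one short script per capability. For instance
`python examples/04_scores_and_signatures.py` scores a synthetic
study-size cohort and prints:

```
79 of 85 patients scored (6 excluded for missing data)
score distribution: {1.4: 5, 1.6: 11, 1.8: 23, 2.0: 22, 2.2: 18}

4 signature groups (I = smallest benefit):
  signature I    scores 1.4–1.4  n = 5   median TTR = 0.8 months
  signature II   scores 1.6–1.8  n = 34  median TTR = 5.6 months
  signature III  scores 2.0–2.0  n = 22  median TTR = 10.3 months
  signature IV   scores 2.2–2.2  n = 18  median TTR = 28.6 months
  adjacent separation: chi2 = 13.65, p = 0.000221
  adjacent separation: chi2 = 5.30, p = 0.0213
  adjacent separation: chi2 = 4.42, p = 0.0356
```

Six patients are excluded because a score variable is missing; the
remaining 79 fall on the score grid, and four signature groups emerge with
monotonically increasing median relapse-free time — the highest-scoring
group stays relapse-free far longer than the lowest.

The same analysis runs end-to-end from the shell, writing every table plus
a manifest with stage counts and input hashes:

```sh
clical run --seed 11 --out my-run        # simulate → screen → score → report
clical bed --n 3 --d 17                  # BED = 137.7 Gy (displayed 138 Gy)
```

Re-running with the same seed reproduces every output byte-for-byte.

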