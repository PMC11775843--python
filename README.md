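# endotyper

Unsupervised identification of **hypotension endotypes** from continuous
haemodynamic monitoring data.

Intraoperative and ICU hypotension (mean arterial pressure, MAP, below
65 mmHg for at least one minute) is a final common pathway of very
different circulatory failures — vasodilation, hypovolaemia, depressed
myocardial contractility, bradycardia — that call for different causal
treatments. Given 20-second averaged haemodynamic series, this package:

1. **detects hypotensive episodes** (maximal runs of MAP <65 mmHg lasting
   ≥1 min on the 20-s grid) plus the contiguous "preceding" points with
   65 ≤ MAP < 72 mmHg immediately before each episode;
2. **derives and normalizes** the four clustering variables — stroke
   volume index (SVI), heart rate (HR), systemic vascular resistance index
   (SVRI = 80·(MAP − CVP)/CI with CVP assumed 5 mmHg, CI = SVI·HR/1000) and
   stroke volume variation (SVV) — each z-scored to mean 0, sd 1;
3. **embeds** the normalized points into a 2-dimensional latent space with
   an autoencoder;
4. **clusters** the latent points with a full-covariance Gaussian mixture
   model fitted by EM, choosing the number of clusters by the
   Calinski–Harabasz index (higher = better) cross-checked with the
   Davies–Bouldin index (lower = better), with k-means as a sensitivity
   method;
5. **labels** the clusters physiologically (lowest-HR cluster →
   bradycardia; lowest-SVRI of the rest → vasodilation; the remaining pair
   split by HR into myocardial depression and hypovolaemia) and reports
   per-point **posterior endotype probabilities** P(endotype | point) from
   the mixture;
6. **validates correspondence** of endotypes across datasets/models with
   the closed-form Gaussian Kullback–Leibler divergence

   KL(P‖Q) = ½ [tr(Σ_Q⁻¹Σ_P) + (μ_Q−μ_P)ᵀΣ_Q⁻¹(μ_Q−μ_P) − d + ln(det Σ_Q/det Σ_P)].

Because clinical monitoring datasets are proprietary, the package ships a
first-class **synthetic cohort generator** that emulates the study design:
per-patient MAP trajectories with well-formed episodes, and four planted
endotypes whose (SVI, HR, SVRI, SVV) distributions follow the published
per-endotype means and standard deviations, with ground-truth labels for
validation.

## Worked example

`examples/03_fit_endotypes.py` generates a 60-patient synthetic cohort,
embeds and clusters it, and prints (desk-scale settings, under a minute):

```
patients: 60, analysis points: 8090 (5900 hypotensive, 2190 preceding)

cluster-count scan (CH high = good, DB low = good):
 k      ch   db
 2 4323.24 1.12
 3 5690.91 0.95
 4 5197.05 0.87
 5 5091.79 0.91
 6 5736.46 0.94
scan winner: k = 6 (index agreement: False)

four-component endotype summary (original units):
             endotype    n  share  svi_mean  hr_mean  svri_mean  svv_mean
         vasodilation 2320   0.29     49.86    83.36    1217.28      6.80
myocardial_depression 1014   0.13     31.54    62.73    2769.22     18.72
          bradycardia 1145   0.14     42.91    54.77    2438.39      9.03
         hypovolaemia 3611   0.45     33.32    82.20    1540.87     15.42
```

Reading the output: the Davies-Bouldin index bottoms at k = 4 while the
Calinski-Harabasz index is noisy at this small scale (on marginal-moment
emulations the planted clusters overlap strongly - see `docs/methods.md`);
the four-component summary nevertheless recovers the planted haemodynamic
signatures - the vasodilation cluster has the lowest SVRI (~1217, low
afterload) with preserved SVI, bradycardia a mean HR ~55 beats/min,
hypovolaemia low SVI with high SVV (preload-responsive) - and the shares
approximate the planted mixing weights (34.9 / 32.1 / 22.4 / 10.6 %).

The `examples/` directory holds one short script per capability:
simulation, episode detection, fitting, applying a frozen model to a new
cohort, and KL-divergence comparison. A thin CLI mirrors the pipeline
stages (`endotyper simulate|detect|fit|apply|compare|report`).

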