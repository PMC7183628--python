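# somnonet

Effective-connectivity and small-world network analysis of sleep EEG, with
a synthetic polysomnography cohort generator.

Sleep-network studies ask how the brain's large-scale organization differs
between vigilance states and between groups — for example, whether women's
REM-sleep networks are less small-world-like than men's, and whether that
deviation tracks subclinical depressive symptoms.  somnonet implements the
full analysis chain such a study needs, for researchers working with
stage-scored multi-channel polysomnography:

1. **Epoching** — from a raw 19-channel 10-20 recording, a hypnogram and an
   artifact mask, select the first three artifact-free 20-s epochs of each
   analysed stage (pre-onset wake, stages 3/4, REM) and split them into the
   twelve 5-s analysis segments, with a spectral-power homogeneity report.
2. **Connectivity** — fit one multivariate autoregressive (MVAR) model per
   subject x stage by multi-trial pooling and compute the 19 x 19 directed
   Granger-causality matrix, conditional on the remaining channels:
   `F(j -> i | rest) = ln(Sigma'_ii / Sigma_ii)`, the log ratio of reduced-
   to full-model innovation variances; plus Geweke's spectral decomposition
   `f(j -> i | rest)(lambda)` and its band integrals for the delta
   (0.25-3 Hz), theta (3-8), alpha (8-12), sigma (12-16) and beta
   (16-32 Hz) bands.  The frequency average over [0, Nyquist] reproduces
   the time-domain value (checked and reported for every matrix).
3. **Network metrics** — threshold each matrix at fixed density (0.2) and
   compute the small-world coefficient
   `omega = mean(L_rand)/L - C/mean(C_latt)` against degree-preserving
   random and lattice surrogate ensembles; omega is bounded on [-1, 1],
   ~0 small-world, > 0 random-like, < 0 lattice-like.
4. **Statistics** — median (P25-P75) summaries, two-sample Wilcoxon
   rank-sum tests with Bonferroni correction, and Spearman correlations of
   sex and BDI-13 depression scores with the network metrics, emitted as
   four report tables.
5. **Synthetic cohorts** — because polysomnographic recordings are rarely
   shareable, a seeded generator produces stage-labelled EEG from known
   directed coupling graphs (Watts-Strogatz-style, with stage-typical
   oscillatory dynamics), including a 28-man / 16-woman cohort in which
   women's REM coupling graphs are more randomly rewired (larger omega) and
   women's BDI scores are rank-coupled to their REM topology.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Simulate two subjects, run the REM branch of the pipeline, and reduce each
connectivity matrix to its small-world coefficient:

```python
from somnonet import (CohortConfig, MvgcSettings, connectivity_per_subject,
                      select_clean_epochs, split_epochs, small_world_coefficient)
from somnonet.synth import draw_subjects, build_recording

cfg = CohortConfig(n_men=1, n_women=1, stages=("REM",), epochs_per_stage=4,
                   artifact_fraction=0.0, seed=7)
for subject in draw_subjects(cfg):
    rec, hyp, mask = build_recording(subject, cfg)
    epochs = select_clean_epochs(rec, hyp, mask, "REM")
    es = split_epochs(epochs, subject_id=subject.subject_id)
    conn = connectivity_per_subject({"REM": es}, MvgcSettings(order=3, n_freqs=512),
                                    subject_id=subject.subject_id)
    tm = conn.matrices["REM"]["time"]
    nm = small_world_coefficient(tm, density=0.2, n_surrogates=20, seed=cfg.seed)
    rep = conn.integration["REM"]
    print(f"{subject.subject_id} ({subject.sex}, BDI {subject.bdi}): "
          f"mean F = {tm.values[tm.values > 0].mean():.4f}, "
          f"integration max rel err = {rep.max_rel_diff:.2e}, "
          f"C = {nm.C:.3f}, L = {nm.L:.3f}, omega = {nm.swc:.3f}")
```

Output:

```
M01 (M, BDI 1): mean F = 0.0033, integration max rel err = 2.47e-13, C = 0.481, L = 2.988, omega = -0.254
F01 (F, BDI 2): mean F = 0.0032, integration max rel err = 1.58e-13, C = 0.353, L = 2.491, omega = 0.011
```

Reading it: each subject's REM EEG was reduced to a 19 x 19 directed
Granger-causality matrix (mean positive causality ~0.003 natural-log
units); the spectral decomposition integrates back to the time-domain
matrix to ~1e-13, confirming internal consistency; and the thresholded
graph of the man (whose REM coupling graph was generated nearly
lattice-like, rewiring ~0.05) has higher clustering, longer paths and a
clearly negative omega, while the woman's more randomly rewired REM network
sits near the small-world point with a higher omega — the group-level
pattern the cohort statistics then test.

The same chain is available from the shell:

```sh
somnonet run --config examples/demo.yaml --out results_demo --seed 42
somnonet simulate --out cohort --seed 1                   # EDF + CSV cohort
somnonet epoch --edf cohort/M01.edf --hypnogram cohort/M01_hyp.csv \
               --mask cohort/M01_art.csv --stage REM --out epochs
somnonet connectivity --epochs epochs --order auto --out matrices
somnonet network --matrices matrices --density 0.2 --out metrics.csv
somnonet stats --metrics metrics.csv --subjects cohort/subjects.csv --out tables
```

`somnonet run` writes `metrics.csv`, the four report tables
(`table1.csv`...`table4.csv`), `report.txt` and a `manifest.json` with the
configuration hash and per-file checksums; identical config + seed gives
identical checksums.

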