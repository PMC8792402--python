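# ecmap

Eigenvector-centrality hub mapping for resting-state fMRI ROI networks, with
permutation group tests, surrogate/bootstrap null distributions, and coupling
of hub centrality to binocular visual-field scores.

## The problem

In progressive eye disease such as primary open-angle glaucoma, the question
is whether degraded visual input changes the functional organization of the
brain at rest — globally (whole-brain connectivity) or locally (the standing
of individual regions as network *hubs*) — and whether such changes track
functional vision. `ecmap` implements that analysis end to end for people
working with ROI-level resting-state BOLD data and Humphrey-style perimetry:

1. **Prewhitening.** ROI time series are cleaned in a two-step GLM: residualize
   against the six motion parameters, fit an AR(1) coefficient φ per ROI on the
   residuals, apply the whitening filter `x̃_t = x_{t+1} − φ x_t` to the raw
   data, then regress motion, white-matter and CSF signals out of the whitened
   series.
2. **Functional connectivity (FC).** Pairwise Pearson correlation between ROI
   series, Fisher-z transformed (`z = atanh r`); whole-brain FC per participant
   is the mean upper-triangle z, compared between groups by a label-permutation
   test on group medians.
3. **Eigenvector centrality mapping (ECM).** The adjacency is the correlation
   matrix shifted by +1 (entries in `[0, 2]`, so Perron–Frobenius guarantees a
   nonnegative leading eigenvector). Centrality is the unit-norm leading
   eigenvector found by power iteration: a region is central when it is
   strongly connected to other central regions. Hubs are the ROIs whose
   group-mean centrality exceeds the 95th percentile.
4. **Inference.** Group differences at hubs use label permutations with
   max-statistic family-wise error correction. Two resampling references frame
   every centrality value: iAAFT surrogates (phase-randomized series with the
   original value distribution and spectrum, independently per ROI — a null
   with no cross-ROI communication, centered near the uniform value `1/√N`,
   not at zero) and a joint time-point bootstrap (a confidence distribution
   that preserves cross-ROI structure).
5. **Behavioral coupling.** Three visual-field scores per participant —
   WorseMD (mean deviation of the worse eye), BIVF (mean of the pointwise-best
   total deviation across the two eyes) and AbsDiffMD (between-eye MD
   asymmetry) — are correlated with per-participant hub centrality by
   Spearman's rank correlation.

A synthetic-cohort generator (`ecmap.synthetic`) provides ground truth for
every stage: a latent-factor covariance with planted hubs, AR(1) noise, motion
and tissue confounds, and paired-eye perimetry whose severity attenuates hub
loadings.

## Worked example

```python
import pandas as pd
from ecmap import (SimConfig, simulate_cohort, prewhiten_pipeline, ec_from_ts,
                   identify_hubs, behavioral_scores, correlate_scores_with_ec)

cfg = SimConfig(seed=1)                       # 131 ROIs, 260 volumes, 24+20 participants
bundles, truth = simulate_cohort(cfg)
print("planted hubs:", truth.planted_hubs)

ec = {}
for b in bundles:
    ts, conf = b.scans["RS1"]
    ec[b.participant_id] = ec_from_ts(prewhiten_pipeline(ts, conf)).ec
table = pd.DataFrame.from_dict(ec, orient="index")

controls = [b.participant_id for b in bundles if b.group == "control"]
hubs = identify_hubs(table.loc[controls].mean(axis=0).to_numpy(),
                     roi_ids=list(table.columns))
print("control hubs:", hubs.roi_ids, f"(threshold {hubs.threshold:.4f})")

scores = pd.DataFrame({b.participant_id:
                       behavioral_scores(b.vf_left, b.vf_right).as_dict()
                       for b in bundles}).T
corr = correlate_scores_with_ec(scores, table, hubs)
print(corr[corr.score == "bivf"].to_string(index=False))
```

Output:

```
planted hubs: [5, 23, 47, 68, 90, 112]
control hubs: [5, 23, 47, 64, 68, 90, 112] (threshold 0.0876)
 hub score      rho            p  n
   5  bivf 0.781725 1.819466e-08 36
  23  bivf 0.803861 3.552072e-09 36
  47  bivf 0.726898 5.156813e-07 36
  64  bivf 0.416988 1.140423e-02 36
  68  bivf 0.749035 1.480853e-07 36
  90  bivf 0.790991 9.403158e-09 36
 112  bivf 0.691634 2.993183e-06 36
```

All six planted hubs land in the control group's top-5% centrality set (one
extra ROI, 64, clears the threshold by chance), and every planted hub's
centrality correlates positively with the binocular integrated visual field
across the 36 participants with complete perimetry — worse binocular vision
goes with lower hub centrality, exactly the coupling the generator plants.

The same analysis is available from the shell:

```sh
ecmap simulate --seed 1 --out cohort/
ecmap run config.yaml --out results/
ecmap report results/result.json --out figures/
```

## Layout

- `src/ecmap/atlas.py` — spherical ROI atlases, network merge/drop, voxel-averaged extraction from 4-D NIfTI
- `src/ecmap/prewhiten.py` — two-step GLM prewhitening
- `src/ecmap/connectivity.py` — Fisher-z FC, permutation tests with FWE control
- `src/ecmap/centrality.py` — ECM, hub identification, group hub comparison
- `src/ecmap/nulls.py` — iAAFT surrogates, time-point bootstrap, Gaussian fits
- `src/ecmap/behavioral.py`, `vfgrids.py` — perimetry grids, WorseMD/BIVF/AbsDiffMD, Spearman coupling
- `src/ecmap/synthetic.py` — ground-truth cohort generator
- `src/ecmap/pipeline.py`, `cli.py` — end-to-end driver, reporting, CLI

See `docs/methods.md` for the model, parameter defaults and numerical choices.
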