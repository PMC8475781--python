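# demandmri

Simulation and analysis of **matched-difficulty linguistic vs. non-linguistic
demand** in block-design task fMRI.

A central question in the cognitive neuroscience of language — and in the
interpretation of functional imaging in aphasia — is which brain responses
reflect *language processing* and which reflect *task difficulty in
general*. The experimental logic implemented here crosses domain (semantic
word matching vs. perceptual symbol matching) with difficulty (easy vs.
difficult), with an adaptive staircase keeping behavioral difficulty matched
across domains. The contrasts of interest over the four conditions
(SE, SD, PE, PD) are

- **linguistic demand**: SD − SE
- **non-linguistic demand**: PD − PE
- **language**: (SE + SD) − (PE + PD)
- **domain × difficulty interaction**: (SD − SE) − (PD − PE)

Multiple-demand (MD) regions should be modulated by both kinds of demand but
more by non-linguistic demand (negative interaction); language regions only
by linguistic demand (positive interaction); default-mode regions
deactivated by difficulty in both domains.

Because no raw scans ship with the package, a synthetic-data module
generates the full study: block/trial schedules with the adaptive
sub-level rule, 4D BOLD runs from a ground-truth phantom (difference-of-
gammas HRF, AR(1) noise, drift, nuisance series), and go/no-go behavior
with the study's characteristic error asymmetry. Every analysis stage —
first-level GLM, sign-flip maximum-cluster-extent permutation FWER
correction, cross-run top-10% functional ROI selection with
orthogonal-contrast exclusion, and permutation-based ROI statistics
(Cohen's d_z, max-statistic family correction, Greenhouse–Geisser omnibus
ANOVA) — is therefore verifiable by parameter recovery, null calibration,
and brute-force oracles. See `docs/methods.md` for the model details.

## Worked example

```python
from demandmri import pipeline as pl, froi, group

cfg = pl.PipelineConfig(n_participants=8, seed=7,
                        phantom_kwargs=dict(grid_dims=(16, 16, 12)))
cfg.inference = group.InferenceConfig(n_permutations=500, seed=7)
cfg.froi = froi.FROIConfig(n_permutations=2000, seed=7)
phantom, parts = pl.simulate_cohort(cfg)
res = pl.analyze_cohort(phantom, parts, cfg)
print(res["behavior"]["anova_accuracy"].round(4).to_string(index=False))
```

```
     effect       F  df1  df2      p
     domain  0.0597  1.0  7.0 0.8140
 difficulty 71.1572  1.0  7.0 0.0001
interaction  0.1995  1.0  7.0 0.6686
```

Accuracy shows the intended behavioral structure: a large main effect of
difficulty, no domain effect, no interaction — difficulty is matched across
domains, so neural domain differences are not confounded by performance.
ROI statistics for the interaction contrast recover the phantom's profile
(`res["froi"]["stats"]["interaction"]`, excerpt):

```
      roi     d_z    mean  p_unc  p_corrected  network
    L IFJ -4.8303 -0.6088 0.0078       0.0078       md
    R IFJ -5.8233 -0.5904 0.0078       0.0078       md
 L IFGpop  6.0739  0.8457 0.0078       0.0078 language
  L IFGpt  7.8920  0.8775 0.0078       0.0078 language
```

MD-like ROIs show significant *negative* interactions (more modulation by
non-linguistic demand), language-like ROIs significant *positive* ones;
`mean` is percent signal change for the interaction contrast and `0.0078 =
2/256` is the floor of the exact 8-participant sign-flip enumeration. The
recovery report compares estimated and true contrast effects per truth
region (`res["recovery"]`): e.g. the MD-family non-linguistic demand truth
of 1.10 signal units is estimated at 1.06 in this cohort.

The same pipeline is scriptable from the shell:

```bash
demandmri simulate --seed 7 --n-participants 8 --out ds/
demandmri all --dataset ds/ --out results/ --n-perm 500
```

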