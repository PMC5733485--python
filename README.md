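# dyadmotion

Automated motion-feature extraction and rating analysis for dyadic
(mother–infant) motion-capture recordings.

Observational research on early parent–infant interaction increasingly
pairs global behavioural rating systems — such as the Coding Interactive
Behavior (CIB) scheme, with its 1–5 Likert scales averaged into composites
like *maternal sensitivity* or *infant negativity* — with objective,
automatically extracted movement measures from optical motion capture.
`dyadmotion` implements that measurement pipeline end to end for
researchers in developmental psychology and social signal processing:

1. **Kinetic energy.** From 3-D marker trajectories (head, wrists, elbows,
   shoulders of both partners, sampled at e.g. 240 Hz), the per-frame
   translational kinetic energy of the head, arms and upper body is
   computed as K = Σ ½ m v², where each body segment's mass m is a
   fraction of total body mass (Winter-style anthropometric tables) and v
   is the segment's centre-of-mass speed:

   - K_h = ½ m_h v_h²
   - K_a = Σ_sides ½ m_fa v_fa² (+ ½ m_ua v_ua²)
   - K_ub = K_h + K_a terms (+ Σ_sides ½ m_s v_s²)

   with the parenthesised terms dropped when shoulder markers are unusable
   (4-month-old infants).
2. **Movement segmentation.** A frame is "moving" when its energy exceeds
   20% of the actor's spike-robust mean energy; movements separated by
   pauses shorter than 350 ms are merged, movements shorter than 350 ms
   are discarded.
3. **Dyadic motion features.** Per dyad and body part, four coarse features
   (infant/maternal activity ratio, overlap ratio, silence ratio) and four
   fine-grained coordination features (infant/maternal coactive and
   alternating onset ratios, with a 1.5 s response window).
4. **Rating statistics.** CIB composite scoring (with scale reversal),
   Cronbach's α, ICC(2,1) inter-rater reliability with 95% CI, and
   two-tailed Spearman correlation tables of features × composites.

Because recordings of this kind are not generally shareable, the package
includes a first-class synthetic-data generator that plants movement
episodes, coactive/alternating coupling, sensor noise, energy spikes and
occlusion-style missing runs with known ground truth — so the whole
pipeline is testable and demonstrable without external data.

## Worked example

```python
from dyadmotion import (SyntheticDyadSpec, generate_dyad, RunConfig,
                        segment_dyad, compute_feature_set)

spec = SyntheticDyadSpec(duration_s=60.0, seed=7, p_co=0.6, p_alt=0.2)
mother, infant, truth = generate_dyad(spec)

cfg = RunConfig(window_start_s=0.0, window_duration_s=60.0)
inf_segs, mot_segs = segment_dyad(mother, infant, cfg)["upper_body"]
print(compute_feature_set("demo", "upper_body", inf_segs, mot_segs).as_dict())
```

prints

```
infant_activity_ratio: 0.428        maternal_activity_ratio: 0.465
overlap_ratio: 0.194                silence_ratio: 0.300
infant_coactive_onset_ratio: 0.588  maternal_coactive_onset_ratio: 0.222
infant_alternating_onset_ratio: 0.176  maternal_alternating_onset_ratio: 0.333
```

The infant moved 42.8% of the window, both partners moved simultaneously
19.4% of it, and neither moved 30.0% of it. 58.8% of the infant's
movement onsets began while the mother was already moving and within 1.5 s
of her movement onset — exactly the coactive fraction the generator
planted for this dyad (10 of 17 movements). Correlating an extracted
feature with a synthetic rating composite across a 60-dyad cohort with a
planted rank correlation of 0.6:

```python
from dyadmotion import generate_cohort, run_extract, run_correlate

dyads, ratings = generate_cohort(60, "silence_ratio", planted_rho=0.6, seed=1)
table, qc = run_extract(cfg, ((d.dyad_id, *d.realize()) for d in dyads))
corr = run_correlate(table, ratings)
```

yields `rho=0.682, p=2e-09, n=60` for the silence-ratio × composite cell —
the planted association recovered through the full read→filter→energy→
segment→feature→correlate chain.

A CLI mirrors these stages (`dyadmotion simulate | extract | correlate |
all`); real recordings enter as tab-separated marker files (one row per
frame, `<label>_X/_Y/_Z` columns, mm or m) with per-dyad CIB ratings as
CSV and the composite map as YAML.

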