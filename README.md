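# handquant

Quantification of hand muscle volume and intramuscular fat from MRI, for
studying muscle loss (sarcopenia, rheumatoid cachexia) in inflammatory
arthritis. Rheumatoid arthritis (RA) and psoriatic arthritis (PsA) are
associated with loss of fat-free muscle mass that BMI does not detect,
because fatty infiltration keeps body weight normal; imaging-based
volumetry of the hand — the region routinely scanned in arthritis care —
makes that loss measurable. `handquant` implements the full analysis
pipeline on T1-weighted + 2-point Dixon hand MRI, and the cohort
statistics to compare psoriasis (Pso, control), PsA and RA patients.

## Method

Per subject:

1. **N4 bias-field correction** of the T1 volume (smooth multiplicative
   intensity modulation removed in the log domain).
2. **Hand cross-sectional area**: per-slice thresholding, morphological
   closing, hole filling and minimum-area filtering.
3. **Random-forest muscle segmentation**: each hand voxel is classified
   muscle/background from neighborhood image features; the muscle voxels
   form the muscle VOI.
4. **Gaussian cleanup**: a Gaussian is fitted to the VOI intensity
   histogram and voxels outside μ ± 2σ are removed (stray tendons and
   vessels).
5. **Volumetrics** between the proximal and distal MCP-III slice bounds:

       V_H  = Σ hand voxels   × voxel volume        [mm³]
       V_M  = Σ muscle voxels × voxel volume        [mm³]
       V_M^rel = V_M / V_H

6. **Dixon fat quantification**: from the water/fat pair,
   `I_ff = fat/(water+fat) × 1000` (integer grey values, 1 gv = 0.1% fat);
   the T1 hand is registered to the Dixon frame by rigid mutual-information
   registration, the VOI transferred with nearest-neighbour resampling, and

       V_F = Σ_muscle voxel volume × I_ff/1000      [mm³]
       V_F^rel = V_F / V_M

Reanalysis precision is reported as RMS-SD and RMS-CV over repeated
analyses of the same datasets. Cohort statistics: sex-stratified OLS of
`V_H` / `V_M^rel` on age (or age³), BMI and diagnosis; adjusted group
differences Δ averaged over an age window; percent change across the
window; and per-decade ([40,50) … [70,80]) one-way ANOVA with Tukey HSD.

Because no patient data ship with the package, a first-class synthetic
module generates hand phantoms (schematic palm + fingers with muscle,
bone, tendon and vessel compartments, known bias field, known Dixon
transform, exact ground-truth volumes) and cohorts with known generating
coefficients. Conventions (axes are `(slice, row, col)`, spacing
`(dx, dy, dz)` mm; bounds are 0-based and inclusive) and all design
decisions are documented in `docs/methods.md`.

## Worked example

```bash
# a synthetic subject with known truth
handquant simulate phantom --seed 5 --out subj/
cat subj/truth.json   # v_h_mm3: 180360.0, v_m_mm3: 58536.0, v_m_rel: 0.3246

# train the voxel classifier on labeled scans (here: phantom truth labels)
python - <<'PY'
from handquant import train_on_phantoms
train_on_phantoms([100, 101, 102]).save("clf.joblib")
PY

# full per-subject analysis
handquant run-subject --t1 subj/t1.nii.gz --water subj/water.nii.gz \
    --fat subj/fat.nii.gz --model clf.joblib --out out/
```

prints (one line, reformatted):

```json
{"bounds": [3, 20], "scan_id": "t1", "v_f_mm3": 3832.326,
 "v_f_rel": 0.1028, "v_h_mm3": 181440.0, "v_m_mm3": 55911.0,
 "v_m_rel": 0.3082}
```

Hand volume is recovered within 1% of the truth above, muscle volume
within 5% (the μ±2σ cleanup deliberately trims the distribution tails),
the relative muscle volume to ±0.02, and the fat fraction inside the
muscle VOI (true value 0.10) to ±0.003. The cohort side:

```bash
handquant simulate cohort --seed 3 --out cohort.csv
handquant stats --cohort cohort.csv --sex male --out stats.json
```

`stats.json` then contains the fitted age slope (−0.00101/y at this
seed), the adjusted group differences — `"RA - Pso": Δ = −0.0215,
p = 3.1e-05`, an estimate of the generating RA offset of −0.035 within
its sampling error at n = 165 — and the percent change of relative
muscle volume over the age window (−26% over 20–80 y).

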