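# irisopt

Coverage–leakage evaluation and Iris collimator diameter selection for
robotic-radiosurgery lung tracking (CyberKnife-style Xsight lung tracking
plans).

## The problem

During tracked lung SBRT the beam aperture follows the *predicted* target
position while the tumor is actually at the position seen in the x-ray
images; the residual delivery error (correlation + prediction error, ~1 mm
per axis) displaces the aperture relative to the clinical target volume
(CTV) at every imaging time point. A larger collimator absorbs this jitter
and keeps target coverage — but irradiates more surrounding lung. `irisopt`
quantifies that tradeoff and picks the aperture diameter.

For every voxel it accumulates, over all imaging time points of all
fractions, the fraction of time the voxel center lies inside the tracked
aperture ball:

- **coverage possibility** on CTV voxels → **CVH**, the cumulative
  coverage-volume histogram (% of structure volume with coverage ≥ level),
  with D95-style quantiles **C95**/**C90**;
- **leakage possibility** on non-target voxels → **LVH**, the cumulative
  leakage-volume histogram (absolute cm³ vs level), with the **absolute mean
  leakage** (leak AUC / leakage volume) and the **leakage/coverage ratio**
  (leak AUC / PTV coverage AUC).

Diameter selection is a three-step rule over the 12 Iris field diameters
(5–60 mm): candidates in [0.5·A_min, A_max + 5 mm] (A_max/A_min = PTV
long/short axis); feasibility by CTV C95 ≥ 90% (falling back to C90 ≥ 90%);
then the cost

    F(d) = w · C95_PTV(d) − mean_leakage(d) / V_lung

maximized over the feasible set (default w = 0: pure leakage minimization,
ties to the smaller aperture).

Intended users: medical physicists studying collimator/margin strategy for
tracked lung SBRT, and anyone needing CVH/LVH-style geometric plan metrics
on voxelized structures plus motion traces. It computes geometric
possibility, not dose.

## Worked example

A cohort-mean-sized ellipsoidal target, simulated delivery errors, and the
full selection:

```bash
irisopt phantom --shape ellipsoid --semi-axes 24.4 15.03 14.18 --label CTV --out ctv.nii.gz
# wrote ctv.nii.gz: volume 21.80 cm^3, a_max 49.26 mm, a_min 28.82 mm
irisopt phantom --shape ellipsoid --semi-axes 28.4 19.03 18.18 --label PTV --out ptv.nii.gz
# wrote ptv.nii.gz: volume 41.19 cm^3, a_max 57.33 mm, a_min 36.24 mm
irisopt simulate-trace --sd-lr 1.21 --sd-ap 0.58 --sd-si 0.86 \
    --points 40 --fractions 5 --seed 7 --out trace.csv
# wrote trace.csv: 200 points over 5 fractions
irisopt optimize --ctv ctv.nii.gz --ptv ptv.nii.gz --trace trace.csv --out result.json
# tier C95; selected diameter: 50.0 mm -> result.json
```

`result.json` then contains (abridged): candidates
`[20, 25, 30, 35, 40, 50, 60]`, feasible `[50, 60]` at tier `C95`, selected
Φ = 50 mm with Φ/A_min = 1.38 and Φ/A_max = 0.87, and per-candidate metrics —
for the selected diameter: `c95_ctv = 100.0`, `c95_ptv = 68.5`,
`mean_leakage = 0.698`, `leak_cov_ratio = 1.107`. Read: only the 50 and
60 mm apertures keep ≥ 95% of the CTV covered ≥ 90% of the time under this
error trace; of those, 50 mm leaks less into surrounding tissue, and the
aperture ends up 1.38× the PTV short axis. `irisopt evaluate` writes the
underlying coverage/leakage maps (NIfTI) and CVH/LVH curves (CSV) for one
diameter; `irisopt cohort` runs a whole synthetic cohort and its statistics
(paired Wilcoxon across coverage-threshold groups, Spearman correlations,
diameter × A_min contingency table); `irisopt report` renders the summary.

The same pipeline is available as a library (`irisopt.accumulate`,
`irisopt.build_cvh`, `irisopt.optimize_collimator`, …); see `docs/methods.md`
for the model, conventions and limitations.

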