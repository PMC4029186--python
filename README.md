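# kneespect

Zone-based quantification of bone-tracer uptake in knee SPECT/CT, with
mechanical-alignment measurement and observer-reliability analysis — aimed at
the follow-up of patients before and after medial opening-wedge high tibial
osteotomy (HTO).

## The problem

Bone-tracer uptake on SPECT/CT (e.g. ⁹⁹ᵐTc-HDP) reflects the loading history
of the knee: a varus knee overloads its medial compartment, and a successful
HTO unloads it. Making that signal quantitative and comparable across
patients and timepoints needs three ingredients, which this package
implements:

1. **A standardized localization scheme.** The periarticular bones are
   partitioned into named anatomical zones — 9 femoral (8 condylar quadrants
   plus the femoral-shaft reference zone `R`), 8 patellar, and 13 tibial —
   using a compact label grammar (`F1sa` = femur, medial, superior, anterior;
   `T4` = tibial distal plate area). An identical label set applies to native
   and postoperative knees; only the partition geometry is adjusted (the `T4`
   plate box, an inferior shift of the tibial transverse plane).
2. **Reference-normalized uptake.** For each zone the maximum voxel value
   `max_z` is divided by the mean uptake `R̄` of the femoral-shaft reference
   region, giving the dimensionless ratio `q_z = max_z / R̄` that can be
   compared across acquisitions.
3. **Mechanical alignment.** The hip–knee–ankle (HKA) angle is measured from
   five landmarks — femoral head centre, medial/lateral femoral epicondyles,
   tibial plateau centre, talar centre. Both mechanical axes are projected
   onto the coronal plane oriented by the epicondylar line; medial deviation
   of the distal tibial axis is *varus* (signed positive), lateral is
   *valgus*.

Observer agreement is summarized with the intraclass correlation coefficient
ICC(2,1) (two-way random effects, absolute agreement, single measure),

    ICC = (MS_rows − MS_err) / (MS_rows + (k−1)·MS_err + (k/n)·(MS_cols − MS_err)),

with the conventional interpretation bands (0.81–1.00 very good, 0.61–0.80
good). Median/range tables of absolute paired differences complement the
ICCs for alignment readings.

Because clinical images cannot ship with the package, a **synthetic phantom
generator** builds box-bone knee volumes with configurable hot spots,
Poisson counting noise, and simulated observer noise — with exact known
ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
import kneespect as ks

# A knee with medial tibial overloading: hot spot of amplitude 8 over a
# baseline of 2, reference region at 2  ->  expected T1sa ratio (2+8)/2 = 5.
cfg = ks.PhantomConfig(
    baseline=2.0, reference_level=2.0,
    hotspots=(ks.HotSpot("T1sa", amplitude=8.0, radius_mm=6.0),),
)
vol, landmarks, truth = ks.make_phantom(cfg)
report = ks.build_report(vol, landmarks, "native")
print(report.table.iloc[[0, 12, 24]].to_string(index=False))
```

```
zone  raw_max  ratio  missing
F1sa      2.0    1.0    False
T1sa     10.0    5.0    False
  T4      2.0    1.0    False
```

The medial-superior-anterior tibial zone lights up at ratio 5.0 (five times
the reference uptake); every unloaded zone sits at 1.0.

```python
pre = ks.hka_angle(ks.default_landmarks(hka_deg=4.0))    # varus knee
post = ks.hka_angle(ks.default_landmarks(hka_deg=-4.0))  # after correction
print(pre.formatted(), "->", post.formatted())
print(ks.report_alignment(pre, post).delta_deg)
```

```
4.0° varus -> 4.0° valgus
8.000000000000002
```

A 4° varus knee corrected to 4° valgus: an 8° correction crossing neutral.

```python
# Two observers read 23 noisy uptake ratios twice (observer noise SD 0.2
# on subjects with between-subject SD 1.0):
rng = np.random.default_rng(1)
data = ks.simulate_raters(rng.normal(2.0, 1.0, 23), ks.RaterNoiseModel(sd=0.2, seed=2))
print(ks.reliability_report(data).table.round(3).to_string(index=False))
```

```
 location  n_subjects  intra_obs1  intra_obs2  inter      band
alignment          23       0.882       0.902   0.92 very good
    Total          23       0.882       0.902   0.92 very good
```

Inter-observer ICC 0.92: *very good* reliability, as expected for this
noise level (analytic ICC = 1/(1+0.2²) ≈ 0.96, estimated here on 23
subjects).

The same steps are available from the shell:

```bash
kneespect phantom --out-dir work --hotspot T1sa:8:6 --baseline 2 --reference-level 2
kneespect report work/phantom.nii.gz work/landmarks.json --out-dir work --subject P1
kneespect align work/landmarks.json
```

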