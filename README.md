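# petac

**How low can the CT dose go before PET attenuation correction breaks?**

`petac` is a desk-scale simulation and analysis pipeline for studying the
impact of CT exposure (tube current, tube voltage, pitch) and CT
reconstruction algorithm (filtered back projection, FBP, vs iterative
reconstruction, IR) on quantitative PET. In PET/CT, the CT provides the
511-keV attenuation-correction (AC) map; when the CT is acquired *only*
for AC — serial dosimetry or gated studies — its exposure should be pushed
as low as quantitative accuracy allows. The package reproduces, with a
digital anthropomorphic torso phantom and a simplified CT/PET simulator,
the complete analysis a physicist would run on a scanner: one PET emission
acquisition, reconstructed once per AC map over a 24-protocol CT exposure
grid × {FBP, IR}, then compared against a reference reconstruction with
ROI statistics and a voxel-wise significance analysis. It also accepts
pairs of real, co-registered NIfTI volumes and applies the identical
analysis without simulation.

It is aimed at nuclear-medicine physicists and image-reconstruction
researchers who want a reproducible, fully synthetic testbed for AC-driven
SUV bias — no scanner time, no DICOM plumbing.

## The statistics at the core

For a 2-D circular ROI, the noise proxy is the SUV coefficient of
variation,

```
SUV COV = SUV SD / SUV mean × 100 ,
```

and matched FBP/IR reconstructions of the same acquisition are compared by

```
ΔCOV = COV_FBP − COV_IR          (positive ⇒ FBP noisier),
```

with a two-sided paired *t* test across all matched protocol pairs.

For the voxel analysis, every test reconstruction (TR) is compared with
the reference reconstruction (RR; 50 mAs, 120 kVp, pitch 0.828, IR) on the
shared grid. The significance threshold is the *quantitatively significant
difference*

```
QSD = SD(liver ROI of RR) ,
```

and per TR the pipeline reports the paired-*t* p value, the percentage of
voxels with |RR − TR| strictly greater than the QSD, the maximum and mean
voxel difference as a percentage of the RR value, and the binary
significance mask, whose spatial structure is scored as per-region
enrichment (high-activity compartments, attenuation interfaces,
beam-hardening corridor).

The CT dose model is `CTDI = c(kVp) × mAs` with per-voltage coefficients
calibrated to the scanner's reported dose table (pitch-independent at the
0.1 mGy reporting precision).

## Worked example

```python
import petac
from petac.protocols import CTProtocol, ctdi_model

spec = petac.default_phantom(shape=(64, 64, 16), spacing_mm=(8, 8, 10))
bundle = petac.generate_study(spec=spec, seed=1)   # 48 reconstructions

liver = next(r for r in petac.default_rois(spec) if r.name == "liver")
rr = bundle.reference.volume
stats = petac.roi_stats(rr, liver)
qsd = petac.compute_qsd(rr, liver)
print(f"RR liver: mean {stats.mean:.2f} SUV, SD {stats.sd:.3f}, "
      f"COV {stats.cov_percent:.1f}%")
print(f"QSD = {qsd.value:.3f} SUV "
      f"({petac.suv_cov(qsd.value, stats.mean):.1f}% of liver mean)")

table, masks = petac.compare_bundle(bundle, qsd)
low = table[(~table.is_reference) & (table.ctdi_mgy == 0.3)]
for alg, sub in low.groupby("algorithm"):
    print(f"CTDI 0.3 mGy, {alg}: {sub.percent_gt_qsd.mean():.2f}% voxels > QSD")
mid = table[(~table.is_reference) & (table.ctdi_mgy >= 1.0)]
print(f"CTDI >= 1.0 mGy: max {mid.percent_gt_qsd.max():.2f}% voxels > QSD")

ref, low_dose = ctdi_model(petac.REFERENCE_PROTOCOL), ctdi_model(CTProtocol(25, 100, 0.828))
print(f"25 mAs/100 kVp AC protocol: {100 * (1 - low_dose / ref):.0f}% dose reduction")
```

prints (about half a minute on one CPU):

```
RR liver: mean 2.52 SUV, SD 0.120, COV 4.8%
QSD = 0.120 SUV (4.8% of liver mean)
CTDI 0.3 mGy, FBP: 0.00% voxels > QSD
CTDI 0.3 mGy, IR: 3.78% voxels > QSD
CTDI >= 1.0 mGy: max 0.00% voxels > QSD
25 mAs/100 kVp AC protocol: 69% dose reduction
```

Reading: at the lowest exposure, AC maps from iteratively reconstructed CT
push ~4% of body voxels beyond a quantitatively significant difference
(and depress the liver mean), while FBP AC maps stay quantitatively
faithful; once CTDI reaches ~1 mGy the two algorithms agree with the
reference everywhere — so a ~70% CT dose reduction (3.3 → 1.0 mGy) is
possible without compromising quantitation, provided the right
reconstruction is chosen.

## Command line

```
petac run-all --seed 1 --out runs/            # simulate + analyze + report
petac simulate --config cfg.yaml --out runs/  # also save volumes as NIfTI
petac analyze --rr rr.nii --tr tr1.nii --tr tr2.nii --rois rois.yaml --out out/
petac report --study runs/run-xxxxxxxx --out out/
```

`run-all` writes the acquisition-grid table, the per-region ΔCOV summary
with paired-*t* p values, the per-TR voxel-analysis table, figure data
(statistic vs CTDI per algorithm), significance masks as NIfTI, overlay
renderings, and a JSON manifest with the seed and output checksums;
rerunning the same configuration reproduces the CSVs byte-for-byte.

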