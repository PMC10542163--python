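# endokit

Quantification machinery for synaptic-endocytosis imaging studies, built for
labs measuring how endocytic proteins (dynamin splice variants, endophilin)
organize and act at presynaptic boutons.  The package re-implements, as a
tested and reusable pipeline, four analysis stages that are usually buried
in one-off scripts:

1. **STED distance analysis** (`endokit.sted_distance`) — two-channel
   super-resolution images are lightly Gaussian-blurred, deconvolved by two
   rounds of blind Richardson–Lucy (the second round seeded with the PSF
   returned by the first), and cropped into 30×30-pixel bouton ROIs
   (0.81 µm² at the default 30 nm pitch).  The active-zone boundary is the
   iso-intensity contour at half of each local peak of the reference
   (Bassoon) channel; protein clusters are subpixel local maxima of the
   target channel; each punctum gets a signed Euclidean distance to the
   nearest boundary (negative = inside), plus colocalization fractions.
2. **EM morphometry** (`endokit.em_morphometry`) — per-micrograph annotation
   coordinates (membrane polyline, PSD, vesicle circles, endosome polygons,
   pit polylines) become structure counts per synaptic profile over a
   flash-and-freeze time course, and pit geometry: width = base-chord
   length, depth = maximum perpendicular distance from the chord.  Vesicles
   <60 nm are synaptic vesicles, 60–100 nm large endocytic vesicles (LEVs),
   larger circular structures endosomes.
3. **pHluorin kinetics** (`endokit.phluorin_kinetics`) — rolling-ball or
   constant background subtraction, photobleach correction
   F_corr(t) = F(t)·e^(t/K) with K fitted on a no-stimulation control,
   baseline/peak normalization, single-exponential decay fits
   y(t) = a·[p + (1−p)·e^(−(t−t_peak)/τ)], and percent-of-peak remaining at
   60 s per field of view.
4. **Binding metrics and statistics** (`endokit.binding_metrics`,
   `endokit.stats_report`) — one-site saturation Kd fits
   B(c) = B_max·c/(K_d + c), chemical shift perturbations
   Δδ = √(ΔδH² + (ΔδN/5)²), and a hand-implemented nonparametric toolbox:
   exact/asymptotic Mann–Whitney, Kruskal–Wallis with Dunn's
   Bonferroni-adjusted post-hoc tests, order-statistic median confidence
   intervals and the D'Agostino–Pearson normality screen.

Every stage is exercised end-to-end on synthetic data with known ground
truth from `endokit.synthetic_data`: Gaussian-blob STED fields, parametric
semicircular/Ω-shaped pits on membrane polylines, bleached exponential-decay
traces sampled at 2 Hz with a 10-pulse 20 Hz stimulus train at 5–5.5 s, and
saturation binding curves.

## Worked example

```python
import numpy as np
from endokit import synthetic_data as sd, sted_distance as st
from endokit import phluorin_kinetics as pk, binding_metrics as bm

# STED colocalization on a synthetic field: 10 host clusters, 10 guest
# puncta, 7 of them placed inside the hosts' half-max boundaries
images, truth = sd.demo_colocalization_field(n_hosts=10, n_guests=10, n_inside=7)
side = min(images["reference"].shape)
roi = st.extract_rois(images, [(side // 2, side // 2)], side)[0]
hosts = st.detect_active_zones(roi, min_peak_intensity=100.0)
guests = st.detect_puncta(roi, min_peak_intensity=100.0)
summary = st.colocalization_summary(hosts, guests)
print(f"guest-inside fraction: {summary['fraction_guests_inside']:.2f}")

# pHluorin decay: bleach constant from a no-stim control, then the fit
trace, _ = sd.make_phluorin_trace(sd.GroundTruthTrace(
    tau_s=10.7, plateau=0.0, bleach_k_s=300.0, noise_sigma=2.0, seed=4))
control, _ = sd.make_phluorin_trace(sd.GroundTruthTrace(
    amplitude=0.0, bleach_k_s=300.0, noise_sigma=2.0, seed=5))
bleach = pk.estimate_bleach_constant(control)
fit = pk.fit_decay(pk.correct_and_normalize(trace, bleach))
print(f"bleach K = {bleach.k_s:.1f} s, tau = {fit.tau_s:.2f} s")

# ELISA-style saturation binding
curve, _ = sd.make_binding_curve(44.0, 1.0, [1, 3, 10, 30, 100, 300, 1000],
                                 noise_sigma=0.02, seed=6, replicates=4)
kd = bm.fit_one_site_kd(curve)
print(f"Kd = {kd.kd_nM:.1f} +/- {kd.kd_se:.1f} nM")
```

Output:

```
guest-inside fraction: 0.70
bleach K = 307.9 s, tau = 10.66 s
Kd = 44.0 +/- 1.9 nM
```

The colocalization fraction reports exactly the 7/10 guests generated inside
host boundaries; the decay constant recovers the generating τ = 10.7 s
despite 2% noise and photobleaching; the Kd fit recovers the generating
affinity with its Jacobian-based standard error.

A thin CLI wraps the same entry points:

```sh
endokit simulate --config generators.yaml --out data/
endokit sted --images field.tif --out results/
endokit em --annotations profiles.json --out results/
endokit phluorin --traces traces.csv --control-roi roi0 --out results/
endokit kd --curve curve.csv
endokit csp --shifts shifts.csv
```

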