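# nervequant

Quantitative image analysis for high-resolution neurosonography (HRNS) of
peripheral nerve trauma. Given transverse-view ultrasound stills and an
operator-drawn region of interest (ROI) over the nerve (or target muscle),
the package computes:

* **FR — fascicular ratio**: the percentage of the nerve cross-section
  occupied by hypoechogenic (dark, fascicular) tissue on B-mode. A nerve with
  a neuroma in continuity shows a markedly increased FR.
* **CSA / CSR — cross-section area and ratio**: the calibrated ROI area in
  mm² and the per-subject enlargement factor, mean(affected CSA) /
  mean(unaffected CSA).
* **VR — vascular ratio** and **MPR — muscle perfusion ratio**: the
  percentage of the ROI covered by color-Doppler flow signal, plus the
  proportion of that signal carried by high-velocity flow. VR quantifies the
  hypervascularization of traumatic neuromas; the identical computation on a
  muscle ROI (MPR) quantifies the perfusion drop in denervated muscle.

It is aimed at neurosonography researchers who want these ratios computed
reproducibly (fixed thresholding rule, auditable intermediate areas) rather
than by interactive image editing, and it ships a synthetic-frame generator
so the whole measurement chain can be validated against known ground truth
without patient data.

## Method

**B-mode (FR).** The frame is converted to 8-bit grayscale, inverted, and
background-subtracted (rolling-ball estimate: grayscale opening with a disk,
default radius 50 px). Within the ROI, hypoechogenic fascicles — bright after
inversion — are selected by maximum-entropy (Kapur) automatic thresholding:
the threshold t* maximizes

    H(t) = H_b(t) + H_f(t)

where H_b and H_f are the Shannon entropies of the normalized ROI histogram
restricted to bins [0..t] and [t+1..255]. Then FR = 100 · |{x ∈ ROI :
I(x) > t*}| / |ROI|.

**Color Doppler (VR/MPR).** The RGB frame is split into channels and the
color overlay decomposed by saturating channel subtraction into four
velocity/direction class maps: light blue = G−R (fast, away from the
transducer), dark blue = B−G (slow, away), light red = G−B (fast, toward),
dark red = R−G (slow, toward). Any pixel with R = G = B — the entire
grayscale background — is exactly zero in all four maps. Since flow
direction is not analyzed, fast and slow maps are merged by pixel-wise
maximum projection, each merged map is binarized by the same
maximum-entropy threshold over the ROI and filtered by connected-component
(particle) size. Because palette structure makes fast-flow pixels bleed into
the slow maps, the slow mask is corrected by set-subtracting the fast mask.
Then

    VR (or MPR) = 100 · |fast ∪ corrected slow| / |ROI|,
    high-velocity proportion = |fast| / |fast ∪ corrected slow|.

**Statistics.** Per-frame values are averaged per subject; groups are
compared with one-way ANOVA + Tukey HSD when every group passes a normality
check (D'Agostino–Pearson for n ≥ 8, Shapiro–Wilk for 3 ≤ n < 8), otherwise
Mann–Whitney U (2 groups) or Kruskal–Wallis with Bonferroni-adjusted Dunn
post hoc. Stars: p ≤ 0.05 (\*), ≤ 0.01 (\*\*), ≤ 0.001 (\*\*\*). Correlations
are Pearson's r.

## Worked example

Generate a synthetic Doppler frame with known ground truth (43% of the nerve
ROI painted with flow signal, 36% of it high-velocity), then measure it:

```sh
$ nervequant simulate doppler --out demo --seed 7 \
      --doppler-fraction 0.43 --high-class-fraction 0.36
{
  "frame": "demo/doppler.png",
  "roi": "demo/doppler.roi.json",
  "truth_doppler_fraction": 0.43001241464928613,
  "truth_high_class_fraction": 0.36015878744135693,
  "seed": 7
}
$ nervequant vr --image demo/doppler.png --roi demo/doppler.roi.json
{
  "roi_area_px": 6444,
  "high_area_px": 998,
  "low_corrected_area_px": 1773,
  "total_area_px": 2771,
  "high_velocity_proportion": 0.36015878744135693,
  "thresholds_used": { "high": 0, "low": 0 },
  "degenerate_high": false,
  "degenerate_low": false,
  "vr_percent": 43.00124146492862
}
```

The measured `vr_percent` (43.00) and `high_velocity_proportion` (0.360)
recover the generator's truth exactly: of the 6,444 ROI pixels, 998 carry
fast-flow signal and 1,773 corrected slow-flow signal, 2,771 in total. The
same on B-mode:

```sh
$ nervequant simulate bmode --out demo --seed 7 --fascicle-fraction 0.88
$ nervequant fr --image demo/bmode.png --roi demo/bmode.roi.json \
      --pixel-area-mm2 0.004017
{
  "hypoechoic_area_px": 5529,
  "roi_area_px": 6444,
  "fr_percent": 85.80074487895718,
  "threshold_used": 212,
  "degenerate": false,
  "csa_mm2": 25.885548
}
```

Here FR = 85.8% against a painted truth of 88.0% — about 2 pp low, the
method's characteristic small bias on speckled frames (see
`docs/methods.md`), and CSA = 6,444 px × 0.004017 mm²/px = 25.89 mm².

Cohort workflows use `nervequant simulate cohort`, `nervequant csr` and
`nervequant report --measurements m.csv --compare vr:neuroma,unaffected`.
Everything is also available as a library (`import nervequant`).

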