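# Published clinical cohort values

Per-patient values transcribed from a published ten-patient Lu-177 therapy
cohort (five neuroendocrine-tumour patients treated with Lu-177-Octreotate,
P1-P5; five metastatic castration-resistant prostate-cancer patients treated
with Lu-177-PSMA-617, P6-P10). The underlying images and raw count data are
not public; these summary values drive the cohort-statistics stage and the
acceptance checks.

- `patients.csv` — sex, injected activity (MBq) and haematocrit per patient.
- `rp_results.csv` — reference-protocol total bone-marrow absorbed doses
  (mGy/GBq) and the percentage contribution of remainder-of-body, blood and
  organs to the total.
- `protocol_doses.csv` — total bone-marrow absorbed doses under the
  reference protocol and the three hybrid variants (planar anchor at 24, 48
  or 72 h post-injection).
- `half_lives.csv` — planar whole-body and SPECT abdominal effective
  half-lives (h) per patient.

Note: the published summary table for the prostate cohort prints a
reference-protocol median of 10.8 mGy/GBq, which is not the median of its
own per-patient column (10.2 mGy/GBq, consistent with the protocol
comparison table). This package recomputes medians from the per-patient
values.
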