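# locreset

Single-cell live-imaging analysis of transcription-factor
nucleocytoplasmic dynamics — built for experiments of the kind used to
study YAP in breast epithelial monolayers, where a fluorescently tagged
factor shuttles between nucleus and cytoplasm, drives nascent transcription
visible through MS2/MCP reporters, and exchanges with chromatin on
timescales accessible to FRAP.

The package provides, as an importable library plus a thin `locreset` CLI:

* **Nucleus segmentation and tracking** — Perona–Malik anisotropic
  diffusion enhancement plus a sum-of-derivatives term, global (Otsu or
  fixed) thresholding, seeded-watershed splitting of touching nuclei, a 3D
  mode with per-region local thresholds placed at the peak of the
  intensity-percentile derivative (dI/dP), and distance-minimizing frame
  linking (Hungarian assignment with a displacement gate).
* **N/C quantification** — the nuclear/cytoplasmic ratio
  *N/C* = (⟨I_nuc⟩ − b) / (⟨I_cyto⟩ − b), measured in a 3-plane volume
  centred on the plane of maximal nuclear-stain signal, with the lowest
  35% of nuclear reporter intensities excluded (nucleoli) and the
  cytoplasm sampled in a 0.5 µm ring outside the nuclear boundary; local
  cell density (centroids within 250 px); per-cell pretreatment
  normalization; 2^ΔCt qPCR fold changes.
* **Fluctuation ("localization-reset") detection** — maximal monotone runs
  of the N/C trace with net amplitude ≥ 0.12, where continuity breaks
  whenever the trace changes < 0.005 over a sliding 3-frame window;
  cohort statistics (fraction fluctuating, frequency, amplitude).
* **Nascent-transcription spot calling** — LoG localization gated at each
  nucleus's own 99.97th intensity percentile, integrated-intensity scoring
  on a 37-pixel disk (r < 3.5 px) with a 32-pixel background shell
  (3.5 ≤ r < 4.5 px), pulse tracking, activity time courses, and
  mitosis-aligned traces (daughter-OR rule, premitosis activity
  normalized to 1).
* **FRAP and transport kinetics** — spatiotemporal (line-FRAP "carpet")
  fitting of pure-diffusion and reaction–diffusion models
  (∂f/∂t = D_f∇²f − k*_on·f + k_off·c, ∂c/∂t = k*_on·f − k_off·c;
  Keq = k*_on/k_off, bound fraction Keq/(1+Keq)), SSD + plausibility model
  selection, bootstrap uncertainty (30 resamples of 5 experiments), and
  first-order import/export rates from compartment-bleach traces (slope
  over the first 30 s, frames 1–4, normalized by the source compartment's
  postbleach intensity).
* **A synthetic-microscopy generator** (`locreset.synthetic`) — moving
  textured nuclei with nucleoli, programmed N/C time courses with
  localization-resets, telegraph-model transcription spots,
  reaction–diffusion FRAP surfaces and two-pool bleach recoveries, all
  with exported ground truth, so every stage can be validated end to end
  without raw movies.

## Worked example

`examples/` contains one short script per capability. Estimating
import/export kinetics (`examples/07_transport_rates.py`):

```bash
$ python examples/07_transport_rates.py
MCF10A-like: k_imp=0.00676/s k_exp=0.00173/s ratio=3.900 (programmed 3.9)
transformed-like: k_imp=0.00296/s k_exp=0.00185/s ratio=1.600 (programmed 1.6)
```

The 30-s linear fit slightly underestimates each individual rate (the
recovery already curves within the fit window), but both bleach directions
share the same relaxation rate, so the bias cancels and the import/export
*ratio* — the biologically interpreted quantity — is recovered exactly.

Fitting a FRAP carpet with 50% bound fraction
(`examples/06_frap_fitting.py`):

```bash
$ python examples/06_frap_fitting.py
pure diffusion:     D = 0.33 um^2/s, SSD = 1.14
reaction-diffusion: D_f = 15.35 um^2/s, k_on* = 0.100/s, k_off = 0.100/s, SSD = 1.11e-05
Keq = 1.00, bound fraction = 0.50
selected model: reaction_diffusion
```

A pure-diffusion fit of binding-dominated data collapses to an
implausibly small effective diffusivity, while the reaction–diffusion fit
recovers the generating parameters; the selector accepts it because the
SSD improvement is large and D_f is physically plausible.

The full pipeline (`locreset run --out out/ --seed 4`, or
`examples/08_full_pipeline.py`) chains
simulate → segment → track → quantify → fluctuations → spots → pulses and
writes CSV tables plus a manifest with per-stage counts.

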