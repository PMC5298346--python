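# hvkit

Toolkit for the quantitative electrophysiology of a voltage-gated,
proton-selective channel with ΔpH-dependent gating, and for the kinetics of
the proton-triggered bioluminescent flash it drives.

The package contains:

- **`hvkit.biophysics`** — Nernst electrochemistry (slope per pH unit,
  proton reversal potential), solution/condition types, unit conventions
  (mV, pA, nS, ms, µM throughout).
- **`hvkit.simulate`** — forward simulator of voltage-clamp current
  families: single-Boltzmann gating whose midpoint shifts 40 mV per unit
  pH (saturating above pH 8), single-exponential activation falling e-fold
  per 10 mV, instantaneous 1:1 Zn²⁺ block, ohmic leak, gated contaminant
  conductance, Gaussian noise, junction-potential offsets, and tail-scan
  protocols.
- **`hvkit.analysis`** — per-family analysis: single-exponential fits with
  extrapolated steady-state amplitudes, tail-current measurement, reversal
  potentials (tail-bracketing and direct family methods), chord-conductance
  g–V curves and the voltage at 10 % of g_max.
- **`hvkit.gating`** — cross-family inference: ΔpH gating slope,
  V_rev-vs-ΔpH selectivity regression against the Nernst line, bath-cation
  substitution statistics, Zn²⁺ dose–response with Hill fit.
- **`hvkit.flash`** — kinetic model of the depolarization-triggered
  scintillon flash: regenerative proton action potential pinned below E_H,
  buffered luminal acidification, pH-gated luciferin release and luciferase
  activation, luciferin-pool depletion; plus channel-independent acid-pulse
  stimulation and Zn²⁺ curves.
- **`hvkit.motif`** — sequence scanner for the diagnostic signature:
  mid-segment aspartate in the first transmembrane segment plus the
  R-x-W-R-x-x-R motif inside a later one (Kyte–Doolittle hydropathy TM
  prediction, FASTA batch scanning).
- **`hvkit.io` / `hvkit.cli` / `hvkit.pipeline`** — plain-TSV trace format
  (lossless, byte-identical round trips), strict JSON run configuration,
  provenance logs (config hash + seed), and end-to-end pipelines.

## CLI

```bash
hvkit simulate --config cfg.json --out family.tsv        # current family
hvkit simulate --config cfg.json --tail-scan \
      --prepulse 128 --tails 40,45,50,55,60,65 --out tails.tsv
hvkit analyze family.tsv --vrev-from tails.tsv --out report.json
hvkit gating report_pH6.json report_pH7.json report_pH8.json \
      --varied-side pH_o --out gating.json                # ΔpH slope
hvkit selectivity tails_*.tsv --out selectivity.json
hvkit zn --zn 0,10,30,100,300 --out zn.json               # dose-response
hvkit flash --out flash.tsv                               # flash time course
hvkit flash --zn 0,30,100,300 --out flash_zn.tsv          # peak-light table
hvkit scan-motif proteins.fasta --out hits.tsv
```

Every command writes a `<out>.log.json` sidecar with the config hash, seed
and package version; identical configs reproduce outputs bit-identically.

## Notes on the flash model

Scintillon volume, buffer capacity and channel density are unknown
experimentally; defaults are order-of-magnitude choices tuned so the
default stimulus produces a flash latency of 15–22 ms and a time-to-peak of
100–200 ms, with a regenerative peak voltage just below E_H (~200 mV). The
electrical driving force is frozen at its pre-flash value (the vacuole is
treated as an infinite proton reservoir), which makes the action potential
genuinely all-or-none; the corollary is that nothing closes the channel, so
very long simulations acidify the compartment without bound.
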