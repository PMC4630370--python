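# peptarget

Target-profile deconvolution and temporal expression profiling for
peptide-drug proteomics.

When a drug candidate is profiled by chemical proteomics (affinity pull-down
on an immobilized, biotinylated drug followed by LC-MS/MS), the raw hit list
is dominated by background: proteins that stick to the unloaded matrix,
ubiquitously expressed "central proteome" proteins, and contaminants that
recur across AP-MS experiments. A companion expression experiment (4-plex
isobaric labeling over a treatment time course) measures which proteins the
drug actually modulates. `peptarget` implements both computational arms and
the network analysis that joins them:

- **Deconvolution** — subtract control-matrix binders and central-proteome
  members from the identified list, annotate with contaminant-repository
  average spectral counts (strictly `> 2` flags an abundant contaminant),
  and report protein complexes overlapping the filtered profile.
- **Abundance / affinity** — in-silico tryptic digestion (cleave after K/R
  unless before P), PAI = observed/observable peptides,
  emPAI = 10^PAI − 1, and drug-affinity scores a = emPAI / max(emPAI) ∈ (0, 1].
- **Reporter quantification** — 4-plex reporter envelopes (channels
  114 = control, 115/116/117 = time points) are deconvolved by non-negative
  least squares against in-silico isotope templates; fit quality is a
  goodness-of-fit GOF = 1 − ½Σ|obs − fit| on unit-area distributions, and
  peptides with GOF < 0.8 are discarded. Peptide ratios are averaged
  geometrically per protein, median-centered per time point, and called
  against the population threshold τ = 2^(|median| + 1.6449·SD) of log2
  ratios (two-sided p < 0.1). Proteins detected only in treated (ON) or only
  in control (OFF) channels are significant by definition.
- **Enrichment** — hypergeometric upper-tail P(X ≥ k) with
  Benjamini–Hochberg FDR over annotation terms.
- **Network scoring** — functional subnetworks (largest connected induced
  component per term) scored by
  S_net = (Σ_{t∈T∩V_f} a_t + Σ_{t∉V_f} a_t·e(t,V_f)/deg(t)) / |V_f|,
  plus the interaction overlap between targets and differential proteins.
- **Synthetic data** — seeded generators for every input with stored ground
  truth, and packaged transcriptions of the published result tables
  (55 filtered targets with emPAI, 10 scored subnetworks, 72 differential
  proteins with per-time-point thresholds 2.6/2.6/2.4).

## Worked example

```python
import peptarget as pt

# chemical arm at the study's cardinalities
fx = pt.gen_pulldown_fixture(265, 104, 106, seed=1)
report, profile = pt.deconvolve(fx.identified, fx.sticky, fx.central, fx.crapome_counts)
print(report.n_identified, report.n_profile, report.n_filtered, report.n_crapome_above)
# 265 161 55 91   -> 265 identified, 161 after matrix-binder subtraction,
#                    55 after central-proteome subtraction; 91 of the 106
#                    central members have contaminant spectral count > 2

# expression arm: replay the packaged 72-row differential table
tables = pt.load_paper_tables()
t3 = tables.table3.rename(columns={"fc_40min": "40min", "fc_2h": "2h", "fc_5h": "5h"}).set_index("accession")
calls = pt.call_differential(t3, pt.TABLE3_THRESHOLDS)
print(int(calls["significant_any"].sum()))
# 72   -> every transcribed protein is significant in >= 1 time point
```

The same stages are scriptable from the shell (`peptarget simulate`,
`deconvolve`, `quantify`, `call-de`, `enrich`, `netscore`, `intersect`,
`run-chemical`, `run-expression`, `fixtures`); see `peptarget --help`.

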