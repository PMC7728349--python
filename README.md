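# cobindkit

Toolkit for three complementary measurements of protein co-binding, of the
kind used to characterize the association between the chromatin insulator
CTCF and the mSWI/SNF (BAF/PBAF/ncBAF) chromatin remodeling complexes:

1. **Genomic co-occupancy** — do two chromatin factors bind the same sites?
   Replicate ChIP-seq peak lists are reduced to *consensus peaks* (regions
   common to all replicates, regions narrower than 5 bp discarded), the
   fraction of one factor's consensus peaks overlapping another's is
   reported, and CTCF-overlapping peaks are placed onto chromatin states
   derived from histone marks (active promoter = H3K4me3; active enhancer =
   H3K27ac ∩ H3K4me1; gene body = H3K36me3 ∩ H3K79me2; inactive enhancer =
   H3K9me3; inactive promoter = H3K27me3).
2. **AP-MS interactor filtering** — which proteins co-purify specifically?
   Scored peptide-spectrum matches (PSMs) from a concatenated target-decoy
   search get q-values via

   *FDR(s) = #{decoys ≥ s} / max(1, #{targets ≥ s})*,  *q(x) = min<sub>s ≤ x</sub> FDR(s)*,

   proteins are aggregated (mean distinct peptides and PSMs over replicate
   injections; protein q = best supporting-PSM q), classified high
   (q < 0.01) / medium (0.01 ≤ q < 0.05) / rejected, filtered against the
   IgG control IP and a contaminant list, and annotated against a packaged
   table of the 29 mSWI/SNF subunits (core / signature / accessory;
   BAF / PBAF / ncBAF membership).
3. **Binding affinity by BLI** — how tightly do two purified domains bind?
   Biolayer-interferometry interferograms are blank-subtracted (carrier
   protein at matched concentration), the plateau shift is read at 150 s,
   and the one-site binding isotherm *B(c) = B<sub>max</sub>·c / (K<sub>D</sub> + c)* is fit by
   nonlinear least squares to give the equilibrium dissociation constant.

All interval operations run on a self-contained 0-based half-open interval
algebra (`cobindkit.intervals`), cross-checked in the test suite against
per-base bitmap/all-pairs oracles and an independent ranges library.
Synthetic-data generators (`cobindkit.simulate`) provide ground-truth
inputs for every stage: peak sets with planted cross-factor overlap
fractions and replicate jitter, target/decoy score mixtures with known
null proportion, and 1:1 Langmuir interferograms with known K_D.

## Worked example

```python
from cobindkit import (PeakSimConfig, simulate_peakset, simulate_cofactor,
                       percent_overlap)

cfg = PeakSimConfig(n_peaks=10_000, overlap_fraction=0.20, seed=1)
ctcf = simulate_peakset(cfg)                  # 10,000 disjoint peaks, 100 Mb
cofactor, _ = simulate_cofactor(ctcf, cfg)    # 20% planted to overlap CTCF
report = percent_overlap(cofactor, ctcf, "cofactor")
print(f"{report.n_overlapping_ctcf}/{report.n_consensus} = {report.percent:.2f}%")
```

prints

```
2047/10000 = 20.47%
```

— 2,047 of the 10,000 cofactor peaks share at least one base with a CTCF
peak, i.e. the pipeline recovers the planted 20% overlap up to binomial
sampling spread (±3 SE ≈ ±1.2%). The `examples/` directory has one
narrative script per capability (`cooccupancy_demo.py`, `psm_fdr_demo.py`,
`bli_kd_demo.py`), each printing its results with an interpretation line.

A thin CLI wraps the same pipelines for shell use:

```bash
cobindkit simulate peaks --seed 1 --out sim/
cobindkit cooccupancy --ctcf sim/ctcf_rep1.bed,sim/ctcf_rep2.bed \
    --factor cofactor=sim/cofactor.bed --out report.tsv
cobindkit psm --psms psms.tsv --contaminants contaminants.txt --out interactors.tsv
cobindkit bli --manifest traces/manifest.tsv --out kd.tsv
```

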