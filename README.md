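# netten

Global exploration of personalized gene regulatory networks: per-sample
network inference, supervised orthonormal tensor subspace learning, and
differential-network interpretation.

## The problem

Sample-specific (personalized) gene regulatory networks assign every sample —
a patient, a cell line — its own network of regulator → target coefficients,
indexed by a scalar clinical characteristic such as an
epithelial–mesenchymal-transition (EMT) score. A panel of hundreds of samples
therefore yields hundreds of networks, each with thousands of genes: a
third-order tensor (targets × regulators × samples) far too large to read
edge by edge. `netten` implements a two-stage strategy for analysing such
multilayer networks globally, plus the downstream statistics that turn the
fitted model into biology: differential-network markers, regulatory effect
changes and tissue associations.

## The model

**Stage 1 — per-sample network inference.** For target gene *l* and sample
*α* with modulator value *m<sub>α</sub>*, the varying-coefficient model

> Y<sub>l</sub> = Σ<sub>j</sub> β<sub>jl</sub>(m<sub>α</sub>) X<sub>j</sub> + ε<sub>l</sub>

is fitted by minimizing the kernel-weighted penalized loss

> ½ Σ<sub>i</sub> G(m<sub>i</sub> − m<sub>α</sub> | b) (y<sub>il</sub> − β₀ − Σ<sub>j</sub> β<sub>jl</sub> x<sub>ij</sub>)² + P(β),
> with G(d | b) = exp{−d²/b},

so only samples with similar modulator values inform sample *α*'s network.
P is a recursive (adaptive) elastic net: a standard elastic-net round
followed by re-fits with per-coefficient weights 1/(|β̂| + δ), which
de-biases strong edges while keeping absent edges at exactly zero. Stacking
all fits gives the network tensor, with each sample's slice one network.

**Stage 2 — supervised tensor subspace learning.** Orthonormal mode-wise
projections C⁽¹⁾ (targets) and C⁽²⁾ (regulators) map each network to
X̄<sub>i</sub> = C⁽¹⁾ᵀ X<sub>i</sub> C⁽²⁾, from which a small head predicts
the response y<sub>i</sub>. Projections and head minimize jointly

> O = (1/n) Σ<sub>i</sub> { L(y<sub>i</sub>, ŷ<sub>i</sub>) + γ ‖X<sub>i</sub> − C⁽¹⁾ X̄<sub>i</sub> C⁽²⁾ᵀ‖²<sub>F</sub> },  subject to C⁽ᵏ⁾ᵀC⁽ᵏ⁾ = I,

where orthonormality is enforced via the SVD polar factor of a latent matrix
Z⁽ᵏ⁾ (Z = P S Qᵀ ⇒ C = P Qᵀ). A rank-one multi-linear surrogate
ŷ′<sub>i</sub> = ⟨g⁽¹⁾∘g⁽²⁾, X̄<sub>i</sub>⟩ + b is fitted to the head's own
predictions; contracting each network with the other mode's projection and
surrogate factor gives per-sample vectors u<sub>i</sub>⁽ᵏ⁾ whose principal
components are the *crucial components* — the interpretable axes of network
variation relevant to the response.

**Stage 3 — interpretation.** Samples are split into high/low regions of a
component score; each region's networks collapse to a binary adjacency (edge
= nonzero coefficient in ≥ 1 sample); genes are ranked by incident edges
differing between regions (top-10 = markers). Edge strength is summarized by
the regulatory effect RE<sub>jlα</sub> = β̂<sub>jl</sub>(m<sub>α</sub>)·x<sub>αj</sub>
and its modulator dependence by REC<sub>jl</sub> = max<sub>α</sub> RE − min<sub>α</sub> RE;
PCA of the REC matrix groups markers, and Pearson χ² tests relate region
membership to tissue of origin.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/04_markers_and_rec.py` plants three regulators whose edges
switch on with the modulator among twelve background regulators, runs the
full chain, and prints:

```
planted switched regulators: ['R001', 'R002', 'R010']
|corr(component 1, modulator)| = 0.905
top-10 differential markers: ['R010', 'R001', 'R002', 'T002', 'T015', 'T017', 'T025', 'R000', 'R006', 'T001']
planted regulators recovered: 3/3
mean REC of planted vs background regulators: 1.477 vs 0.523
tissue association chi-squared = 11.2, p = 8.09e-04 ***
```

The first extracted component tracks the modulator, all three planted
regulators top the differential-adjacency marker ranking, and their REC
values (the range of realized edge effects across samples) are about three
times those of modulator-independent background edges — exactly the
signature a modulator-switched regulator should leave.

The other scripts show the synthetic generator (`01`), the per-sample kernel
fits localizing a step edge while keeping absent edges at exactly zero
(`02`), and subspace learning on planted low-rank tensors (`03`), where the
reported relative reconstruction error on noisy slices sits at the noise
floor while the planted signal subspace is recovered almost exactly.

A command-line interface mirrors the stages:

```sh
netten simulate --n 60 --targets 20 --regulators 10 --out data.tsv
netten infer --expression data.tsv --out tensor.h5
netten decompose --tensor tensor.h5 --j1 5 --j2 5 --out model.h5
netten components --model model.h5 --tensor tensor.h5 --out scores.tsv
netten run --outdir run/          # full pipeline with a manifest
```

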