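# simplicia

Higher-order structure of cortical connectomes: directed-simplex motifs in the
excitatory network and the positioning of inhibition within them.

## The scientific problem

Cortical excitatory connectivity is not a homogeneous random graph: it is
organized around *directed simplices* — motifs of d+1 neurons with a numbering
0..d such that a synaptic connection runs from every lower- to every
higher-numbered member. Position 0 is the motif's *source*, position d its
*target*; the motif is a densely connected feed-forward unit, and d is its
*dimension*. Electron-microscopic connectomes show far more high-dimensional
simplices than any distance-dependent or degree-preserving control, a divergent
"few sources, many targets" flow along them, and inhibitory interneurons that
attach to these motifs in specific sequential positions: excited by neurons
near the source, innervating neurons near the target, implementing symmetric,
targeted competition between motifs — moderated in turn by a disinhibitory
class of interneurons that preferentially inhibits the mediators.

`simplicia` implements this analysis chain as a tested, reusable library for
anyone studying connectome topology: neuron/synapse table ingestion, directed
flag-complex enumeration, the inhibition tensors and their reductions, all the
control models, simplex grouping, neighborhood complexity, and a
plasticity-inspired rewiring rule — together with a synthetic-connectome
generator reproducing the statistical structure these analyses assume, so every
stage is testable without downloading an EM dataset.

## The statistics at the core

For simplices of dimension d (S of them) and N_inh interneurons, two
S x (d+1) x N_inh synapse-count tensors M_ei and M_ie record connections from
the neuron at position j of simplex i to interneuron k, and back. Summing over
position gives M'_ei and M'_ie, and

    I = M'_ei · M'_ie^T

is the simplex-by-simplex matrix of **disynaptic inhibition** (synapse-weighted
E→I→E path counts). Its symmetry is scored as

    S = var(I − I^T) / var(I)        (off-diagonal entries)

which is 0 for a perfectly symmetric matrix and has expectation 2 when entries
(i,j) and (j,i) are independent. The null preserves every simplex's inhibitory
in/out totals by permuting the interneuron columns of M'_ei and M'_ie.
Disinhibitory candidates are flagged per interneuron j by the hypergeometric
survival probability of its outdegree onto other interneurons, d_j^inh, given
its total outdegree d_j^ttl and the pooled totals:

    p_j = 1 − HG(Σ_i d_i^ttl, Σ_i d_i^inh, d_j^inh − 1; n = d_j^ttl)

flagged at p_j ≤ 1e−6. An analytic reconstruction-error control uses the
expected maximal dimension ≈ −2·log(n)/log(p) of an Erdős–Rényi graph to ask
how dense a structureless graph would have to be to contain the observed
motifs.

## Worked example

```python
from simplicia.pipeline import AnalysisConfig, run_analysis

cfg = AnalysisConfig(seed=42, plant={"disinhibitory_fraction": 0.15}, max_dim=6)
res = run_analysis(cfg)
```

On the default synthetic slab (400 excitatory / 80 inhibitory neurons,
distance-dependent background plus 25 planted 5-dimensional motifs) this
prints, via the keys of `res`:

```
target dimension: 5
simplex counts: {0: 400, 1: 1372, 2: 550, 3: 384, 4: 155, 5: 26, 6: 0}
normalized unique fraction: [1.0, 1.3, 1.6, 1.9, 2.3, 2.6]
inhibitory in-degree by position:  [4.6, 6.1, 8.9, 20.0, 19.7, 20.1]
inhibitory out-degree by position: [13.2, 11.0, 9.3, 8.8, 5.9, 3.8]
disynaptic symmetry S: 1.21 | shuffled control: 1.75
corr(source overlap, I): 0.24 | corr(target overlap, I): 0.16
targeting-flagged fraction: 0.1375
```

Reading: divergence is strongest at dimension 5 (the *target dimension*) — 2.6x
more unique neurons at the target than at the source. Interneurons innervate
target-side neurons (in-degree rises 4.6 → 20.1 along the motif) and are
excited by source-side neurons (out-degree falls 13.2 → 3.8). The disynaptic
matrix is more symmetric than its degree-preserving shuffle (1.21 < 1.75 < 2),
its strength tracks source-side overlap more than target-side overlap, and
13.75% of interneurons are flagged as disinhibitory-targeting — recovering the
15% planted.

A CLI mirrors the library: `simplicia run --config cfg.yaml`, plus
`simplices`, `fit-dd`, `make-controls`, and `inhibition` subcommands over saved
HDF5 connectomes.

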