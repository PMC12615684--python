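# grnclamp

Dual-framework simulation of perturbation-induced state transitions in gene
regulatory networks (GRNs), built around the epithelial–mesenchymal
transition (EMT) as the motivating system.

Cell-fate decisions such as EMT are governed by signed networks of mutually
inhibiting transcription factors and microRNAs whose dynamics settle into a
small number of stable expression states. A central question for both basic
biology and drug targeting is *which small perturbations — forcing one or two
genes on or off for a while — reliably flip the network from one stable state
to the other, and how much transcriptional noise helps.* `grnclamp` answers
this in silico with two complementary engines over the same topology:

- **Boolean spin model.** Gene states are spins $s_i = \pm 1$ on the signed
  interaction matrix $J_{ij}$ with pseudo-energy $E = -\sum_{ij} s_i J_{ij}
  s_j$. Random-sequential Metropolis updates flip spins with probability
  $\min(1, e^{-\Delta E/T})$, where $\Delta E = 2 s_i \sum_j J_{ij} s_j$ and
  the pseudo-temperature $T$ plays the role of transcriptional noise. Stable
  phenotypes are low-*frustration* states (few regulatory links violated);
  an *epithelial score* $\sum_i \sigma_i s_i$ over annotated marker genes
  ($\sigma_i \in \{-1, 0, +1\}$) calls states E or M.
- **Randomized ODE ensemble.** Many kinetic parameter sets are sampled for
  one topology (production $G \sim U[1,100]$, degradation $k \sim U[0.1,1]$,
  Hill coefficients $n \in \{1..6\}$, fold changes $\lambda$, half-functional
  thresholds), each gene following shifted-Hill dynamics
  $\dot A = \tfrac{G_A}{\prod_{\text{act}}\lambda} \prod_i \big(\lambda_i +
  \tfrac{1-\lambda_i}{1+(B_i/B^0_i)^{n_i}}\big) - k_A A$.
  Steady states found from random initial conditions are log-transformed,
  standardized, and clustered into E/M with a Gaussian mixture; models with
  exactly one stable state in each cluster ("E/M bistable") are the unit of
  the screens. Optional Ornstein–Uhlenbeck noise with correlation time
  $\tau$ and per-gene stationary s.d. $D \cdot \langle g \rangle$ enters the
  dynamics during the signal window.

A screening layer enumerates all 1- and 2-node *clamp* signals (binary
values in the Boolean model; target-state expression values in the ODE
model), measures per-signal transition efficacy, runs noise-only controls
and transition-time/noise-threshold analyses, and relates efficacy to group
betweenness centrality of the clamped nodes.

## Worked example

```python
import numpy as np
import grnclamp as gc

topo, anno = gc.make_toggle_switch()          # A <-| B, each self-activating
ens = gc.build_ensemble(topo, gc.EnsembleConfig(n_models=200, n_ics=60),
                        seed=1, e_marker="A")
clf = gc.StateClassifier.from_ensemble(ens, k=min(25, len(ens.processed)))
models = gc.classifier_consistent(ens.bistable(), clf)
proto = gc.ProtocolConfig(t_signal=100, t_relax=50)
rng = np.random.default_rng(2)
for sig in gc.enumerate_signals(topo):
    det = gc.signal_efficacy(models, sig, gc.OUNoiseSpec(D=0.0), proto, rng, topo, clf)
    noisy = gc.signal_efficacy(models, sig, gc.OUNoiseSpec(D=0.04), proto, rng, topo, clf)
    print(f"{sig}: {det:.0f}% deterministic, {noisy:.0f}% with noise")
```

prints (seed 1):

```
A: 100% deterministic, 100% with noise
B: 0% deterministic, 5% with noise
A+B: 100% deterministic, 100% with noise
```

Clamping the epithelial gene A at its mesenchymal (low) value destabilizes
the E state of every bistable toggle model (100%); clamping B on alone
leaves many models inside the E basin deterministically (0%), and a small
amount of transcriptional noise starts carrying some of them over the
barrier (5%) — the noise-amplification effect the package is built to
quantify. Clamping both genes forces the endpoint outright.

The `examples/` directory holds one short narrative script per capability:
Boolean clamp protocol, ODE ensemble bistability, the dual screen with
noise controls, and trajectory/centrality analysis. Each prints the numbers
it computes and one line on how to read them.

The `grn` command-line tool wraps the same library for file-based use:

```bash
grn make-fixture --kind random --nodes 8 --edges 20 --seed 4 --out net.topo
grn centrality --topo net.topo --genes G6
grn ode-states --topo net.topo --models 200 --ics 50 --e-marker G0 --seed 7 --out states.h5
grn ode-screen --states states.h5 --noise 0.04 --seed 11 --out efficacy.tsv
```

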