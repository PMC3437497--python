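# scfc — structure–function connectivity in Wilson–Cowan network models

`scfc` is a toolkit for studying how functional brain connectivity (FC, the
statistical dependence between regional activity time series) emerges from
structural connectivity (SC, the anatomical wiring between regions) in
networks of oscillatory neural populations — and, crucially, how that
relationship depends on the parameters of the *local* dynamics. It is aimed
at computational neuroscientists interested in mechanisms of FC breakdown
(e.g. in disease) that do not require any change of the anatomical substrate.

## The model

Each cortical area is a Wilson–Cowan node, two interacting populations with
activities $u_i$ (excitatory) and $v_i$ (inhibitory):

$$
\dot u_i = -u_i + f\Big(c_1 u_i - c_2 v_i + P + \varepsilon \sum_j w_{ij} u_j\Big) + \sigma\,\xi_i(t),
\qquad
\dot v_i = -v_i + f\big(c_3 u_i - c_4 v_i + Q\big),
$$

with the logistic firing rate $f(x) = 1/(1+e^{-x})$, constants
$c_1=c_2=c_3=10$, $c_4=-2$, background inputs $P, Q$, and coupling weights
$w_{ij} = b_{ij} / \sum_k b_{ik}$ row-normalized from a binary directed
adjacency $b$ ($b_{ij}=1$: link from node $j$ to node $i$). Depending on
$(P,Q)$ a node is quiescent or oscillates; the oscillation is born on a Hopf
curve, and rest states merge along saddle-node curves.

The package implements the full analysis chain:

- **node_model** — fixed points, linear stability, Hopf / saddle-node loci in the $(P,Q)$ plane;
- **connectome** — modular matrices, a seeded synthetic cortex-like fixture,
  Maslov–Sneppen degree-preserving rewiring, dense/edge-list text I/O;
- **simulate** — Euler–Maruyama integration of the coupled stochastic network;
- **fc_measures** — Pearson correlation and mean phase coherence
  $R_{ij} = \big|\langle e^{\,i(\phi_i(t)-\phi_j(t))}\rangle_t\big|$ via the Hilbert transform;
- **netmetrics** — density-matched binarization, path length $L$, clustering $C$,
  Erdős–Rényi references, small-world index $\gamma/\lambda$, Jaccard SC–FC agreement;
- **phase_reduction** — limit cycle, adjoint (phase-response) vector, phase
  interaction function $H(\theta)$ and its slope $H'(0)$, synchrony Jacobian
  $\varepsilon H'(0)\,(w_{ij} - \delta_{ij}\sum_k w_{ik})$;
- **sweep** — parameter-plane experiments tiling all of the above, with a CLI.

The theoretical centrepiece: for weak coupling each oscillating node reduces
to a phase $\theta_i \in [0,1)$ obeying
$\dot\theta_i = 1/T + \varepsilon \sum_j w_{ij} H(\theta_j - \theta_i)$.
The synchronous state is stable iff $H'(0) > 0$, so wherever $H'(0) > 0$ in
the $(P,Q)$ plane, structurally linked nodes synchronize and FC mirrors SC;
where $H'(0) < 0$, synchrony breaks down and FC decouples from the substrate.

## Worked example

```python
from scfc import NodeParams, SimConfig, modular_sc, integrate, drop_transient
from scfc import mean_phase_coherence_fc, binarize_to_density, jaccard_similarity
from scfc.phase_reduction import hprime_at
from scfc.netmetrics import BinaryNetwork

for (P, Q) in [(-2.5, -8.5), (-1.5, -6.0), (2.5, -3.5)]:
    print(f"H'(0) at (P={P}, Q={Q}): {hprime_at(P, Q):+.4f}")

sc = modular_sc(3, 4)                      # 3 modules of 4, fully connected inside
und = sc.undirected()
density = und.sum() / (sc.n * (sc.n - 1))
for (P, Q) in [(-1.5, -6.0), (-2.5, -8.5)]:
    cfg = SimConfig(epsilon=0.5, noise_sigma=0.01, t_total=3000.0, t_transient=300.0, seed=0)
    ts = drop_transient(integrate(sc, NodeParams(P=P, Q=Q), cfg))
    fc = mean_phase_coherence_fc(ts)
    j = jaccard_similarity(binarize_to_density(fc, density), BinaryNetwork(und))
    print(f"SC-FC Jaccard (mean phase coherence) at (P={P}, Q={Q}): {j:.3f}")
```

prints

```
H'(0) at (P=-2.5, Q=-8.5): -0.0817
H'(0) at (P=-1.5, Q=-6.0): +0.0428
H'(0) at (P=2.5, Q=-3.5): -0.0817
SC-FC Jaccard (mean phase coherence) at (P=-1.5, Q=-6.0): 1.000
SC-FC Jaccard (mean phase coherence) at (P=-2.5, Q=-8.5): 0.286
```

Interpretation: at $(-1.5, -6)$ the pairwise synchronous state is stable
($H'(0)>0$), every module phase-locks internally, independent modules
decohere, and the binarized FC reproduces the modular SC exactly (Jaccard 1).
At $(-2.5, -8.5)$ synchrony is unstable ($H'(0)<0$) and the agreement falls
to the chance level of an equal-density random graph (≈ 0.16 ± 0.06 here).

The same chain is scriptable from a shell:

```
scfc sweep --sc modular:3x4 -o records.csv
scfc compare --records records.csv
scfc hprime-map --resolution 13 -o hprime.txt
```

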