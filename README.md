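# endonet

Attractor-landscape analysis of signed molecular interaction networks.

Cell phenotypes — normal, malignant, differentiated, apoptotic — can be
understood as the *attractors* of a closed ("endogenous") regulatory
network: limited stable activity patterns picked out by the network's
feedback structure rather than by any designated input. `endonet` turns a
signed activation/inhibition wiring diagram into quantitative dynamics and
asks the questions this picture makes precise: Which attractors does the
wiring support? Which saddle points connect them? Which clamped
interventions (drug or genetic, held for a while and released) drive the
system from one attractor into another? And do the answers survive when
every interaction's parameters are randomized?

The motivating application is acute promyelocytic leukemia (APL), where a
leukemic attractor, a normal progenitor attractor and differentiated
attractors coexist on one network and differentiation therapy corresponds
to an induced attractor switch.

## Model

Each node activity is normalized to x_i ∈ [0, 1] and obeys

    dx_i/dt = f_i(x) − x_i

(unit-rate exponential self-degradation). The generation rate composes
saturating Hill terms: activating regulators are summed inside one Hill
function and inhibitors form a single repressive factor,

    f_i = [ S_A / (1 + S_A) ] · [ 1 / (1 + S_I) ],
    S_A = Σ_j (x_j / a_j)^{n_j}   over activators j,
    S_I = Σ_k (x_k / a_k)^{n_k}   over inhibitors k,

which for a single regulator reduces to the textbook forms
x^n/(aⁿ + xⁿ) and aⁿ/(aⁿ + xⁿ) (half-activity at the threshold a;
defaults n = 3, a = 0.5, overridable per edge). A node with no regulators
decays to zero; a node with only inhibitors is generated at full rate when
uninhibited. Since 0 ≤ f_i ≤ 1, the unit box is forward-invariant.

On top of this the package provides

* **fixed-point census** — attractors from random-start integration with
  basin tallies, plus saddle/unstable points from damped-Newton refinement,
  classified by the Jacobian spectrum (index 0 / 1 / ≥2);
* **Boolean cross-validation** — the discrete analogue (activators OR,
  inhibitors veto, synchronous or asynchronous), with exhaustive attractor
  enumeration up to 20 nodes;
* **transition landscape** — flows from each saddle's unstable directions
  down to attractors, attractor adjacency through shared saddles, and
  route finding between phenotypes;
* **perturbation protocols** — staged clamp-and-release switching
  experiments and exhaustive screens for minimal switching clamp sets;
* **robustness** — attractor recurrence statistics under random per-edge
  (n_i, a_i) resampling;
* **profiles** — >0.5 discretization (phenotype signatures), up/down
  differential calls, and concordance scoring against observed expression
  call tables.

## Worked example

```python
import endonet as en
from endonet import synthetic as syn
from endonet.fixed_points import enumerate_fixed_points, sample_attractors, census
from endonet.perturbation import perturbation_screen

net = syn.make_toggle_switch()              # A -| B, B -| A
atts = sample_attractors(net, None, n_starts=200, seed=1)
fps = enumerate_fixed_points(net, None, n_seeds=100, seed=1, attractors=atts)
print(census(fps))
for aid, fp in zip(atts.ids, atts.points):
    print(aid, fp.profile(), fp.state.round(4))

hits = perturbation_screen(net, None, "A2", "A1", max_set_size=1,
                           attractors=atts)
print(hits)
```

prints

```
{'attractor': 2, 'saddle': 1, 'unstable': 0, 'degenerate': 0}
A1 (0, 1) [0.1147 0.9881]
A2 (1, 0) [0.9881 0.1147]
[{'A': 0.0}, {'B': 1.0}]
```

The mutual-inhibition toggle is bistable: two mirror-image attractors
(one node high at 0.988, the other repressed to 0.115) separated by the
symmetric saddle at (0.5, 0.5). The screen reports the two minimal
interventions that switch the A-high cell state to the B-high one: fully
suppress A, or fully activate B, either held for the default 50 time
units and then released.

The same calls scale to the bundled 8-node miniature fate network
(`syn.make_miniature_fate_network()`, four attractors: two fates, an
apoptotic and a null state) and to any user-supplied network in the TSV
or JSON dialect. A transcription of the published 81-node APL network can
be dropped in at the path given by `endonet.datasets.apl_network_path()`
to unlock the APL-specific analyses.

Everything is also available from the shell:

```
endonet fixtures make toggle -o toggle.tsv
endonet attractors toggle.tsv --starts 200 --seed 1
endonet screen toggle.tsv --from A2 --to A1
```

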