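# edgotype

Tools for asking a blunt question about protein–protein interaction (PPI)
networks: **what fraction of a cell's interactome is completely dispensable**
— a true physical interaction whose loss has no measurable fitness effect?

The package is aimed at structural systems biologists. It builds a
*structural interactome* (PPIs with residue-level binding interfaces resolved
from chain-pair structures via sequence alignments), maps curated missense
mutations onto it, classifies each mutation's *edgotype* (which PPIs it
disrupts), and turns the resulting edgetic rates into a Bayesian estimate of
dispensable PPI content with a confidence interval.

## The model

A new missense mutation is effectively neutral (N), mildly deleterious (M)
or strongly detrimental (S) with prior probabilities P(N) = 0.27,
P(M) = 0.53, P(S) = 0.20 (population-genetic estimates). Common variants
from healthy individuals proxy class N, Mendelian disease mutations proxy
class M, and class S mutations are assumed quasi-null (destabilizing the
whole protein) rather than edgetic, so P(E|S) = 0. Measuring the edgetic
rates P(E|N) = k_N/n_N and P(E|M) = k_M/n_M on a structural interactome
gives

    P(E)   = P(E|N)·P(N) + P(E|M)·P(M) + P(E|S)·P(S)
    P(N|E) = P(E|N)·P(N) / P(E)

and P(N|E) — the probability that an edgetic disruption is neutral — is the
dispensable fraction of the interactome. Its 95% CI comes from the log-scale
(Katz) interval for the rate ratio P(E|M)/P(E|N), mapped through
`1/P(N|E) = r·P(M)/P(N) + 1`.

Edgotypes are called two ways:

* **geometry** — a mutation disrupts a PPI iff it sits on the interface
  mediating that PPI (interface residue: minimum inter-atomic distance to
  the partner chain ≤ 5 Å);
* **physics** — an interfacial mutation disrupts a PPI iff its binding
  free-energy change ΔΔG > 0.5 kcal/mol (ΔΔG tables are consumed, not
  computed).

A fully synthetic world generator (`edgotype.synthetic`) emulates every
input — coordinates, alignments, interactome, mutation tables, ΔΔG tables,
GO/expression side tables — with known ground truth, so the entire pipeline
is testable without downloading anything.

## Worked example

```python
from edgotype import DispensabilityModel, EdgeticCounts

# geometry-based edgetic tallies on a Y2H-derived structural interactome:
# 19/376 non-disease and 27/145 disease mutations are edgetic
model = DispensabilityModel(EdgeticCounts(k_N=19, n_N=376, k_M=27, n_M=145))
print(model.fit().summary())
```

```
Dispensable PPI content estimate
================================================
variant:               standard
edgetic non-disease:   19 / 376  (P(E|N) = 0.0505)
edgetic disease:       27 / 145  (P(E|M) = 0.1862)
priors P(N)/P(M)/P(S): 0.27 / 0.53 / 0.20
------------------------------------------------
P(E)    =  11.2 %
P(N|E)  =  12.1 %
95% CI  =   7.4 - 19.4 %   (z = 1.96)
```

Read: a new missense mutation has an 11.2% chance of being edgetic, and an
edgetic disruption is effectively neutral 12.1% of the time — i.e. about
12% (7–19%) of this interactome is dispensable.

The same end-to-end flow on synthetic data:

```python
from edgotype import SyntheticWorldConfig, generate_world, analyze_world

world = generate_world(SyntheticWorldConfig(seed=1))
analysis = analyze_world(world, method="geometry")
print(analysis.counts)                  # EdgeticCounts(k_N=27, n_N=376, k_M=25, n_M=145)
print(analysis.results.p_dispensable)   # dispensable fraction on this world
```

Shell users get the same stages as commands: `synth-world`, `build-si`,
`map-mutations`, `edgotype`, `dispensable`, `qc-si` (see `--help` on each).

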