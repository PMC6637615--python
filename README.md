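# metreg

Mechanistic path-of-influence search in combined metabolic and regulatory
networks.

High-throughput omics experiments surface associations between genes,
proteins and metabolites whose mechanistic link is not obvious: a knocked-out
kinase raises the level of a metabolite five interaction steps away, or
twenty co-varying genes turn out to share a single upstream regulator.  In a
well-curated organism most such associations are explainable from existing
knowledge — if someone traces the chain of reactions, transporters, enzyme
cofactors, substrate-level activation/inhibition and transcriptional or
translational regulation that connects them.  `metreg` automates that
tracing for biologists and bioinformaticians who have (i) a machine-readable
metabolic + regulatory network and (ii) small sets of entities of interest.

Two modes are supported:

* **directed** — the user supplies *condition* entities (deliberately
  perturbed: knockouts, supplied nutrients) and *effect* entities (observed
  to change); the tool finds low-cost paths by which each condition can
  influence each effect.
* **undirected** — the user supplies a single *effects* set; the tool finds
  *influencers*, entities with paths to two or more of the effects, that can
  explain why they co-vary, and reduces the problem to directed mode by
  positing a greedy covering set of influencers as conditions.

## The model

The network is compiled into a weighted influence graph G1, explored outward
from the effect entities by a priority-queue (Dijkstra-style) search up to a
cost cutoff *C*<sub>max</sub> (default 20).  A gene, its product and any
homomultimer of the product are coalesced into one logical node; chemically
modified forms and heteromultimeric complexes stay distinct.  Each edge
records one influence of *I* on *X* and is priced by type and *specificity*
— how many reactions or genes the participants touch — so that hub
metabolites and global regulators price high:

| influence of *I* on *X*                | cost                                        |
|----------------------------------------|---------------------------------------------|
| reactant of reaction producing *X*     | 1 + (\|R<sub>X=sub</sub>\| + \|R<sub>I=sub</sub>\|)/20 |
| reactant of reaction consuming *X*     | 1 + (\|R<sub>X=sub</sub>\| + \|R<sub>I=sub</sub>\|)/10 |
| product of reaction consuming *X*      | 2 + (\|R<sub>X=sub</sub>\| + \|R<sub>I=sub</sub>\|)/10 |
| enzyme of reaction producing *X*       | 1 + \|R<sub>I=enz</sub>\|/20                |
| enzyme of reaction consuming *X*       | 2 + \|R<sub>I=enz</sub>\|/20                |
| transporter of *X*                     | 1 + \|R<sub>I=transporter</sub>\|/20        |
| activator/inhibitor of enzyme *X*      | 1 + \|Enzs<sub>I=modulator</sub>\|/20       |
| cofactor of enzyme *X*                 | 1 + \|Enzs<sub>I=cofactor</sub>\|/20        |
| transcriptional/translational regulator| 1 + (\|Regs<sub>X</sub>\| + \|G<sub>I=reg</sub>\|)/20 |
| sigma factor for transcription of *X*  | 1 + \|G<sub>I=reg</sub>\|/20                |
| component of protein complex *X*       | 0.1                                         |
| transcription unit of gene *X*         | 0 (undirected mode only; dead end)          |

Substrate counts exclude the edge's own reaction; ubiquitous compounds
(water, ATP, ...) generate no substrate edges; consumption-side costs exceed
production-side costs to favour upstream explanations.  An influencer that
is itself one of the input entities always costs 0.1.

Phase 2 enumerates, per (effect, condition) pair, every simple path within
an offset (default 2.0) of the minimum path cost, optionally filtered by
*parity* — the product of edge signs, which must match the observed
directions of change (edges through reversible reactions support either
parity).  In undirected mode each node reaching ≥ 2 targets is scored

&nbsp;&nbsp;score(N) = Σ<sub>t reached</sub> PC(N, t) + 1.5 · C<sub>max</sub> · #unreached,

lower is better, and a greedy covering set over the ascending ranking
becomes the condition set.  Phase 3 partitions the kept paths into metabolic
and regulatory connected components, assembles display-time "temporary
pathways" (forcing in primary substrates a reaction needs to be drawable,
suppressing side metabolites), and exports a styled explanation graph as
DOT, GraphML and/or JSON.

## Worked example

The bundled toy fixture (`tests/data/toy_network.json`, also available as
`metreg.toy_network()`) has five enzyme-catalysed reactions and three
transcription factors; TF0 activates expression of enzyme E5, which produces
metabolite M0.  Ask how perturbing TF0 (down) explains a rise in M0:

```sh
metreg explain --network toy.json --targets targets.tsv \
    --offset 3.0 --out-dir out
cat out/paths.txt
```

```
== effect M0 <- condition gTF0 (2 path(s))
  cost 1.150  parity +  inconsistent: M0 -[enzyme-of-producing,+]-> gE5 -[transcriptional-regulator,+]-> gTF0
  cost 3.200  parity -  consistent: M0 -[reactant-of-producing,+]-> M5 -[enzyme-of-consuming,-]-> gE5 -[transcriptional-regulator,+]-> gTF0
```

Reading the first line right to left: TF0 activates expression of E5's gene
and E5 produces M0 — an all-activating (parity +) route, costing 1.05 for
the enzyme edge (E5 catalyses one reaction: 1 + 1/20) plus the flat 0.1
because TF0 is an input entity.  A positive-parity path cannot explain a
*down* condition producing an *up* effect, so it is flagged inconsistent;
the second, negative-parity route (TF0 ⟶ E5 ⟶ consumption of M5, a
precursor of M0) is consistent with the observed directions.

Undirected mode on the three co-varying enzyme genes gE2, gE3, gE5 ranks
common influencers (`out/influencers.tsv`):

```
rank  entity  score    n_reached  targets        top_ten
1     gTF0    5.7500   3          gE2;gE3;gE5    1
2     tu1     30.0000  2          gE2;gE3        1
3     gTF1    32.3000  2          gE2;gE3        1
```

TF0 reaches all three targets (score = 1.15 + 2.30 + 2.30, no penalty) and
alone forms the covering set; the transcription unit tu1 explains the
gE2/gE3 correlation at zero path cost but pays one unreached-target penalty
(1.5 × 20 = 30).

## Network format

A single JSON document with `entities`, `reactions`, `regulations`,
`transcription_units` and `meta` arrays (see `metreg/network_model.py` and
the bundled toy fixture for the field-level layout).  `metreg generate`
writes synthetic networks in this format; `metreg validate` checks a file;
`metreg export` dumps per-table TSVs.  Import from external database
formats (BioCyc, SBML) is out of scope.
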