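# Methods

## Network model and logical entities

The package operates on a self-contained network document: entities (genes,
proteins, complexes, chemically modified forms, metabolites), reactions
(direction, catalysts, transport and protein-binding flags), regulations
(transcriptional, translational, sigma-factor, substrate-level enzyme
modulation, cofactor; the latter two fixed to their defining sign where the
biology fixes it — cofactor and sigma-factor records are always positive)
and transcription units.

Search operates on *logical nodes*: a gene, its product and any
homomultimer of the product collapse to one node whose canonical id is the
gene's (the monomer's when no gene link exists; preference order gene >
monomer > complex makes display names gene-centric and deterministic).
Modified forms and heteromultimers are distinct nodes.  The entity schema
carries an explicit `product_of` link from protein to gene to drive this
coalescing, since the collapse cannot be inferred from names.  Homomultimer
detection is structural: a complex whose component list names exactly one
distinct entity.

Ubiquitous currency compounds generate no substrate edges in either role.
The flag is data (`ubiquitous` per entity); when absent it defaults from a
name list (water, ATP, ADP, AMP, phosphate, diphosphate, H+, NAD(H),
NADP(H), CO2, O2), because any fixed list is necessarily a stand-in — real
datasets should set the flag themselves.

## Influence edges and costs

Fourteen edge types connect an influenced entity X to an influencer I
(stored X→I, the search direction; influence runs I→X).  Costs follow the
specificity-weighted table in the README.  Decisions worth recording:

* Substrate counts |R<sub>·=sub</sub>| exclude the edge's own reaction
  ("other reactions"); enzyme/regulator counts do not, so an enzyme
  catalysing only its own edge's reaction counts 1 and the edge costs 1.05.
* For small molecules, protein-binding reactions are excluded both from the
  counts and from edge licensing: ligand binding changes the protein, not
  the free small-molecule pool.
* Reversible reactions count as both producing and consuming X; both edge
  variants are emitted with distinct provenance and **ambiguous** sign,
  since a reversible step can support either parity.
* |R<sub>I=transporter</sub>| is the number of transport reactions I
  catalyses (symmetric with the enzyme count); a transporter edge requires
  X to be in the reaction's transported set, and replaces the enzyme edge
  for that reaction.
* The 0.1 input-entity override applies to every type except
  transcription-unit edges, which stay at 0: the TU link is already free
  and the TU pseudo-node is never itself a user input.
* Default sign policy (replaceable as a table): production-side and
  transporter edges +, consumption-side −, product-of-consuming ambiguous,
  activator +, inhibitor −, cofactor +, sigma +, component +,
  transcriptional/translational per the regulation record, TU ambiguous.
  Only the regulation signs are data; the rest encode mass-action intuition
  and are deliberately a configuration, not a claim.
* Parallel edges between the same node pair with different types/provenance
  are all retained (one entity can act on another through several distinct
  mechanisms at once); iteration order is fixed by (type, provenance,
  target) for reproducibility.

## Phase 1 — building G1

Roots are the (coalesced) effect entities at cost 0.  A priority queue pops
the cheapest node, enumerates its influencers, and prices each edge.  A new
node is created only when C<sub>N</sub> + cost < C<sub>max</sub> (default
20, configurable); edges between two existing nodes are always recorded.
Each node keeps C (minimum cost to any root) and a per-root PC map; when a
relaxation improves any PC entry the improvement is propagated recursively
to already-stored descendants along strictly improving entries, which
guarantees termination (edge costs are non-negative and the only zero-cost
edges terminate in dead-end transcription-unit nodes, so no zero-cost
cycles exist).  Nodes whose C improves are re-inserted into the queue so a
late improvement can still create nodes near the cutoff.  Edges whose
target failed the creation test are deferred and re-examined once the
queue drains, because the target may meanwhile have been created through a
cheaper route; this makes the final graph — nodes, edges, C and PC — a
fixpoint independent of expansion and tie-breaking order (ties themselves
break on (cost, node id)).  The resulting invariants, verified against an
independent multi-source/single-source Dijkstra oracle: a non-root node
exists iff its multi-source distance over the full priced edge set is
below C<sub>max</sub>; its C equals that distance; its PC entries equal
per-root distances over the graph restricted to existing nodes.

Transcription-unit pseudo-nodes (undirected mode only) are created but
never expanded: they explain correlation between co-transcribed genes, not
causation, and deliberately dead-end.

## Phase 2 — filtering and scoring

Per (effect, condition) pair, all simple paths within `offset` of the
minimum pair cost are enumerated by depth-first traversal pruned with exact
remaining-distance bounds (a reverse Dijkstra from the terminus — an
admissible bound, so enumeration is exact).  Paths are simple at the
logical-node level: with non-negative weights a revisit can never lower
cost and only clutters diagrams.  The offset defaults to 2.0 — roughly two
extra unit-cost steps beyond optimal — and is configurable; the per-pair
budget defaults to 25 paths.  When a pair exceeds the budget the reduction
order is: parity filter first (when both directions were supplied), then
halve the offset repeatedly down to 0, then hard truncation of the sorted
list.  The minimum-cost path is never lost.

Parity is the product of edge signs with ambiguous absorbing; a path is
consistent when its parity matches the relation between the observed
condition and effect directions (+ = same way, − = opposite), and
ambiguous paths are always consistent.

Undirected scoring: every node with PC entries for ≥ 2 targets gets
score = Σ PC + 1.5 · C<sub>max</sub> per unreached target ("minimum path
length" is read as minimum path *cost*; hop counts appear nowhere in the
machinery).  Targets absent from a node's PC map are penalised — no
distinction is drawn between "unreachable" and "beyond the cutoff", which
is the only information the graph retains.  The greedy covering pass keeps
each influencer, in ascending score order, that adds at least one new
target; the cover is deliberately not minimal (better-scoring influencers
are preferred even when redundant) and may contain targets themselves.
The cover then becomes the condition set of a directed run.

## Phase 3 — explanation graph

Nodes of the filtered graph split into a metabolic group (reactant,
product or enzyme of a reaction underlying a kept edge) and a regulatory
group (everything else; a node qualifying for both goes to the metabolic
group, per the group definition — the regulatory connection survives as a
cross-component edge).  Each group splits into connected components under
the kept edges within the group.  Metabolic components become temporary
pathways: underlying reactions are chained by shared non-ubiquitous
substrates and each reaction is guaranteed a drawable substrate on both
sides — a primary substrate is one in the filtered graph or shared with an
adjacent reaction in the chain, and when a side has none, the
lexicographically first non-ubiquitous substrate is forced into the
display.  Enzymes and side metabolites outside the filtered graph are
recorded as suppressed.  Styling is a total function: one arrowhead class
per influence type, colour black for reaction-derived edges and by sign
for regulatory ones, node highlight classes for targets / covering-set
members / forced-in nodes, and direction-of-change classes when supplied.
Export formats are DOT, GraphML (via networkx) and a documented JSON
envelope, all byte-stable under re-export; pixel layout is left to the
rendering tool.  Subset reselection reruns Phases 2–3 against the cached
G1 without rebuilding it.

## Synthetic data

`generate_network` emulates the shape of a curated organism database at
desk scale: a metabolite pool with heavy-tailed (∝ 1/rank) reaction
participation so hub compounds exist and specificity weighting is
exercised; enzymes as gene+protein pairs with occasional homodimers,
heterodimers and phosphoforms; transport and protein-ligand-binding
reactions; transcriptional, translational, sigma-factor, modulation and
cofactor records; operon-like transcription units.  Defaults (24
metabolites, 20 reactions, 12 enzymes, 5 TFs, 3 TUs, 20% reversible, 10%
transport) give networks of ~60–70 entities — large enough that every
influence type occurs across a handful of seeds, small enough that
brute-force oracles stay exact and fast.  What it does **not** emulate:
realistic stoichiometry, compartments, the actual degree distribution or
regulon structure of a real organism, or kinetics.  Passing tests
therefore certify algorithmic correctness on structurally representative
inputs, not biological performance on real databases.

The fixed toy fixture preserves three relations of the classic worked
example for this class of tool (E1 catalyses M0→M1; TF0 represses TF1;
TF0 activates E5) and labels everything else as invented in its manifest;
tests assert only the labelled-published relations plus the fixture's own
documented structure.

`planted_path_network` realises a requested sequence of influence types as
a ground-truth path and adds decoy structure that cannot create
alternative routes between the endpoints (decoy clusters plus dead-end
influencers of path nodes; helper substrates are flagged ubiquitous so
they license no bypass edges).  Recovery of the planted path by the full
directed pipeline is a property of the package, checked at ≥ 95/100 seeds.

## Numerical choices and limitations

* Float comparisons use an absolute tolerance of 1e-9; queue ties break on
  node id; all exported artefacts sort their records.
* Costs are exact binary floats of the form k/20 or k/10 sums, so
  grid-formula tests use exact equality.
* The path enumerator carries a hard cap (default 20 000 found paths) as a
  safety valve on pathological graphs; the cap is reported via the
  truncation flag.
* No kinetic, stoichiometric or flux-based weighting; no learned edge
  weights; no compartment model beyond the transport flag; no import of
  BioCyc/SBML sources (noted as future work).  Influence scores compare
  only within one run: they depend on C<sub>max</sub> and the network's
  specificity counts.
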