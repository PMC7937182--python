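# Methods

## Model and assumptions

The pipeline infers the relative order in which binary traits emerged on a
rooted species phylogeny under a single-gain, multiple-loss model. The
assumptions are:

1. **Single origin.** Each trait arose exactly once. This is defensible
   for complex traits built from many coordinated genes, whose de novo
   assembly (or functional arrival by lateral transfer) is rare; it is not
   appropriate for simple or frequently transferred characters. The CI/RI
   diagnostics quantify how well each trait's distribution fits this
   assumption after the fact.
2. **Irreversible-loss explanation of absences.** Species inside a trait's
   origin clade that lack the trait are explained by losses; losses carry
   no penalty and are not themselves modeled.
3. **Vertical inheritance.** Origins are assigned by ancestry alone. The
   generator can inject lateral-transfer gains precisely to probe what the
   diagnostics report when this assumption is violated.

### The origin-node rule

The origin of a trait is the MRCA of all species bearing it (bearers with
missing state `?` are treated as unobserved and excluded, so missingness
never pulls an origin rootward). The verbal rule "the most recent node
where the trait is present in any descendant", read literally, is satisfied
by every ancestor of any single bearer; the MRCA of *all* bearers is the
only reading consistent with a single origin followed by losses, and is
what this package implements.

Order relations between two origins: identical node → simultaneous (at the
resolution of the current taxon sample); ancestry → the ancestral node's
trait emerged earlier; otherwise non-nested. Non-nested pairs contradict a
totally ordered emergence history; they are reported as a first-class
result list rather than treated as an error, because loss noise or genuine
independent origins can produce them.

### Parsimony and CI/RI

Step counts use Hartigan's generalization of Fitch parsimony, exact on
multifurcating trees: at each internal node the children vote with their
optimal state sets, and a node with `K` votes for the best state
contributes `(#children − K)` changes. Missing leaves carry the full state
set {0,1}. The count is root-invariant (verified by re-rooting in tests),
so the rooted implementation matches any unrooted convention. For a binary
trait, `m = 1` when variable else 0, and `g = min(#0s, #1s)` over observed
leaves (the star-topology step count). `CI = m/s` is undefined for
invariant traits (`s = 0`); `RI = (g−s)/(g−m)` is undefined when `g = m`
(e.g. a single-bearer trait). Medians are computed over the traits where
the index is defined, and the excluded traits are listed alongside.

### Gene-tree concordance

A gene tree votes on a trait pair only when it carries at least two
bearers of each trait (one bearer cannot define a clade within the tree).
Origins inside the gene tree use the same MRCA rule restricted to the gene
tree's leaves. Agreement is exact relation equality by default (a
simultaneous species-tree pair must be simultaneous in the gene tree). How
to score a gene tree whose resolution differs — a non-nested gene relation
against a nested species relation — is genuinely open; the default
(strict) counts it as disagreement, matching "the order is the same";
`mode="lenient"` instead removes such votes from the denominator. The
taxon-exclusion rerun prunes a named clade from every gene tree before
evaluation and re-checks evaluability, supporting long-branch-attraction
sensitivity analyses.

### Root census

Per gene tree: (1) discard when the outgroup leaves present in the tree do
not form a single partition of the unrooted topology (reason
`outgroup_split`; trees containing no outgroup leaf are likewise
unrootable and fall in this category); (2) root on the outgroup and strip
it; (3) discard when any named group has fewer than `min_per_group = 2`
members (reason `min_group_count`) — the requirement applies to *every*
group, and the outgroup filter is applied first, matching the narrative
order of the analysis it reproduces; (4) classify: basal if no group spans
the root and exactly one side is single-group; ancestral if exactly one
group spans the root; ambiguous otherwise. Two defensive sub-cases are
labeled ambiguous with a note: a multifurcating ingroup root (root "sides"
undefined; cannot arise from the binary simulator), and two single-group
sides with different groups (possible only when two groups survive
filtering, where "basal" is not well defined).

## Synthetic data

The generator emulates the *shape* of a phylogenomic trait survey, with
defaults at the scale of a large cyanobacterial dataset: 199 ingroup
species, 21 traits, 553 gene trees, a 6-taxon outgroup, three named
ingroup groups.

* **Species tree**: Yule (pure-birth) topology with exponential waiting
  times, the simplest defensible random-tree model here since branch
  lengths are never used downstream. The draw is repeated (with a bumped
  substream) until all three groups derived from the root split have at
  least two members, so census runs are informative; attempts are logged.
* **Traits**: origin nodes are spread evenly along the root-to-deepest-leaf
  backbone, giving a nested (totally ordered) truth with blocks when
  traits outnumber backbone nodes. Below the origin, each edge loses the
  trait independently with `loss_prob = 0.05` by default (the mild-noise
  regime the recovery tests target); draws leaving no bearer are resampled
  and counted. An optional lateral gain (`lgt_prob`, default 0 — the
  model assumes vertical inheritance) grafts presence onto one clade
  disjoint from the origin; the origin's sole sibling is excluded as a
  graft target because the union would fuse into a single clade and carry
  no homoplasy signal.
* **Gene trees**: species-tree copies with leaves kept at
  `retention_prob = 0.9` (redrawn under 4 survivors), `n_nni = 1` random
  nearest-neighbor interchanges (small, composable perturbations whose
  count maps smoothly onto disagreement rates), and a pectinate outgroup
  clade attached as sister to the ingroup so rooting machinery runs end to
  end. Branch lengths are not propagated.
* **Determinism**: one master seed feeds per-component substreams
  (tree / traits / gene trees), so changing the number of gene trees does
  not alter the trait matrix, and a manifest re-run is byte-identical
  (SHA-256 checksums recorded).

What the generator does **not** emulate: sequence evolution, alignment
error, heterogeneous gene-tree error correlated with alignment length,
paralogy/incomplete lineage sorting, and non-monophyletic outgroups in
gene trees (outgroup-split discards are exercised with constructed
fixtures instead). Passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated model, not
robustness to every failure mode of real phylogenomic data.

## Numerical and design choices

* Missing trait states get the full state set in parsimony and are
  excluded from presence sets and evaluability counts — standard ambiguity
  handling.
* Rooting on an edge splits its branch length equally between the two new
  root edges; lengths are otherwise inert, so any deterministic convention
  suffices. Already-correctly-rooted input is returned unchanged.
* Blocks with a common origin are emitted in input-column order (the
  intra-block order carries no information); block sorting ties on equal
  depth break by node id for determinism.
* Opposite-coded trait pairs (e.g. unicellular vs filamentous) are kept as
  independent columns; no complementarity constraint is imposed.
* Traits absent from every species are an error by default
  (`skip_absent=True` / `--skip-absent` downgrades to a logged skip).
* MRCA queries run on precomputed leaf-set bitmasks (a scan over nodes per
  query), which keeps the 553-gene-tree × 21-trait concordance pass fast
  in pure Python; the test suite checks it against an independent
  path-intersection oracle.

## Problem sizes in tests and the acceptance script

Unit and property tests run on trees of 4–64 leaves; parsimony is verified
against exhaustive enumeration on 200 random instances with ≤ 7 internal
nodes. The acceptance script uses the full study-scale default
configuration once, a 32-species noise-free configuration for exact
recovery, and 20-seed sweeps at 24–32 species for the recovery rate and
the NNI degradation trend — sizes chosen so the whole script completes in
about a minute while keeping the multi-seed estimates stable.

## Known limitations

* The origin-node rule is conservative: losses that erase an entire child
  clade of the true origin pull the inferred origin tipward, and nothing
  in the data can distinguish that from a genuinely later origin.
* CI/RI are descriptive indices, not tests; no null distribution is
  attached.
* Simultaneity is relative to the taxon sample: denser sampling can split
  a block.
* The census presumes a bifurcating ingroup root; polytomous roots are
  reported ambiguous rather than resolved.
* No probabilistic ancestral-state reconstruction, no divergence dating,
  no tree inference: the species and gene trees are inputs.
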