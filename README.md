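# minnet — minimal metabolic network design and analysis

`minnet` is a toolkit for systems and synthetic biologists who want to
strip a genome-scale metabolic model down to a minimal gene set while
preserving near-wild-type growth, and to understand which genes such
minimisations can never discard.

Starting from a constraint-based model (SBML Level 3 + FBC, or
COBRA-style JSON) the pipeline:

1. evaluates gene deletions through gene–protein–reaction (GPR) logic
   and Flux Balance Analysis — maximise `v_bio` subject to `S·v = 0`
   and flux bounds;
2. runs an **evolutionary search** over deletion states that maximises
   the number of knockouts subject to
   `v_bio ≥ f · v_bio(wild type)` (f = 0.99 or 0.90), using
   Hamming-distance domination fronts (`p` dominates `q` iff
   `Ham(p,q) = 1` and `nKO(p) = nKO(q)+1`), diversity preservation,
   age-based logistic discard and backtracking; every returned
   **minimal metabolic network (MMN)** is certified by exhaustively
   testing all single-knockout extensions;
3. designs **minimal growth media** by randomised removal of exchange
   inputs with an exhaustive fallback, then narrows each uptake bound
   to the minimum magnitude supporting the optimum;
4. analyses MMN collections: per-gene retention fractions (*NED
   degree*), classification of **NED genes** (non-essential genes
   retained in >95% of MMNs), pairwise shared-reaction similarity;
5. quantifies a gene set's structural importance by the
   Latora–Marchiori **global efficiency**
   `E(G) = (1/(N(N−1))) Σ_{i≠j} 1/d_ij` of the bipartite
   metabolite–reaction graph (optionally pFBA-flux-weighted), with
   Monte-Carlo removal experiments, degree/betweenness statistics and
   power-law ML fits.

Deletable-state spaces are astronomically large at genome scale (976
deletable genes ⇒ 2⁹⁷⁶ ≈ 10²⁹³ states), which is why the search is
evolutionary; on small synthetic models the package ships an
exhaustive oracle that the search is validated against exactly.

## Worked example

The package generates its own toy fixtures. `TOY1` is a linear chain
`A_e → A → B → C → biomass` (uptake and transport capped at
10 mmol/gDW/h) with parallel isoenzymes g1/g2 on A→B, a complex
"g3 and g4" on B→C and a transporter gene gT:

```
$ minnet make-fixtures --out models
$ minnet minimise --model models/TOY1.json --pop-size 10 \
      --generations 30 --seed 11 --out run1
2 MMNs written to run1
```

`run1/mmns.json` holds the two certified minimal networks — exactly
the two single knockouts that the exhaustive enumeration of all 32
deletion states finds (deleting either isoenzyme, never both, and
never the transporter or a complex subunit):

```
deleted        retained                growth
['g2']         ['gT','g1','g3','g4']   10.0
['g1']         ['gT','g2','g3','g4']   10.0
```

`run1/ned_report.csv` gives each gene's retention fraction across the
collection and its class — gT/g3/g4 are retained in both MMNs
(NED genes at the 0.95 threshold), g1/g2 in half:

```
gene,retention_fraction,essential,is_ned,gene_class
gT,1.0,False,True,always_active
g1,0.5,False,False,variable
g2,0.5,False,False,variable
g3,1.0,False,True,always_active
g4,1.0,False,True,always_active
```

Minimal-medium design on `TOY2` (which has two redundant carbon
sources) keeps exactly one exchange open and narrows its uptake bound
from the unconstrained 1000 to the 10 units the network actually
needs at its optimum:

```
$ minnet media --model models/TOY2.json --min-growth 1.0 --seed 5 \
      --out medium.tsv
medium with 1 open exchanges written to medium.tsv (seed=5)
$ cat medium.tsv
exchange_id	lower_bound
EX_A	-10
```

Removing the two isoenzymes from TOY1 disconnects the graph downstream
of A and lowers its global efficiency:

```
$ minnet netstats --model models/TOY1.json --remove g1 --remove g2 \
      --out stats.json
$ cat stats.json
{"baseline_efficiency": 0.2073..., "removal_efficiency": 0.1398...}
```

The same operations are available as a library
(`minnet.minimise`, `minnet.design_minimal_medium`,
`minnet.graphs.monte_carlo_removal`, …); see `docs/methods.md` for the
model, the algorithm and every numerical choice.

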