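# orbitcount

Incremental counting of 2–5-node graphlet and orbit occurrences in undirected
networks under single-edge additions and removals, plus evolving random-network
generators and a graphlet-redundancy criterion for growing ranked
gene-regulatory networks.

When one edge of a network changes, only the subgraphs touching that edge
change. `orbitcount` exploits this: it enumerates, exactly once, every
connected 2–5-node set containing both endpoints of the modified edge
(necessarily within depth 3 of the edge), classifies each set's induced
subgraph with and without the edge through a precomputed edge-mask lookup
table, and emits a sparse signed delta matrix. Accumulating deltas reproduces
a full static recount exactly while visiting orders of magnitude fewer
subgraphs on large networks.

## Modules

| module | contents |
| --- | --- |
| `orbitcount.taxonomy` | the 30 graphlet / 73 orbit catalogue, computed by canonical-form enumeration; edge-mask encoding; per-size classification lookup tables; graphlet redundancy |
| `orbitcount.graph_store` | undirected simple graph with bit-packed adjacency (32 booleans per 4-byte word) + neighbour sets; edge modifications; h-index; edge-list and stream I/O |
| `orbitcount.static_counter` | full orbit counting by unique connected-induced-subgraph enumeration; an independent brute-force oracle (`count_all_brute`) |
| `orbitcount.incremental_counter` | per-edge delta matrices, changed-set enumeration, stream replay |
| `orbitcount.evolving_models` | evolving Barabási–Albert / Erdős–Rényi / geometric network generators and a replay benchmark harness |
| `orbitcount.redundancy_optimiser` | redundancy penalty, incremental penalty increase, percentile-gated ranked-edge growth, AUROC/AUPR/F1 evaluation |
| `orbitcount.cli`, `orbitcount.fixtures` | the `orbitcount` command-line tool and synthetic fixture generators |

## CLI

All commands write machine outputs to files under a `--prefix` and log to
stderr; every run also writes its resolved configuration to
`<prefix>.config.json`. Exit codes: 0 success, 1 usage/parse error,
2 verification failure.

```bash
# full static orbit counts of an edge list
orbitcount count network.tsv -p out            # -> out.counts.tsv, out.totals.tsv

# replay a modification stream incrementally, verifying against a recount
orbitcount delta network.tsv stream.tsv -p out --verify

# generate an evolving network (ER | BA | GEO)
orbitcount generate ER -n 1000 -d 0.01 -o 200 --seed 1 -p er

# grow a low-redundancy network from a ranked candidate list and evaluate
orbitcount optimise ranked.tsv --gold gold.tsv -k 100 --percentile 90 \
    --budget 1000 -p opt

# synthetic fixtures
orbitcount fixture toy_graph --name K5 -p k5
orbitcount fixture planted_grn -n 100 --seed 0 -p grn
```

File formats: edge lists are two whitespace-separated label columns
(single-token lines declare isolated nodes, `#` starts a comment);
modification streams are `op<TAB>u<TAB>v` with `op` in `{+, -}`; ranked lists
are `source<TAB>target<TAB>score` with non-increasing scores; count matrices
and totals are TSV.

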