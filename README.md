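# netcentral

Shortest-path centrality metrics (betweenness, closeness, eccentricity,
stress) for large sparse undirected networks, built on an edge-parallel,
level-synchronous all-pairs BFS over a flat two-array edge representation.
Includes a seeded Barabási–Albert generator for scale-free benchmark
networks.

## Design

- **graph**: simple undirected graphs with stable string labels, edge-list
  I/O, and conversion to the flat edge-array form (each undirected edge
  stored once per direction; array length `l = 2m`).
- **sssp**: the computational core. Each BFS level examines every edge
  slot: a slot whose head is on the frontier settles its tail's distance
  and accumulates geodesic counts. Shortest-path predecessors are kept as
  one boolean per edge slot (O(l) per source, not O(n²)). Brandes-style
  back-propagation fills per-source dependencies for betweenness, and an
  analogous recursion yields raw path counts for stress.
- Two interchangeable engines implement the identical contract: `ref`, a
  literal per-edge-slot loop (numba-compiled), and `vec`, a vectorized
  whole-array engine. Their outputs are checked to agree bit-for-bit on
  integers and to 1e-12 on real scores.
- **metrics**: all four metrics computed from one streaming APSP pass.
  Unordered-pair convention (directed accumulation halved); closeness is
  the reciprocal of the mean geodesic distance and eccentricity the
  reciprocal of the maximum, over reachable nodes only; unreachable-only
  nodes score 0. Betweenness is unnormalized by default
  (`--normalize` divides by `(n-1)(n-2)/2`).
- **netgen**: preferential attachment starting from β isolated seed nodes
  (first added node attaches to all of them), giving exactly `β(n−β)`
  edges; fully determined by the seed.
- **oracle**: brute-force geodesic enumeration (n ≤ 14), used only by the
  test suite as an independent reference.

## CLI

```sh
# centrality from an edge-list file (two labels per line, '#' comments)
netcentral compute --input network.tsv --metric bc --metric cc --outdir out/

# centrality on a generated scale-free network
netcentral compute --n 1000 --beta 5 --seed 1 --metric bc --metric sc \
    --engine vec --outdir out/ -v

# write a generated network as an edge list
netcentral generate-ba --n 1000 --beta 5 --seed 1 --out ba.tsv
```

Each metric is written to `<outdir>/<metric>.tsv` as
`# metric=BC normalized=false` followed by `node<TAB>score` rows in input
node order. A `key = value` config file can supply any `compute` option
(`--config run.cfg`); command-line flags override it.

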