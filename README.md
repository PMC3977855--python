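# cenval

Compute five node-centrality measures from first principles on empirical and
synthetic networks, characterize their extreme nodes, measure cross-measure
agreement, score each measure against ground-truth influential nodes, and
probe how seed centrality relates to SI diffusion speed.

The five measures, all implemented from scratch (no graph library at
runtime):

| measure      | definition                                             |
|--------------|--------------------------------------------------------|
| degree       | deg(v) / (n − 1)  (raw counts via `--degree-raw`)      |
| betweenness  | Σ over unordered pairs of σ_st(v)/σ_st, endpoints excluded, unnormalized (Brandes accumulation) |
| closeness    | 1 / Σ_t d(v, t)  (inverse farness; Freeman variant via flag) |
| eccentricity | max_t d(v, t)  (raw hop count; sign-inverted wherever rankings need "high = central") |
| eigenvector  | dominant adjacency eigenvector by power iteration (automatic +I damping on bipartite oscillation) |

Closeness and eccentricity are undefined across components and are computed
on the largest connected component, with the restriction recorded.

## Data

* `karate` — the 34-node / 78-edge karate-club friendship network is
  vendored under `src/cenval/data/` (nodes "1".."34"; documented key nodes
  are the instructor "1" and president "34").
* `dolphins` (62/159) and `celegans` (297/2359) — these public datasets are
  **not redistributed** in this repository. `bundled_fixture()` raises
  `FixtureUnavailableError` with instructions; drop the public files at
  `src/cenval/data/dolphins.edgelist` (whitespace edge list with the
  original dolphin names) and `src/cenval/data/celegans.gml` to enable
  them. The acceptance tests that depend on them fail until then.

## CLI

```sh
# full pipeline on a fixture, bundle written to out/
cenval analyze --fixture karate --k 5 --outdir out

# same on a file (GML or edge list), with the SI probe enabled
cenval analyze --input net.gml --diffusion --beta 0.3 --replicates 200 \
    --rng-seed 7 --outdir out

# YAML config (flags override file values)
cenval analyze --config run.yaml

# seeded generators: er | hub (planted hub) | bridge (planted broker)
cenval generate --model er --n 50 --p 0.1 --seed 7 --out net.gml

# diffusion probe only
cenval diffuse --input net.gml --beta 0.3 --replicates 200 --rng-seed 1 \
    --out diffusion.json

# score measures against a fixture's documented key nodes
cenval validate --fixture karate --k 2
```

`analyze` writes: `nodes.csv` (per-node scores + ranks), `extremes.csv`
(max/min values, exact tie counts and 10-bin histogram end-bin counts),
`correlations.json` (Kendall tau-b or Spearman matrix + top-k overlap),
`validation.json`, `annotated.gml` (scores as numeric node attributes,
round-trippable), optional `diffusion.json`, plus `run_config.yaml` and
`run.log`. Runs are deterministic under a fixed seed and config.

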