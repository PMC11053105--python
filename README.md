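# cephnet

Correlation-network analysis of 2D cephalometric measurement sets.

The package turns a subjects-by-variables table of lateral-cephalometric
measurements into:

- an **absolute-Pearson correlation network**: edge weight = |r|, with
  inclusive cutoffs chosen from the empirical weight distribution
  (histogram / CPDF / retained-fraction summaries);
- **clusters and cliques** across nested cutoffs, including the overlay of
  fine-cutoff (0.8) clusters onto the coarser 0.6 network;
- the **minimum spanning tree** over d = 1 − |r| (Kruskal with an explicit
  union-find and deterministic lexicographic tie-breaking), annotated with
  cluster labels and inter-cluster edge flags.

Because the reference dataset of adults with normal occlusion is
access-restricted, the package ships two fully tested input sources:

- `cephnet.synthetic` — multivariate-Gaussian tables with a prescribed
  block-correlation structure (a 10-group preset over the standard
  65-variable list), plus landmark sets drawn from a perturbable 2D
  template;
- `cephnet.measure` + `cephnet.registry` — the 65 measurements computed
  from named 2D landmarks via a declarative YAML registry over four
  geometric primitives (three-point/vector angles, line–line angles,
  signed point-to-line distances, projections) and linear combinations,
  so composite-index identities (ANB = SNA − SNB, the Tweed triangle,
  the APDI/ODI decompositions) hold mechanically.

## CLI

```sh
# synthetic 10-block table (and optional landmark sets)
cephnet generate --n 735 --seed 1 --out table.csv --landmarks-out lm.csv

# measurements from landmark files (CSV: subject_id,landmark,x,y — or JSON)
cephnet measure --in lm.csv --out measured.csv

# correlation matrix, thresholded networks, MST
cephnet corr --in table.csv --out corr.csv
cephnet network --corr corr.csv --cutoff 0.6 --overlay-cutoff 0.8 \
    --graphml net.graphml --tsv net.tsv
cephnet mst --corr corr.csv --out mst.graphml --tsv mst.tsv

# full pipeline: corr.csv, histogram/CPDF figure + CSV twin, one GraphML
# per cutoff with overlay colors, MST exports, report.json / report.txt
cephnet run --in table.csv --out-dir out/
cephnet report --report out/report.json
```

Generator configs are YAML/JSON
(`n_subjects, seed, unassigned_r, blocks[{label, members, within_r, between_r}]`);
a custom measurement registry can be passed to `cephnet measure --registry`.

## Layout

```
src/cephnet/
  geometry.py    2D primitives (angles, signed distances, projections)
  landmarks.py   LandmarkSet + CSV/JSON IO
  registry.py    declarative measurement definitions (data/registry_v1.yaml)
  measure.py     table computation, complete-case policy, redundancy check
  synthetic.py   block-correlation generator, landmark template, presets
  corrnet.py     Pearson matrix, weight distribution, cutoff graphs,
                 components, cliques, overlays, subnetwork comparison
  mst.py         distance transform, Kruskal MST, tree annotation/exports
  pipeline.py    end-to-end run with artifacts and run report
  cli.py         click entry points
```
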