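# litmap

Build concept co-occurrence ("connectivity") networks from bibliographic
corpora. Articles are tagged against a two-level concept scheme (categories →
parent nodes → child nodes) by searching their titles, abstracts, author
keywords and KeyWords Plus for curated keywords; pairwise tag counts are
normalized by the keyword counts of the two concepts:

```
C_ab = N_ab / (K_a + K_b)
```

where `N_ab` is the number of articles tagged with both concepts and `K_a`
is the number of keywords assigned to concept `a`. The resulting weighted
network supports median thresholding (strong vs. weak connections), top-k
strongest-pair drill-downs into child nodes, deterministic circular layouts,
and export to GEXF/GraphML for viewers such as Gephi. A synthetic-corpus
generator with exact ground truth makes every stage testable offline.

## CLI

The `litmap` entry point exposes the pipeline stages:

```sh
# 1. generate a synthetic corpus + scheme with planted structure
litmap simulate --config sim.yaml --seed 42 -o corpus.tsv \
    --scheme-out nodes.csv --map-out keywords.csv --truth-out truth.json

# 2. tag each article with the concepts whose keywords occur in its text
litmap tag --corpus corpus.tsv --scheme nodes.csv --map keywords.csv \
    [--boundary substring|word_start|word] [--no-case-fold] -o tags.tsv
# (add --wos to read a Web of Science tab-delimited export instead)

# 3. build the connectivity network (parent level, or child drill-down)
litmap network --tags tags.tsv --scheme nodes.csv --map keywords.csv \
    [--level parent|child] [--top-k 5] -o network.json --matrix-csv matrix.csv

# 4. circular layout + GEXF/GraphML export
litmap export --network network.json --format gexf \
    --category-order "Ecology,Evolution,General Characteristics" -o figure1.gexf
```

File formats:

- **WoS export** — tab-delimited with a header of two-letter field tags
  (`TI` and `UT` required; `AB`, `DE`, `ID`, `PY` optional); multi-value
  cells are `;`-separated.
- **canonical corpus TSV** — `record_id, title, abstract, author_keywords,
  keywords_plus, year` with `|`-joined lists; round-trips exactly.
- **nodes CSV** — `category,parent,child` (empty `child` declares a parent
  node). A default 14-parent/3-category node table ships in
  `src/litmap/data/default_nodes.csv`.
- **keyword map CSV** — `keyword,parent,child` (child optional); each keyword
  maps to exactly one parent and at most one child of that parent.

## Library

```python
from litmap import (read_wos_export, load_scheme, tag_corpus,
                    cooccurrence_counts, connectivity_network,
                    below_median_subnetwork, top_k_pairs, child_network,
                    circular_layout, scale_visuals, write_graph)
```

The synthetic generator lives in `litmap.simulate`: configure concept
prevalences and pairwise joint-probability boosts (`1` = independence, `0` =
a planted gap), and it produces a corpus plus exact expected co-occurrence
and connectivity matrices (fitted by iterative proportional fitting over the
exact joint for ≤ 12 concepts).

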