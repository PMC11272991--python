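# acroid — DNA-barcode species identification for *Acropora* corals

Staghorn corals (*Acropora*) are traded internationally under CITES, and
some jurisdictions require imports to be identified to species. The
standard molecular route is two-locus DNA barcoding — the mitochondrial
putative control region (mtCR) and the nuclear *PaxC* intron — with
candidate names taken from the best database matches. In *Acropora* this
route is fragile: both markers evolve slowly, species share haplotypes
(incomplete lineage sorting), and reference databases are salted with
open-nomenclature labels (`sp.`, `cf.`, `aff.`) that cannot anchor an
identification. `acroid` implements the full identification pipeline and
the evaluation machinery needed to quantify exactly when and why it fails.

## What it does

* **Reference curation** (`acroid.refdb`) — FASTA + metadata ingestion,
  open-nomenclature label parsing, per-species indexing.
* **Similarity search** (`acroid.similarity`) — exact Smith–Waterman local
  alignment with affine gaps (a gap of length *k* costs `open + k·extend`),
  Karlin–Altschul bit scores `S' = (λS − ln K) / ln 2`, ranked hit tables,
  BLAST outfmt-6 tabular I/O, amplicon locus verification, and rotation of
  circular sequences to a shared anchor.
* **Hierarchical assignment** (`acroid.assign`) — the decision tree used in
  two-marker coral barcoding: (1) a unique species with a 100.000%-identity
  hit wins; otherwise (2) a unique species at the top bit score; otherwise
  (3) a unique species at the top percent identity among the bit-score-tied
  hits; otherwise (4) no assignment. Genome mode skips step 1. A specimen
  receives a final identity only if both loci concur (`concord`).
* **Leave-one-out evaluation** (`acroid.evaluate`) — can a reference
  database identify its own members? Every record is queried against the
  database minus itself; singleton species are excluded as queries but kept
  as hit subjects; the success rate is `100 · #correct / #evaluated`.
* **Synthetic data** (`acroid.simulate`) — a seeded two-locus generator
  with controllable intra-/inter-species divergence, cross-species
  haplotype sharing and per-locus recovery dropout, plus power-curve
  sweeps of identification success against divergence.
* **Reporting** (`acroid.report`) and readers for per-sample results
  spreadsheets (`acroid.supp_ingest`).

## Worked example

```python
from acroid import (AlignmentParams, SimulationConfig, simulate_dataset,
                    search, assign_species, loo_evaluate)

cfg = SimulationConfig(seed=1)          # 16 species x 8 specimens, 2 loci
ds = simulate_dataset(cfg)

q = ds.queries_for("mtCR")[0]
table = search(q, ds.reference["mtCR"])
print(assign_species(table, locus_tag="mtCR"))

result = loo_evaluate(ds.pooled_db("mtCR"))
print(result.n_correct, "/", result.n_evaluated, "=",
      result.success_rate_pct, "%")
```

The numbered drivers under `analysis/` run the whole study end to end
(each accepts `--seed`, default 1) and print what they find. With the
default seed:

```
$ python analysis/01_simulate_survey.py
specimens: 128
mtCR recovered: 124  PaxC recovered: 75  both loci: 71

$ python analysis/03_concordance.py
specimens with both loci: 71
  concordant_species: 31
  none: 3
  preliminary_mt_only: 34
  preliminary_nuc_only: 3

$ python analysis/04_loo_genomes.py
database: 119 records, 25 species, 9 singleton species excluded as queries
correct: 56 / 110 evaluated (50.91%)
```

Reading: of 128 simulated trade specimens, the mitochondrial marker was
recovered almost universally but the nuclear intron failed in ~40% of
specimens; only 71 specimens had both loci, and under 25% haplotype
sharing fewer than half of those received a concordant two-locus species
identity. A mitogenome-style database of 119 records could self-identify
only half of its evaluable members. `analysis/05_power_curve.py` maps
identification success against interspecific divergence: it collapses to
0% when species are no more divergent than individuals and saturates at
100% once interspecific divergence clears ~4× the intraspecific level.

There is also a CLI binding the same steps
(`acroid simulate|curate|search|assign|concord|loo|power|report|supp`);
see `acroid --help`.

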