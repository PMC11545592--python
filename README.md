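# dietmb — diet analysis from faecal DNA metabarcoding

`dietmb` turns predator faecal amplicon data — a sample × OTU read-count
table plus per-OTU BLAST-style best hits — into dietary inference. It was
built around the analysis needs of non-invasive diet studies of endangered
fish such as the dark sleeper (*Odontobutis obscurus*), where stomach
contents cannot be obtained and the evidence is COI amplicon reads from
faecal samples, but every stage is generic.

The pipeline:

1. **Quality filtering** — remove OTUs below a relative read-count
   threshold (default ≥ 0.01% of all reads; guards against secondary
   predation, contamination and sequencing error), then drop host,
   `"no match"`, non-prey (fungi, Chromista, livestock, …) and
   low-identity (< 97%) hits, harmonise species calls against a field
   survey (species never recorded locally are demoted to genus), and
   collapse OTUs to genus-level prey items.
2. **Dietary metrics** — per item *i* over *S* samples with reads
   *n<sub>i,k</sub>*:
   - %FOO*<sub>i</sub>* = 100/S · Σ<sub>k</sub> I(n<sub>i,k</sub> > 0)
     (frequency of occurrence),
   - %RRA*<sub>i</sub>* = 100/S · Σ<sub>k</sub> n<sub>i,k</sub> /
     Σ<sub>j</sub> n<sub>j,k</sub> (relative read abundance),
   - %P*<sub>i</sub>* = 100 · ΣS<sub>i</sub> / ΣSt<sub>i</sub>
     (prey-specific abundance: the item's pooled read share over only the
     samples that contain it),
   and the Costello feeding-strategy diagram (%P against %FOO) with
   quadrant labels: dominant, rare, specialist (high between-phenotype
   niche component) or generalist (high within-phenotype component).
3. **Prey selectivity** — Jacobs's index
   D = (r − p) / (r + p − 2rp) per prey group, comparing diet share *r*
   (within-group renormalised %RRA) with field availability *p*
   (individuals counted in a survey), plus the faecal-vs-field
   genus-set overlap (chironomid genera merged to family Chironomidae,
   the usual identification limit of benthos surveys).
4. **Group statistics** — per-sample read share and richness of fish vs
   benthic invertebrates compared with an in-package two-sided
   Mann–Whitney U test (exact enumeration for small tie-free samples,
   tie-corrected normal approximation otherwise), and hypergeometric
   sample-based / individual-based rarefaction.
5. **Synthetic data** — a Dirichlet-multinomial generator with known
   truth (per-item occupancy ψ, diet shares, host carryover,
   sub-threshold noise OTUs) so the whole pipeline can be validated
   without sequencing data.

## Worked example

Simulate a 24-sample study under the default conditions and run the full
pipeline:

```sh
dietmb simulate --out sim --seed 11
dietmb run --counts sim/counts.tsv --taxonomy sim/taxonomy.tsv \
           --survey sim/survey.tsv --out demo
```

which prints the dietary metrics table:

```
           item           prey_group  occurrence_count  pct_foo  pct_rra  pct_prey_specific costello_region
      Zacco sp.                 fish                24    100.0     66.6               65.3        dominant
Rhinogobius sp.                 fish                16     66.7      8.3               12.5  generalist_wpc
   Ephemera sp. benthic_invertebrate                14     58.3      6.6               11.0  generalist_wpc
Polypedilum sp. benthic_invertebrate                12     50.0      4.9                9.8  generalist_wpc
Micropterus sp.                 fish                 6     25.0      3.7               14.3            rare
 Chironomus sp. benthic_invertebrate                10     41.7      3.0                8.1            rare
  ...
```

Reading the first row: *Zacco* was detected in all 24 samples
(%FOO = 100), its reads average 66.6% of each sample's prey reads
(%RRA), and its share within the samples containing it is 65.3%
(%P ≥ 50 and %FOO ≥ 50 ⇒ "dominant"). Most other items sit in the
lower-left "rare" quadrant — the signature of a generalist predator with
one staple prey. `demo/` also holds the filter audit (one row per OTU
with its kept/dropped reason), the selectivity table (e.g. *Zacco*:
r = 0.81 vs field availability p = 0.14 giving D = 0.92, strong positive
selection), the Mann–Whitney comparison of the two prey groups, the
rarefaction curve, and a JSON manifest with input checksums for
reproducible reruns.

The same stages are importable directly:

```python
from dietmb import (generate_dataset, SyntheticConfig, run_filter_pipeline,
                    metrics_report)

ds = generate_dataset(SyntheticConfig(seed=11))
result = run_filter_pipeline(ds.table, ds.hits, ds.survey)
print(metrics_report(result.prey))
```

A bundled 15-taxon best-hit example (`dietmb.examples`) shows the
taxonomy handling: its two congeneric pairs merge at genus rank, 15 taxa
→ 13 prey items.

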