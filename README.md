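# harelink

Endozoochoric seed dispersal by the European brown hare (*Lepus europaeus*):
a tested re-implementation of a controlled feeding-experiment analysis, for
ecologists studying seed dispersal syndromes and mobile-link connectivity in
agricultural landscapes.

Hares eat seeds while foraging and deposit some of them, still germinable,
in their fecal pellets hours later and often in a different habitat patch.
The package answers two questions about that process:

1. **Which seed traits survive gut passage?** For each of 44 arable plant
   species, seedlings emerging from feces are scored against the species'
   control germination capacity as *standardized germination success*,
   SGS [%] = 100 · feces seedlings / (capacity/100 · seeds fed), and
   modelled against log seed density, eccentricity (length/width) and
   surface area with a Bayesian phylogenetic mixed model
   (y = Xb + a + e, a ~ N(0, σ²ₚR) with R the phylogenetic correlation),
   fitted by a blocked Gibbs sampler. Model subsets are ranked by DIC and
   phylogenetic signal is summarized as Lynch's heritability
   h² = σ²ₚ/(σ²ₚ + σ²ₑ) with a 95% HPD interval.
2. **How many habitats can a hare connect within its seed retention time
   (7 ± 1.4 h)?** Hourly GPS tracks are resampled, assigned to land-use
   patches, and a moving retention-time window (5.6 / 7 / 8.4 h) counts
   land-use types, unique patches per type and travel distance per window,
   contrasting large-field ("simple") and small-field ("complex")
   agricultural mosaics.

Synthetic-data generators (Yule trees, Brownian traits, model-inverse
germination, jittered-grid landscapes, correlated-random-walk tracks) make
every stage testable end to end. The published per-species experiment table
ships with the package; see `docs/methods.md` for the models, assumptions
and numerical choices.

## Worked example

```python
from harelink import datasets, traits

table = datasets.table1_frame()
print(int(table.seeds_fed.sum()), int(table.feces_germ.sum()))
# 34710 177        -> 177 of 34,710 fed seeds germinated from feces (0.51%)

print(traits.standardized_germination(15, 1.0, 685))
# 218.97810218978103   -> Poa annua: 15 seedlings from 685 seeds at 1%
#                         capacity; SGS 218.98% beats the control group

res = traits.group_summary(table, "neophyte", exclude=["Poa annua"],
                           na_policy="zero")
print(res.round(2))
#    neophyte  mean_sgs   n
# 0     False      1.27  34   -> native species germinate 3x better
# 1      True      0.42   9      after gut passage than neophytes
```

The analysis drivers reproduce the full pipeline and write their tables
under `results/`:

```sh
python analysis/01_seed_traits.py        # indices, screening, group means
python analysis/02_germination_model.py  # mixed model, DIC ranking, h2
python analysis/03_mobile_links.py       # landscape connectivity contrast
```

Driver 03 prints, among other things, the landscape contrast of unique
crop-field patches connected per 7 h window (simulated mosaics, identical
movement): ~1.8 in 27.5 ha fields vs ~3.5 in 2.9 ha fields — small-field
landscapes are connected at more patches even though hares travel no
farther.

The command-line interface exposes the same stages
(`harelink traits|germ|pmm|movement|simulate`, see `--help`).

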