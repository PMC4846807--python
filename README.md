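# forestdiv

Community-assembly analysis of stem-level forest inventories: species
importance values, Hill-number rarefaction/extrapolation, species-abundance
distribution (SAD) model selection, and assemblage structure (group-average
clustering + correspondence analysis). The package targets the standard
design of secondary-forest surveys in montane China — two altitudinal belts
(birch and pine–oak), five stand types per belt, five 30 × 30 m permanent
plots per stand, every stem with DBH ≥ 5 cm recorded — and ships a
synthetic survey generator with known ground truth so the entire pipeline
is testable end to end without field data.

It is written for community ecologists and biodiversity statisticians; the
same machinery (Hill numbers, coverage-based standardization, SAD fits)
applies directly to microbiome and metagenomic count data.

## What it computes

**Importance values.** For species *i* with *n<sub>i</sub>* stems out of
*N*, occupying quadrat fraction *F<sub>i</sub>*, with basal area
*d<sub>i</sub>* = Σ π(DBH/2)²:

- RD<sub>i</sub> = 100 · n<sub>i</sub>/N, RF<sub>i</sub> = 100 · F<sub>i</sub>/Σ<sub>j</sub>F<sub>j</sub>, Rd<sub>i</sub> = 100 · d<sub>i</sub>/Σ<sub>j</sub>d<sub>j</sub>
- IV<sub>i</sub> = (RD<sub>i</sub> + RF<sub>i</sub> + Rd<sub>i</sub>)/3, so Σ IV = 100.

At family/genus level, the overall relative importance of a taxon is
ORI = R.Ab + R.Fr (relative abundance plus relative frequency).

**Hill-number diversity.** <sup>q</sup>D for q = 0 (richness), 1
(exponential Shannon), 2 (inverse Simpson), standardized to a common sample
size m by exact hypergeometric rarefaction below the reference sample and
analytic Chao1/Chao2-anchored extrapolation up to 2× the reference, with
Good–Turing sample coverage and 200-replicate bootstrap confidence bands
(abundance- and incidence-based).

**SAD model selection.** Broken-stick, niche preemption, log-normal, Zipf,
Zipf–Mandelbrot and the neutral sampling formula
φ<sub>n</sub>(θ, m) are fitted to ranked abundances by Poisson maximum
likelihood and compared by AIC = −2 log L + 2k and a Kolmogorov–Smirnov
statistic.

**Assemblage structure.** Bray–Curtis (or chi-square) distances between
stands, UPGMA dendrogram with a k-group cut, and correspondence analysis
whose total inertia equals χ²/N.

## Worked example

```python
from forestdiv import synthetic_data, plot_data, importance, hill_diversity, sad_fit

stems, plots, truth = synthetic_data.gen_survey(seed=1)   # 5,650 stems, 50 plots
birch = [s for s in stems if s.belt == "birch"]

importance.iv_from_stems(birch).head(3).round(2)
#                        RD    RF     Rd    IV
# Pinus armandii       8.38  3.53  15.37  9.09
# Tsuga chinensis      7.38  3.53  12.97  7.96
# Betula albosinensis  9.90  3.53   7.68  7.03

x = plot_data.abundance_table(birch, group_by="belt").pooled_vector()
[round(hill_diversity.hill_number(x, q), 2) for q in (0, 1, 2)]
# [43.0, 24.31, 18.66]        richness, Shannon, Simpson diversity

hill_diversity.extrapolate(x, 0, 2 * int(x.sum())).estimate   # 43.4 species
for f in sad_fit.compare_models(x)[:3]:
    print(f.model, round(f.AIC, 1))
# niche-preemption 247.7      <- generating model family, lowest AIC
# neutral 322.1
# broken-stick 411.1
```

The IV table says the birch belt has no strong dominant (top IV ≈ 9%,
conifers lead on basal area while birch leads on stem counts); the Hill
numbers say its 43 species behave like ~24 equally common ones; the AIC
table recovers the niche-preemption dominance structure the generator used.

Or from the shell:

```bash
forestdiv simulate --out survey --seed 1
forestdiv run --outdir results --seed 1          # IV/ORI tables, diversity
                                                 # curves, SAD fits, dendrogram,
                                                 # CA scores, manifest.json
```

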