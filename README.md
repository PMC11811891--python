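# tetherlink

Single-molecule evidence for a flexible tether between two macromolecular
bodies, extracted from cryo-EM particle coordinates.

When a complex consists of two independently refined modules joined by a
long disordered linker — the motivating case is human TFIIIC, whose τA
and τB subcomplexes are connected by a ~550-residue segment of TFIIIC220
— each micrograph contains particles of both populations, and the pair
of images belonging to one molecule sit a tether-length apart.
`tetherlink` implements the coordinate-level analysis that turns this
into a quantitative readout:

1. **Pairing.** Per micrograph, build the N_τB × N_τA matrix of
   Euclidean distances between refined particle positions (Å), then pair
   greedily: repeatedly take the smallest remaining entry and delete its
   row and column until one population is exhausted. No particle is used
   twice, and selection-order distances are nondecreasing.
2. **Null model.** Re-run the identical pairing on the same
   per-micrograph particle multiplicities with coordinates re-drawn
   uniformly over the field, pooled over replicates.
3. **Readout.** Histogram the pooled pair distances, subtract the mean
   null histogram, and locate the excess peak. A genuine tether whose
   3-D displacement is isotropic Gaussian with scale σ produces a
   Rayleigh(σ)-shaped excess in the 2-D projection, with mode σ; random
   co-occurrence produces none.

A synthetic scene generator with known ground truth (tethered pairs +
unlinked background + imperfect detection) drives validation end to end,
so every stage runs without any external data. Companion modules cover
the surrounding quantitative steps of the same study design: Hill
binding-curve fitting with the coefficient fixed at 1
(fraction bound = c/(K_d + c)), in-silico annealing and duplex molecular
weight of promoter DNA, and per-column conservation scoring
(entropy over a reduced seven-type amino-acid alphabet for proteins,
information content in bits for DNA logos).

## Worked example

Simulate the default validation scene — 100 micrographs, 20 tethered
pairs each with tether scale σ = 200 Å, 10 unlinked particles per
species per micrograph, 90% detection — then run the full pipeline:

```python
from tetherlink import pair_mapping as pm, distance_stats as ds, synthetic_scenes as ss

params = ss.SceneParams(seed=1)
table_a, table_b, truth = ss.simulate_scene(params)
obs, null = pm.observed_and_null_distances(
    table_b, table_a, params.field_w_A, params.field_h_A, seed=1, n_replicates=10
)
comparison = ds.compare_to_null(obs, null, bin_width_A=20.0, n_null_replicates=10)
print(f"pairs observed:        {len(obs)}")
print(f"genuine tethered pairs: {len(truth)}")
print(f"excess peak (fit):     {comparison.excess_peak_fit_A:.1f} A")
print(f"excess peak (max bin): {comparison.excess_peak_bin_center_A:.1f} A")
print(f"KS observed vs null:   {comparison.ks_statistic:.3f}")
```

prints

```
pairs observed:        2711
genuine tethered pairs: 1610
excess peak (fit):     196.6 A
excess peak (max bin): 230.0 A
KS observed vs null:   0.486
```

The pairing produces 2711 pairs (one per τB particle on each shared
micrograph), of which 1610 are genuinely tethered molecules with both
partners detected. The tether-model fit to the binned excess recovers
the 200-Å scale to within a few Å; the raw maximal-excess bin lands a
couple of bins away, which is expected — a Rayleigh is flat to ~2%
across ±20% of its mode, so the maximal 20-Å bin wanders from sample to
sample while the shape fit stays put (see `docs/methods.md`). The KS
statistic of 0.49 cleanly separates observed from randomized distances.

The same pipeline is available from the shell:

```sh
tetherlink simulate --config scene.yaml --out-a A.star --out-b B.star --truth truth.tsv
tetherlink pairmap --tau-a A.star --tau-b B.star --out pairs.tsv
tetherlink null --tau-a A.star --tau-b B.star --seed 1 --replicates 10 \
    --field-w 14000 --field-h 14000 --out null.tsv
tetherlink stats --observed pairs.tsv --null null.tsv --bin-width 20
tetherlink mw                    # duplex MW of the bundled TRR-TCT3-2 gene
tetherlink bindfit curve.tsv     # Hill (n=1) fit of a titration TSV
tetherlink conserve --alignment msa.fasta --alphabet protein --threshold 0.9
```

`tetherlink mw` reports a 98-bp duplex of 61 kDa for the bundled human
TRR-TCT3-2 tRNA gene (anhydrous residue masses, both strands, no
end-group correction).

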