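# flavopot

Structure-based QSPR prediction of flavoprotein midpoint redox potential
(E_m) from PDB files.

## The problem

Flavoproteins carry a noncovalently bound flavin cofactor (FMN or FAD)
whose midpoint redox potential E_m — the average of the two one-electron
potentials, in mV — is tuned over hundreds of millivolts by the protein
matrix around the isoalloxazine ring. Measuring E_m is laborious;
quantum/molecular-mechanics predictions are accurate but expensive. This
package implements the alternative: a quantitative structure–property
relationship (QSPR) pipeline that maps inexpensive geometric/
physicochemical descriptors of the flavin environment to E_m with machine
learning, for structural biologists and protein engineers who have a PDB
file and want an E_m estimate plus an account of which environment
features drive it.

## The descriptors and models

For each structure, **246 named molecular descriptors** are extracted
around the flavin:

* **165 region descriptors** — one set of 55 counting/sum descriptors
  (residue-type counts; polar/apolar/charged/positive/negative/
  hydrophobic/aromatic/small/H-bond classes; sums and means of volume,
  flexibility, hydrophobicity, steric hindrance, polarity, pI and
  secondary-structure propensities; side-chain N/O/C/S atom counts; net
  charge) at three scopes: the whole protein (`Protein.X`), a sphere of
  radius r1 around the isoalloxazine-ring barycenter (`Bar.X`), and the
  union of spheres of radius r2 around each ring atom (`Ring.X`), plus
  three protein N/O/C atom counts near the ring
  (`Nitrogen_Around`, `Oxygen_Around`, `Carbon_Around`);
* **2 × 28 N5-environment descriptors** — identity and properties of the
  residue nearest to the flavin N5 atom (`N5_nearest_X`) and of that
  residue with its two sequence neighbours (`Around_N5.X`);
* **21 CTD descriptors** — composition/transition/distribution of a
  three-class hydrophobicity encoding of the sequence;
* the assay **pH**.

Radii are scanned over r1 = 8…16 Å × r2 = 3…6 Å (36 configurations,
each giving an n × 247 design matrix including the E_m label). Six
regressors are compared — LR, GPR, SVR, KNR, RF and XGB — with
train-only preprocessing (pH mean-imputation; zero-variance and
|Pearson r| > 0.99 filtering; for the non-tree models, standardization and
elastic-net feature selection with α ∈ {10, 100}, ρ ∈ {0.5, 0.75, 1}).
Evaluation is 10 × random 80/20 splits with hyperparameters chosen by
5-fold CV minimizing MAE; models are compared per metric (MAE, RMSE, R2,
Spearman) with two-sided Mann–Whitney U tests. A fitted model is
interpreted with exact Shapley-value attributions (φ₀ + Σφ reproduces
every prediction) and features ranked by mean |φ|.

## Worked example

```python
import flavopot as fp

spec = fp.StructureSpec(placements=[
    fp.ResiduePlacement("ARG", 5.0), fp.ResiduePlacement("HIS", 6.0),
    fp.ResiduePlacement("GLN", 10.0), fp.ResiduePlacement("TRP", 22.0),
], seed=0)
pdb_text, truth = fp.generate_structure(spec)          # synthetic flavin site
structure = fp.parse_structure(pdb_text, "demo")
site = fp.locate_flavin_sites(structure)[0]
print("cofactor:", site.cofactor_kind, "| ring atoms:", len(site.ring_atoms))
vec = fp.build_feature_vector(structure, pH=7.0, r1=13.0, r2=3.0)
print("descriptors:", len(vec))
for name in ["Bar.ResTot", "Bar.ResPositive", "Bar.nNats in side chain",
             "Protein.GLN", "Around_N5.Hydrophobicity", "pH"]:
    print(f"{name:28s} {vec[name]:8.3f}")
```

prints

```
cofactor: FMN | ring atoms: 17
descriptors: 246
Bar.ResTot                      3.000
Bar.ResPositive                 2.000
Bar.nNats in side chain         6.000
Protein.GLN                     1.000
Around_N5.Hydrophobicity       -7.700
pH                              7.000
```

Three residues were planted within 13 Å of the ring barycenter (ARG, HIS,
GLN), two of them positive, jointly carrying six side-chain nitrogens; the
TRP placed at 22 Å is outside the sphere but still counted at protein
scope. `Around_N5.Hydrophobicity` is the Kyte–Doolittle sum over the
residue nearest to N5 and its sequence neighbours.

The same operations are available from the shell
(`flavopot extract | build-dataset | scan | train | compare | explain |
simulate`), e.g.

```sh
flavopot simulate --kind structures --n 12 --out-dir demo/
flavopot train demo/records.csv -e LR -e XGB --repeats 10 --out-dir demo/run/
```

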