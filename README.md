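# interkit

Analysis toolkit for quantifying a direct protein–protein interaction from
three kinds of raw data, with synthetic ground-truth generators for every
stage:

* **Biosensor (SPR) kinetics** — forward simulation of sensorgrams under a
  1:1 Langmuir binding model with an optional mass-transport step,
  double-referencing preprocessing, and global nonlinear fitting of
  multi-concentration series with residual diagnostics and replicate
  aggregation.
* **Contact-site mapping** — post-processing of two-chain coordinate frames
  (multi-MODEL PDB as a trajectory stand-in, PQR for partial charges) into
  residue-level cross-molecule contacts (≥ 3 atoms within 3 Å), per-pair
  occupancies, Coulomb electrostatic scores and a stable/unstable
  classification (10 %-of-maximum rule).
* **CD conversion** — raw circular-dichroism signal (mdeg) to molar
  ellipticity per residue, θ = CD / (10·n·p·c).

## Library quick tour

```python
import interkit as ik

# simulate a noisy concentration series with known ground truth
scen = ik.SCENARIO_CATALOG["FL1-MPP1"]          # k_on=4.5e4, k_off=1.03e-3
bundle = ik.generate_sensorgram_series(scen)

# double-reference and fit globally
from interkit.referencing import reference_series
series = reference_series(bundle.samples, bundle.blank, bundle.empty_surface)
result = ik.fit_global(series, model="two_compartment")
print(result.k_d, result.param_sd["k_d"], result.chi2)

# contact sites on a toy trajectory
iface = ik.PlantedInterface(contacts=(ik.PlantedContact(residue_a=2, residue_b=3),))
traj, truth = ik.generate_toy_complex(iface, n_frames=10)
sites = ik.aggregate_sites(traj)

# CD conversion
theta = ik.molar_ellipticity(10.0, n=100, p=0.1, c=1e-5)   # -> 1.0e4
```

## CLI

One `interkit` entry point with subcommands:

```bash
interkit simulate      --config sim.yaml --out-dir curves/
interkit reference     --sample s.csv --blank b.csv --empty-surface e.csv --out ref.csv
interkit fit           --config fit.yaml --out report.json --residuals-dir res/
interkit summarize     --reports r1.json --reports r2.json --out table.csv
interkit contacts      --pdb traj.pdb --cutoff 3.0 --min-atoms 3 --out sites.csv
interkit cd-convert    --spectrum raw.csv --n-residues 100 --path-cm 0.1 --conc-m 1e-5 --out conv.csv
interkit make-fixtures --out-dir fixtures/ --scenario FL1-MPP1 --seed 1234
```

Sensorgram CSVs carry `time_s,response_RU` columns with a
`<name>.meta.yaml` sidecar holding concentration and phase times.

## Notes

* K_D is computed as k_off / k_on throughout.
* The two-compartment model is dR/dt = k_on·Cs·(Rmax − R) − k_off·R with
  quasi-steady Cs = (k_t·C + k_off·R)/(k_t + k_on·(Rmax − R)); k_t is in
  RU/(M·s), sharing the conventional RU↔M conflation of single-channel
  biosensor models.
* The CD formula is applied to the instrument signal in mdeg exactly as
  stated; some conventions insert an extra factor of 1000.
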