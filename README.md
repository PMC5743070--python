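# flexens

Weighted conformational ensembles of a flexible two-domain protein from SAXS
profiles and per-domain NMR rotational correlation times.

The package models a two-domain protein connected by a flexible linker that
can either occupy a groove on the larger domain ("bound") or float free
("open").  It generates coarse one-bead-per-residue conformer pools in both
linker modes, predicts per-conformer observables (Debye-sum SAXS profiles and
coupled-domain rotational correlation times), and recovers sparse
non-negative ensemble weights against experimental-style data by minimizing

    chi^2(w, alpha) = chi_saxs^2 + alpha * chi_relax^2 = ||C(alpha) w - B||^2

with a multi-candidate orthogonal matching pursuit, l-curve size selection
and near-optimal solution averaging.  A synthetic-data module generates
ground-truth ensembles and noisy observables so the whole pipeline is
testable without external data.

## Modules

| module              | contents |
|---------------------|----------|
| `flexens.pool`      | bead-chain conformers (3.8 A bonds, excluded volume), domain fixtures, linker-in/out sampling, k-means pool reduction, PDB+JSON persistence |
| `flexens.saxs`      | Debye forward model, Guinier fit, regularized IFT P(r), Dmax selection, dimensionless Kratky, volume-of-correlation mass estimate |
| `flexens.hydro`     | Stokes-Einstein-Debye / Perrin-ellipsoid rotational correlation times with Einstein-viscosity interdomain coupling |
| `flexens.relax`     | 15N dipolar+CSA relaxation forward model (isotropic & axially symmetric), local tau_c from T1/T2, diffusion-tensor fitting |
| `flexens.ses`       | design-system assembly, non-negative beam OMP, l-curve knee, near-optimal averaging, alpha scan |
| `flexens.metrics`   | weighted Rg / d_RM distributions, bound-state percentage, domain center-of-mass maps |
| `flexens.synthetic` | truth ensembles with a prescribed bound fraction, noisy SAXS / tau / relaxation simulation |
| `flexens.cli`       | `flexens` command-line interface |

## Command line

```sh
# generate a mixed pool of conformers (bound + open linker)
flexens --set n_in=100 --set n_out=100 genpool out/pool

# simulate noisy observables from a hidden truth ensemble
flexens --set truth_k=5 --set bound_population=51 simulate out/pool out/obs

# joint SAXS+relaxation sparse ensemble fit (fixed alpha or alpha scan)
flexens --set alpha=0.06 fit out/pool out/obs/saxs_exp.dat out/obs/tau_exp.json out/fit
flexens --set 'alpha_grid=[0,0.001,0.01,0.06,0.3,1]' fit out/pool out/obs/saxs_exp.dat out/obs/tau_exp.json out/fit

# ensemble descriptors and primary SAXS analysis
flexens analyze out/pool out/fit/ensemble.json out/metrics
flexens saxs-primary out/obs/saxs_exp.dat out/saxs_report
```

Configuration lives in a JSON file (`--config cfg.json`) with full
`--set key=value` override; every command writes its materialized config
(all seeds explicit) next to its outputs, so reruns are reproducible.
Exit codes: 0 success, 2 validation error, 3 numerical failure.

## File formats

All inputs and outputs are plain text: SAXS profiles as 3-column ASCII
(q, I, sigma; `#` comments), P(r) as 2-column ASCII with a header, conformers
as CA-only PDB files with a JSON sidecar (segment labels in the chain ID),
pools as a directory plus `manifest.json`, tau tables as 3-column TSV,
relaxation data as a delimited table with a `field_MHz` header, ensembles and
truths as JSON.
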