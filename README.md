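# mabdyn

Antibody conformational-dynamics analysis toolkit: per-frame Fab/Fc
orientation descriptors, accelerated-MD (aMD) reweighting to a 2-D
free-energy surface, minimum-energy conformer extraction, GROMOS
clustering, interaction/structure descriptors, domain correlation maps,
and effect-size statistics for comparing two antibody forms (e.g. a mAb
with and without Fab glycosylation).

The package ships a synthetic-data module that generates pseudo-antibody
systems, boosted angle ensembles and small all-atom fixtures with known
ground truth, so the whole pipeline is testable without any external
trajectory.

## Modules

| Module | Purpose |
| --- | --- |
| `mabdyn.core_io` | PDB/DCD/XTC/NetCDF reading (MDAnalysis-backed), YAML chain/domain annotations, aMD boost logs |
| `mabdyn.synthetic_data` | seeded pseudo-antibody trajectories, designed-PMF boosted ensembles, helix/sheet/H-bond/SASA fixtures |
| `mabdyn.geometry` | Fc-attached reference frame, Fab latitude/longitude (theta/phi), delta-phi, Y/T shape classifier, inter-Fab angle, CH2 and glycan distances |
| `mabdyn.amd` | aMD threshold/alpha parameters, Maclaurin (order 10) reweighting, 2-D PMF grid, minimum-energy frame selection (PMF < 0.5 kcal/mol) |
| `mabdyn.clustering` | pairwise superposed CA RMSD matrix, GROMOS (Daura) clustering (6.5 A cutoff, max 10 clusters) |
| `mabdyn.interactions` | heavy-atom contacts (4 A), geometric H-bonds with 1% frequency filter, Kabsch-Sander 8-state secondary structure, Shrake-Rupley SASA, simplified surface patches |
| `mabdyn.correlation` | dynamic cross-correlation map of CA fluctuations, inter-chain vs inter-halves domain-block summary |
| `mabdyn.stats` | Student's t-test, Cohen's d with 95% CI (normal or noncentral-t) and magnitude labels |
| `mabdyn.pipeline` | the end-to-end two-system comparison with CSV/JSON outputs |

## CLI

All stages are exposed as subcommands of `mabdyn`:

```bash
# generate a synthetic system (PDB + DCD + annotation YAML + boost table)
mabdyn make-toy --out-dir sysA --theta1 70 --frames 100 --noise 0.3 --seed 1

# per-frame descriptor table
mabdyn descriptors --topology sysA/toy.pdb --trajectory sysA/toy.dcd \
    --annotation sysA/toy_annotation.yaml --out descA.csv

# reweighted free-energy surface + minimum-energy frames
mabdyn fes --descriptors descA.csv --boost sysA/toy_boost.txt --out fesA.csv

# clustering, correlation, two-table comparison
mabdyn cluster --topology ... --trajectory ... --annotation ... --out clusters.csv
mabdyn correlation --topology ... --trajectory ... --annotation ... --out dccm.csv
mabdyn compare --table-a descA.csv --table-b descB.csv --out report.csv

# full two-system pipeline from a YAML config
mabdyn run --config config.yaml
mabdyn plots --results-dir out
```

A pipeline config lists two systems plus analysis parameters:

```yaml
systems:
  glyco:   {topology: sysA/toy.pdb, trajectory: [sysA/toy.dcd],
            annotation: sysA/toy_annotation.yaml, boost: sysA/toy_boost.txt}
  aglyco:  {topology: sysB/toy.pdb, trajectory: [sysB/toy.dcd],
            annotation: sysB/toy_annotation.yaml, boost: sysB/toy_boost.txt}
output_dir: out
bins: 60              # FES grid
pmf_threshold: 0.5    # kcal/mol
cluster_cutoff: 6.5   # A
max_clusters: 10
contact_cutoff: 4.0   # A
hbond_freq_cutoff: 0.01
temperature: 300.0
```

## Annotation config

Chains are labeled LC1/LC2/HC1/HC2; domains (VL/CL/VH/CH1/hinge/CH2/CH3)
are inclusive residue intervals per chain; glycans are named chain
selections; descriptor anchors (`fab1_apex`, `fab2_apex`, `hinge_pivot`,
`fc_glyco_site_1/2`) name the residues/atoms used by the inter-Fab angle
and CH2 distance. Residue numbering follows the input topology verbatim,
so antibody-specific numbering is configuration, never code.

Two glycan-separation modes are provided because the two common
descriptions differ: `min-heavy-atom` (closest heavy-atom pair, the
default) and `center-of-mass` (centroid distance).

## Conventions

* 0-based frame indexing; lengths in Angstrom, energies in kcal/mol,
  angles in degrees.
* theta is the polar angle from the Fc z-axis (pointing toward the Fabs);
  a conformation is Y-shaped iff both theta < 90 degrees, else T-shaped.
* delta-phi is unwrapped by default (continuous rotations beyond +-180
  degrees accumulate); a raw circular difference is available by flag.
* Reweighting uses the total (dihedral + potential) boost by default and
  a 10th-order Maclaurin expansion of exp(beta dV); exact-exponential and
  cumulant modes exist for validation.
* The surface-patch analysis is a documented simplification (exposure
  threshold + side-chain adjacency graph), not a reimplementation of any
  proprietary surface tool.

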