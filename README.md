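# capsidkit

Analysis toolkit for icosahedral virus capsids: symmetry expansion,
capsid size and volume metrics, subunit interface (SASA/buried-area)
analysis, symmetry-axis distance measurements, inner-surface charge
mapping, and polyprotein cleavage arithmetic — with a synthetic-capsid
generator so every stage is testable without downloading any structures.

## Modules

| module | what it does |
|---|---|
| `capsidkit.structure_io` | PDB/mmCIF read/write (BIOMT and `_pdbx_struct_oper_list` operators included), atom selection |
| `capsidkit.icosahedral_symmetry` | the 60-element icosahedral rotation group (I222 frame), capsid expansion, axis enumeration, symmetry-mate distances |
| `capsidkit.capsid_geometry` | radial profiles, inner/outer diameters, sphere-model inner volume, voxel flood-fill cavity volume, volume per nucleotide |
| `capsidkit.interfaces` | Shrake–Rupley SASA (deterministic spiral point set), buried surface area, AU–neighbour capsid interfaces, residue contact networks, axis neighbourhood composition |
| `capsidkit.sequence_tools` | polyprotein cleavage, fragment masses, basic-residue inner-surface mapping, modeled-residue accounting |
| `capsidkit.synthetic_data` | seeded ideal-shell capsids, interface fixtures with closed-form buried areas, random polyproteins |
| `capsidkit.cli_pipeline` | `capsid` command-line interface |

Conventions: coordinates are Å throughout; report output converts to nm
at the reporting layer. Inner volume uses the sphere model
V = (π/6)·d³ of the measured inner diameter (0.5th/99.5th radial
percentiles by default); the voxel flood-fill is an independent
cross-check. A poly-A allowance of 200 nt is added to raw genome
lengths for packaging-density calculations.

## CLI

```sh
# comparative size report from a YAML config
capsid report --config entries.yaml --out-csv report.csv --out-json report.json

# single measurements
capsid measure axis-distance --structure au.pdb --chain A --res 114 --atom CB --axis 2
capsid measure contacts --structure au.pdb --sel-a "A:1-13" --sel-b "B:1-13" --cutoff 4
capsid measure bsa --structure au.pdb --sel-a A --sel-b B
capsid measure accounting --structure au.pdb --map A=VP4A --expected VP4A=264
capsid measure charges --structure au.pdb --inner-shell 100:120

# polyprotein arithmetic
capsid cleave --length 931 --sites 264,515

# synthetic fixtures
capsid fixtures shell --out shell.pdb --inner 100 --outer 130 --atoms 500 --seed 1
capsid fixtures polyprotein --out poly.fasta --length 931
```

Report config format:

```yaml
entries:
  - label: my-capsid
    structure: path/to/asymmetric_unit.pdb
    genome_nt: 12333        # raw length; +200 poly-A applied by the pipeline
    t_number: "T=1 (pseudo T=3)"
    use_biomt: false        # true: use the file's own operators
options:
  inner_pct: 0.5
  outer_pct: 99.5
  polya_nt: 200
```

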