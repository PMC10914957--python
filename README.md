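# membind

Trajectory-analysis toolkit for peptide–membrane binding studies:
PBC-aware contacts and insertion depths, geometric hydrogen-bond
detection, DSSP-style secondary-structure assignment, free-energy
landscapes with basin/microstate extraction, a four-class binding-model
classifier, and replica-exchange (solute-tempering) ladder/exchange
diagnostics.  A first-class synthetic-data module generates toy
peptide + bilayer ensembles with planted ground truth (per-region
insertion depths, secondary-structure templates, hydrogen bonds,
bound/unbound mixtures), so every analysis stage is testable without any
external data.

## Layout

| module | contents |
| --- | --- |
| `membind.core` | domain types (`AtomRecord`, `RegionMap`, `Frame`, `TrajectoryEnsemble`, `AnalysisConfig`), `build_system`, `filter_time_window` |
| `membind.io` | multi-model PDB, GRO, TSV/JSON tables, replica-exchange logs |
| `membind.geometry` | minimum-image distances, centres of mass, cell-list contacts, insertion depths, residue contact maps, Kabsch RMSD |
| `membind.hbond` | donor/acceptor tables, geometric H-bond detection, per-residue/partner summaries |
| `membind.secstruct` | Kabsch–Sander backbone H-bonds, 7-class assignment (E/B/H/G/I/T/C), grouped fractions, β content |
| `membind.fel` | 2D/1D free-energy surfaces (G = −kT ln P), basin detection, per-basin microstates, bound partition, binding-model classifier |
| `membind.rest2` | geometric temperature ladders, exchange-rate and ladder-mixing diagnostics |
| `membind.synthetic` | peptide/bilayer builders, posed β-sheets and helices, binding-model template ensembles, CV samples, synthetic exchange logs |
| `membind.pipeline` | `run_full_pipeline`: the end-to-end analysis with deterministic TSV/JSON reports |
| `membind.cli` | the `membind` command-line tool |

Units: nm, ns, K, degrees everywhere inside the package; file readers
convert at the boundary (PDB Å ↔ nm).  Free energies are natively in kT;
kcal/mol conversion uses k = 0.0019872 kcal/(mol·K).  Boxes are
orthorhombic; the membrane normal is the z axis.

## CLI

```sh
# synthetic ensemble with planted ground truth
membind synth --spec spec.json --out traj.pdb --truth truth.json

# full pipeline (per-frame/per-residue tables, FELs, basins, microstates,
# model labels, contact maps, H-bond summaries)
membind --config config.yaml run-all traj.pdb --out report/

# individual stages
membind --config config.yaml contacts traj.pdb --out contacts.tsv
membind --config config.yaml depth traj.pdb --out depth.tsv
membind --config config.yaml hbonds traj.pdb --out hbonds.tsv
membind --config config.yaml secstruct traj.pdb --out ss.tsv
membind --config config.yaml classify traj.pdb --out models.tsv
membind fel --table report/per_frame.tsv --x distance_nm --y n_contacts --out fel.tsv

# replica-exchange tools
membind rest2 ladder --tmin 343 --tmax 500 --nrep 18
membind rest2 diag --log exchanges.log
```

`spec.json` mirrors `membind.synthetic.SyntheticSpec`, e.g.

```json
{"seed": 1, "n_frames": 200, "model_template": "mixture",
 "mixture_weights": {"model3": 0.5, "unbound": 0.5}}
```

The config file (YAML or JSON) mirrors `AnalysisConfig` field names —
contact cutoff 0.5 nm, H-bond donor–acceptor cutoff 0.3 nm and 20° angle,
membrane half-thickness 2.0 nm, temperature 343 K, 200 ns equilibration
discard, FEL bin widths, basin/classifier thresholds — and accepts a
`regions` mapping to override the default NT (1–16) / CHC (17–21) /
CL (22–29) / CT (30–40) partition.  A multi-model PDB carries no time
stamps, so frame times are `i * frame_spacing` (default 1 ns/frame);
`run-all` discards frames before `equilibration_discard`.

### Exchange-log dialect

Plain text, whitespace-delimited: `time_ps  i  j  accepted` where
`(i, j)` is an adjacent pair of temperature-rung indices and `accepted`
is 0/1.  Comment lines start with `#`; an optional `# n_replicas N`
header fixes the ladder size.  Rung occupancies per replica are
reconstructed by replaying accepted swaps from the identity permutation.

## Conventions worth knowing

- Contact and H-bond cutoffs are closed (`<=`).
- "Bilayer" means the union of the three lipid groups; water and ions are
  excluded.
- The H-bond angle criterion is the donor-centred D→H vs D→A angle
  (≤ 20°); the linear D–H···A convention is available via
  `hbond_angle_convention: linear`.
- A frame is *bound* iff it has at least one peptide–bilayer heavy-atom
  contact.
- Insertion depth = |residue COM z − bilayer COM z| − half-thickness;
  negative values are below the surface.
- Basin labels a, b, c, … order minima by descending distance coordinate,
  then ascending free energy; microstates are `<basin>1` (high-β) and
  `<basin>2` (low-β) sub-minima of the per-basin (RMSD, β) surface.
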