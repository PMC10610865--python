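# asictox

Tools for two halves of a peptide-toxin / acid-sensing-channel selectivity
study:

1. **Interface-contact analysis of multi-frame structures.** Given an
   MD-style multi-model PDB (one chain per molecule), classify every
   inter-chain residue contact in every frame into six types — hydrogen
   bond (H), ionic bridge (I), ion–dipole (D), π-cation (P), aromatic
   stacking (S), and hydrophobic (M, following the molecular hydrophobic
   potential concept) — then turn the per-frame events into *relative
   lifetimes* (the fraction of frames in which a contact is present),
   average symmetry-equivalent copies, filter by per-type reporting
   thresholds (H/I > 10 %, M > 30 %, strict), render grouped interface
   tables such as `D15 | K91 (I, H, M)`, and build summed-lifetime contact
   maps between a ligand and a receptor chain.

2. **Hill dose–response pharmacology.** Normalize per-oocyte peak currents
   to the control response and fit the decreasing three-parameter Hill
   curve

   ```
   Y(c) = Bottom + (1 − Bottom) / (1 + 10^((X − LogIC50)·nH)),   X = log10(c)
   ```

   with Top fixed at 1, Bottom ∈ [0, 1] (the residual current at
   saturating inhibitor) and nH > 0 (slope magnitude). Replicate fits are
   summarized as mean ± SEM, and constructs are compared against a
   reference with one-way ANOVA plus Dunnett's many-to-one test
   (Monte-Carlo critical values; IC50 compared on the LogIC50 scale).

Because cluster-scale trajectories and oocyte recordings are not desk-scale
inputs, the package ships synthetic generators with planted ground truth:
trajectories in which chosen residue pairs satisfy a chosen contact
criterion on a planted per-frame schedule, and per-oocyte inhibition curves
drawn from the Hill model with Gaussian noise. Every downstream stage is
tested against these generators and against an independent brute-force
contact oracle.

## Worked example

```python
import asictox as ax

# --- structural half: plant contacts, detect, summarize -------------------
specs = [
    ax.PlantedContactSpec("T", 15, "G", 91, "I", target_lifetime=0.70),
    ax.PlantedContactSpec("T", 16, "G", 298, "M", target_lifetime=0.45),
    ax.PlantedContactSpec("T", 39, "G", 310, "M", target_lifetime=0.20),
]
traj, truth = ax.generate_planted_trajectory(specs, n_frames=500, seed=7)
events = ax.classify_trajectory(ax.annotate(traj))
table = ax.compute_lifetimes(events, n_frames=500)
kept = ax.filter_contacts(table)        # H/I > 10%, M > 30% (strict)
print(ax.make_contact_table(kept, ligand_chain="T").to_markdown())
imap = ax.sum_intensity_map(table, "T", "G", receptor_range=(280, 370))
print(f"map total (receptor 280-370): {imap.total:.2f}")

# --- pharmacology half: synthetic oocyte curves, Hill fits, Dunnett -------
from asictox.params import TOXIN_MUTANTS_HETEROTRIMER

fits = {}
for i, name in enumerate(["WT", "H13A"]):
    data = ax.generate_dose_response(ax.DoseResponseSpec(
        TOXIN_MUTANTS_HETEROTRIMER[name], n_replicates=5,
        noise_sd=0.05, seed=40 + i))
    fits[name] = ax.fit_hill(data)
    s = fits[name].summary()
    print(f"{name}: IC50 = {s.loc['ic50_nm','mean']:.0f} +/- "
          f"{s.loc['ic50_nm','sem']:.0f} nM, Bottom = "
          f"{s.loc['bottom','mean']:.2f} +/- {s.loc['bottom','sem']:.2f}")
cmp = ax.compare_params(fits, reference="WT", seed=0)
row = cmp.comparisons.query("parameter == 'logic50'").iloc[0]
print(f"LogIC50 H13A vs WT: Dunnett-adjusted p = {row['adj_p']:.4f} ({row['tier']})")
```

prints

```
| Ligand | Partner |
| --- | --- |
| K15 | D91 (I) |
| L16 | L298 (M) |
map total (receptor 280-370): 0.65
WT: IC50 = 140 +/- 5 nM, Bottom = 0.06 +/- 0.01
H13A: IC50 = 374 +/- 10 nM, Bottom = 0.06 +/- 0.02
LogIC50 H13A vs WT: Dunnett-adjusted p = 0.0000 (****)
```

Reading the output: the planted 70 % ionic contact and 45 % hydrophobic
contact survive the reporting thresholds (the 20 % hydrophobic row is
dropped, since M requires > 30 %); the planted generator names residues by
the minimal fragments it builds (Lys/Asp for an ionic pair, Leu for a
hydrophobic one), so the labels show those residue types. The interface
map is windowed to receptor residues 280–370, which excludes the contact
at residue 91, leaving 0.45 + 0.20 = 0.65. On the pharmacology side the
five-oocyte fits recover the generative parameters (WT: 130 nM / 0.07;
H13A: 350 nM / 0.07) within the noise, and the ~0.43 log-unit potency loss
of the H13A construct is flagged highly significant.

A thin CLI mirrors the library: `asictox simulate-traj`,
`simulate-doseresp`, `detect`, `lifetimes`, `heatmap`, `report`,
`hillfit` (see `asictox --help`).

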