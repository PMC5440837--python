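# groovedock

Tools for studying how a groove-bearing transmembrane (TM) helix bundle can
dock onto the protruding outer helix of a tetrameric receptor, and for
quantifying the cell-biology assays that test such an interaction.

The motivating system is the mitochondrially encoded complex-I subunit ND2
and the NMDA receptor (NMDAR). Bilaterian ND2 has lost the three N-terminal
TM helices of its bacterial homologue NuoN; the missing third helix leaves a
deep lateral groove in the 11-helix bundle, and that groove can receive the
M4 helix of the receptor's GluN1 subunit — the outermost TM helix, which
protrudes from the receptor's four-fold TM core. The package is aimed at
structural bioinformaticians and cell biologists who want this docking
procedure and the accompanying assay statistics as reusable, tested code
that runs entirely on synthetic structures and images, with no downloads.

## What it computes

**Template-guided rigid docking** (`groovedock.docking`). Given a "long"
template whose filler helix occupies the groove, a "short" groove-bearing
query, and a receptor with a target M4 helix:

1. Kabsch-superpose the template's filler Cα trace onto the receptor's M4
   Cα trace (least-squares proper rotation *R*, translation *t*,
   minimising RMSD, reflections excluded);
2. rotate about the M4 helix axis in 1° steps, counting inter-body
   heavy-atom clashes (pairs with d < 2.5 Å on side-chain-stripped models)
   at each angle, and keep the minimum-clash orientation;
3. map the query into the oriented template frame via their shared atoms;
4. report the composite transform, the clash-vs-angle profile and the pose.

If every orientation clashes above a ceiling, the groove is occupied and
the dock raises a "groove occluded" error — the expected outcome for the
long homolog, whose own filler rides along with the query.

**Interface scoring** (`groovedock.interface`). Shrake–Rupley solvent-
accessible surface area (SASA) on a deterministic golden-spiral quadrature,
and the buried (contact) surface area of a complex by the difference
formula

    buried = [SASA(A) + SASA(B)] − SASA(A ∪ B),

summed over both partners, plus contact residue pairs (d < 4.5 Å) and the
labels of the groove-lining helices.

**Assay statistics.**

* `groovedock.coloc` — per-cell co-localization by the automatic
  (Costes-style) threshold: regress ch2 on ch1, walk the threshold down the
  regression line until the below-threshold pixels are uncorrelated, then
  report Pearson's r over the above-threshold pixels (thresholded PCC).
* `groovedock.bifc` — bimolecular fluorescence complementation scoring:
  a cell is channel-positive iff intensity > 3.5 × its own background
  (strict), Venus intensities are normalized to the control-group mean,
  groups compared by Welch's ANOVA.
* `groovedock.groupstats` — Kruskal–Wallis (tie-corrected) with Dunn's
  post hoc pairwise z tests, Welch's one-way ANOVA, mean ± s.e.m.
* `groovedock.seqstats` — Stretcher-convention global protein alignment
  (BLOSUM62, affine gaps open 12 / extend 2, end gaps penalized) with
  percent identity and percent similarity over the full alignment length.

**Synthetic data** (`groovedock.synthetic_data`). Ideal TM helices (rise
1.5 Å, twist 100°, Cα radius 2.3 Å plus a pseudo-Cβ), the long/short bundle
pair, a four-subunit receptor fixture with protruding M4 helices, planted
ground-truth complexes at any rotation angle, two-channel puncta images
with a tunable co-localized fraction, and BiFC intensity tables with a
tunable reporter fold over background.

## Worked example

```python
import numpy as np
from groovedock import synthetic_data as sd
from groovedock.docking import template_guided_dock
from groovedock.interface import SasaParams, buried_area, groove_lining
from groovedock.structio import select

pair = sd.make_long_short_pair()          # NuoN-like long / ND2-like short
receptor = sd.make_receptor_fixture()     # 4 subunits, M4 outermost
scene = sd.plant_complex(pair, receptor, true_angle=40.0)

result = template_guided_dock(
    template=pair.long.structure, filler=pair.filler,
    query=pair.short.structure, receptor=scene.receptor,
    target_m4=receptor.m4_segments[0],
)
docked = result.transform.apply_structure(pair.short.structure)
rmsd = np.sqrt(np.mean(np.sum((docked.coords - scene.bundle.coords) ** 2, axis=1)))
iface = buried_area(docked, scene.receptor, SasaParams())
m4 = select(scene.receptor, "A", receptor.m4_segments[0])
lining = groove_lining(docked, pair.short.helices, m4)

print(f"best angle:   {result.best_angle:.1f} deg (planted 40.0)")
print(f"clash count:  {result.clash_count}")
print(f"pose RMSD:    {rmsd:.2e} A")
print(f"buried area:  {iface.buried_area:.0f} A^2")
print(f"groove walls: {lining}")
```

prints

```
best angle:   40.0 deg (planted 40.0)
clash count:  0
pose RMSD:    9.41e-15 A
buried area:  1741 A^2
groove walls: ['TM3', 'TM4']
```

The scan recovered the planted rotation exactly, the docked pose matches
the ground truth to machine precision, the complex buries ~1.7 × 10³ Å² of
accessible surface, and the probe contacts exactly the two helices that
flank the designed groove.

The same run is available from the shell:

```
groovedock simulate-structures --outdir fix --angle 40
groovedock dock --template fix/long.pdb --query fix/short.pdb \
    --receptor fix/scene_receptor.pdb --filler A:151-174 \
    --target-m4 A:813-836 --helices fix/short_helices.tsv --outdir run
```

Other subcommands (`coloc`, `bifc`, `align`, `stats`, `simulate-images`,
`simulate-bifc`, `interface`) are documented under `groovedock --help`.
Exit codes: 0 success, 2 configuration error, 3 data error, 4 groove
occluded.

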