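# sitefunc

Active-site residue mapping and sequence–function analysis for enzyme
families.

`sitefunc` is for enzyme engineers and protein biochemists who want to
mine a family alignment for *which* catalytic-pocket residues drive
activity, instead of screening blindly.  It grew out of work on the
flavin-dependent 4-phenol oxidoreductases (VAO/PCMH superfamily), where
17 first-shell residues of the eugenol oxidase pocket — grouped into
five functional clusters (P, T, H, W, A) — explain much of the
family's substrate-scope variation, but nothing in it is specific to
that family.

## What it computes

**Template-anchored mapping.**  All positions are expressed in the
numbering of a template crystal structure (for the built-in scheme:
*Rj*EUGO, PDB 5FXP).  A `PositionMap` ties the template's 1-based
residue numbers to alignment columns, so residue states can be read off
for every homolog, and positions can be renumbered into any homolog's
own coordinates (e.g. template I427 ↔ a homolog's own 432).

**Sequence–function correlations.**  For substrate *s*, position *p*,
and a residue property *V* (volume in Å³, hydropathy, polarity), the
package computes the Pearson product–moment correlation across family
members *e*:

    r(p, s) = corr( V(x_e(p)),  log10 v_e(s) )

where `x_e(p)` is the residue of enzyme *e* at position *p* and
`v_e(s)` its observed rate in s⁻¹.  Larger residues coinciding with
higher activity give r > 0.  A conserved position has *no* correlation
(distinct from r = 0, and reported as such); positions with fewer than
3 usable enzymes are reported as insufficient.  Positions with strong
|r| across substrates are ranked as **hot spots** — candidates for
site-saturation mutagenesis.  Combined-property regressions
(log10 activity vs. the summed volume of a position set) use ordinary
least squares.

**Supporting machinery.**  Per-clade residue diversity profiles;
criterion-based candidate selection ("T-cluster volume sum ≤ t");
p-distance matrices and neighbor-joining trees with nearest-reference
clade assignment; Michaelis–Menten / substrate-inhibition / Hill
fitting by deterministic multi-start nonlinear least squares;
screening-plate normalization `(raw − blank)/(wildtype − blank)` with
hit calling; and a synthetic-family generator that plants known
property→activity couplings so the whole pipeline is testable end to
end.

## Worked example

Simulate a family of 8 enzymes (3 clades) with one planted coupling —
log10 activity decreasing by 0.012 per Å³ of residue volume at position
40 — then recover it:

```python
from sitefunc import (FamilySpec, SequenceFunctionModel, build_position_map,
                      extract_site_states, family_scheme, generate_activities,
                      generate_family)
from sitefunc.profiles import VOLUME

family = generate_family(FamilySpec(seed=42))
activities = generate_activities(family, VOLUME, ["S1", "S2"])
scheme = family_scheme(family, extra_positions=(10, 20, 30))
pmap = build_position_map(family.alignment, family.ids[0])
states = extract_site_states(family.alignment, pmap, scheme)

results = SequenceFunctionModel(states, activities, VOLUME).fit()
print(results.summary())
```

```
Sequence-function correlation results
=====================================
property scale:     volume (A^3)
correlation:        pearson
below-detection:    exclude
positions:          4
substrates:         2
enzymes:            8
cells ok/conserved/insufficient: 4/4/0

correlation grid (r; '.' = conserved, 'x' = insufficient):
substrate    S1    S2
position             
40        -0.99 -0.98
10            .     .
20            .     .
30         0.78  0.77

hot spots (max |r| >= 0.7):
      position  max_abs_r  mean_abs_r  n_substrates supporting_substrates
rank                                                                     
1           40   0.992010    0.987658             2                 S1,S2
2           30   0.780224    0.775806             2                 S1,S2
```

The planted position 40 tops the hot-spot ranking with the correct
(negative) sign: small residues help, large residues hurt.  Positions
10 and 20 happen to be conserved in this family and are flagged, not
scored.  Position 30 picks up a weaker correlation by chance drift —
exactly the kind of runner-up a practitioner would weigh against the
diversity profiles before ordering primers.  The fitted combined-volume
line at position 40 has slope −0.0142 log10 units/Å³ (r = −0.99,
n = 8), consistent with the planted −0.012 plus noise.

Kinetics, on simulated Michaelis–Menten data (K_M = 33 µM,
kcat = 18 s⁻¹, 5% multiplicative noise at 8 substrate concentrations):

```python
import numpy as np
from sitefunc.kinetics import KineticDataset, fit_kinetics

conc = np.array([5, 10, 20, 40, 80, 160, 320, 640], dtype=float)
rng = np.random.default_rng(1)
v = 18.0 * conc / (33.0 + conc) * (1 + rng.normal(0, 0.05, conc.size))
print(fit_kinetics(KineticDataset(conc, v)).summary())
```

```
Kinetic fit: michaelis_menten
----------------------------------------
n points: 8  (distinct [S]: 8)
  kcat     =      18.22 ± 0.37 1/s
  K_M      =      33.73 ± 2.6 uM
  RSS      = 1.252
```

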