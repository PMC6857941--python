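# Methods

## Problem and model

UGT1A1 conjugates glucuronic acid from the coenzyme UDP-glucuronic acid
(UDPGA) onto a substrate hydroxyl. Coding variants of the enzyme change how
often docking places a substrate in a catalytically productive arrangement,
and the TA-repeat promoter polymorphism (*28) lowers expression without
changing the protein. `ugtcap` turns docking output into a capacity
prediction in three stages.

**Pose classification.** A substrate pose is *hydroxyl-oriented* when at
least one conjugatable hydroxyl oxygen lies within a cutoff distance of the
midpoint of UDPGA's glycosidic C–O bond (the bond broken during transfer).
The default cutoff is 3.8 Å, the sum of a donor–acceptor hydrogen-bond
distance (3.2 Å) and an empirical docking placement error (0.6 Å). Out of
`S_DT` docking runs (conventionally 100), `S_DH` poses are oriented. A
UDPGA pose is in the *correct binding mode* when its heavy atoms contact a
quorum (default 5) of the seven reported coenzyme-site residues S38, H173,
G308, L355, S375, H376, G377 within the same cutoff.

**Capacity model.** The conjugation capacity of a variant for substrate *l*
is

    P_c = σ · κ · [ 1 / (1 + e^(−γ_l (S_DH/S_DT − μ_l))) ]^(β_l) + ε,
    β_l = S_DT / S_DH(wild)

σ is a substrate-specific scale (capacity units), γ_l > 0 and μ_l ∈ [0, 1]
the sigmoid slope and midpoint, ε an in-vivo environment offset fixed at 0
for in vitro work, and κ the promoter factor: 1.0 (wild/wild), 0.74
(wild/*28), 0.21 (*28/*28), the ratios of reported Vmax values
16.2 / 12.0 / 3.4 nmol·min⁻¹·mg⁻¹ rounded to two decimals (an exact-ratio
mode is available). β_l is computed once per substrate from the wild-type
counts and shared by all variants. Relative capacity (percent of wild type)
divides out σ; with ε = 0 it is `100 · κ · S(mutant)/S(wild)`.

**Fitting and validation.** (σ, γ, μ) — and ε when explicitly released —
are estimated by minimising the sum of squared errors against in vitro
capacities over the fit set **M**: variants with a known capacity and at
least one correct coenzyme binding mode. The optimiser is bounded
trust-region least squares (`scipy.optimize.least_squares`, TRF) from 20
seeded random starts (μ uniform on [0, 1], γ log-uniform on [0.5, 50], σ
scaled to the data range); bounds are σ > 0, γ ∈ (0, 100], μ ∈ [0, 1]. The
best-SSE restart wins, ties broken by restart order, so a fixed panel and
seed give bit-identical constants. Validation is leave-one-out
cross-validation over M with Pearson's r and a two-sided t-test p-value
(`t = r√(n−2)/√(1−r²)`, n−2 degrees of freedom); the reported regression
line is ordinary least squares of observed on predicted.

## Design choices where the design was open

- **Distance atom.** The orientation distance is measured from the hydroxyl
  *oxygen*, never a hydrogen: pose files often omit or misplace hydrogens,
  and a heavy-atom criterion is reproducible across both conventions.
- **Boundary.** The cutoff is inclusive (≤ 3.8 Å): the cutoff is itself a
  sum of bound-like quantities, so the conservative reading keeps a pose at
  exactly the bound.
- **Hydroxyl definition.** A hydroxyl oxygen has exactly one carbon
  neighbour and no other heavy neighbour; when the molecule carries any
  hydrogens it must also bear exactly one H, which separates O–H from
  carbonyl/amide oxygens. In hydrogen-free files that separation is
  impossible and any terminal one-carbon oxygen qualifies. Carboxylic O–H
  counts (needed for substrates conjugated on a carboxyl, e.g. bilirubin).
- **Connectivity.** Bonds are inferred by the covalent-radius rule
  `d ≤ 1.2 (r_i + r_j)`; explicit CONECT records, when present, win. PDBQT
  ligand files rarely carry usable bond records.
- **Binding-mode quorum.** "Contacts the site" is made explicit as ≥ 5 of
  the 7 residues within the cutoff. Requiring all 7 is brittle when a site
  residue itself is mutated (an H376R-like variant renames the residue —
  this warns and still counts by residue number).
- **Variants with no correct UDPGA binding** are excluded from M and
  predicted as 0% with a distinct flag: the model's sigmoid is defined only
  where coenzyme binding happens, and zero is the only consistent extension
  for a disrupted site.
- **ND capacities** are censored observations, not zeros: they never enter
  fits, and enter correlations as zero only when explicitly requested
  (flagged in the output).
- **Scale convention.** σ absorbs units, so capacities may be supplied on
  any consistent scale; the bundled convention is percent-of-wild-type with
  the wild-type member anchoring 100. The wild-type enzyme is kept in the
  panel and in M, since it anchors σ's identifiability on small panels.

## Synthetic data: what it emulates and what it does not

The pose generator plants a controlled fraction of poses with the hydroxyl
oxygen inside the cutoff, drawing distances from disjoint bands
(default 2.4–3.6 Å inside, 4.2–9.0 Å outside) that leave ≥ 0.05 Å margin so
3-decimal file rounding cannot flip a label; placement is verified on the
quantised coordinates, and multi-hydroxyl templates are re-oriented until
*every* hydroxyl respects an outside label. Substrate templates are minimal
chemically plausible fragments (phenol + amide arm, para-diol, propane-diol,
acetic acid), not real conformers; the coenzyme fragment has one glycosidic
bridge by construction, and the receptor stub rings the seven site residues
around it.

The panel generator draws capacities exactly from the sigmoid model at each
variant's realised oriented fraction, scaled by κ, plus Gaussian noise
truncated at zero (panels emulating assay noise use sd = 5% of the
wild-type capacity, consistent with low-CV in vitro assays); capacities
below an ND threshold are censored. Passing tests therefore demonstrate
internal consistency — classifier vs planted geometry, fitter vs generating
constants — not docking realism: real pose sets have correlated geometries,
scoring bias, and model error the generator does not emulate, so recovery
on synthetic panels bounds, but does not guarantee, performance on real
docking data.

## Numerical notes

- Problem sizes: synthetic campaigns use 100 poses per substrate (the
  conventional number of docking runs) and panels of 20 variants plus wild
  type; cross-validation refits once per fit-set member.
- Pearson r is clipped to [−1, 1] to absorb a few ulp of rounding on
  collinear data; |r| = 1 returns the smallest positive double as its
  p-value, with a warning.
- Noise-free panels are recovered to well below 0.1% relative error; the
  documented guarantees are 1% (noise-free) and 15% (5% noise, fixed seed).
- Degenerate inputs fail loudly: zero wild-type orientations (β undefined),
  identical capacities (unidentifiable), fewer usable members than free
  constants, under-determined cross-validation folds, a substrate without a
  hydroxyl, and zero or multiple glycosidic bridges are all errors, not
  warnings.

## Known limitations

- The pipeline starts from docked poses; it does not run docking, build
  homology models, or relax structures.
- κ multiplies the coding-variant sigmoid; panels combining a coding
  mutation with *28 in one haplotype have not been calibrated.
- Constants are fitted per substrate; nothing is shared across substrates.
- ε ≠ 0 (in vivo offset) is implemented but not exercised by any bundled
  calibration.
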