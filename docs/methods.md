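# Methods

## Scope and conventions

All energies are in eV. Ionisation potentials and electron affinities
are stored as their negatives (`minus_ip`, `minus_ea`), matching the
frontier-level-like convention in which "deep" means more negative;
the optical gap `optical_gap` (ΔO) is a positive excitation energy.
The fundamental gap ΔF = (−EA) − (−IP) and exciton binding energy
EBE = ΔF − ΔO are derived, never stored independently; both identities
hold to machine precision by construction.

Molecules are handled as SMILES throughout. Duplicates are *defined* as
structures with equal RDKit canonical SMILES; canonicalization is
idempotent and invariant to input atom order (property-tested against
random atom renumberings). No 3D geometry, conformers or
stereochemistry enter any stage.

### Aromaticity

Two perception models are used, deliberately:

* canonical SMILES and fragment aromatic flags use RDKit's default
  additive model, under which azulene is aromatic as a whole;
* aromatic-*ring counting* re-perceives each molecule with the per-ring
  Hückel ("simple") model, under which a fused ring counts only if it
  is aromatic on its own. Azulene's 5- and 7-membered rings are not,
  so azulene and its derivatives count as zero aromatic rings, as do
  quinones.

This split mirrors how the chemistry reads: azulene is an aromatic
molecule whose constituent rings are not aromatic rings. The ring-count
convention for other ambiguous fused systems follows whatever the
per-ring Hückel rule yields; it is a convention, not a claim.

## Library enumeration

Eligible substitution sites are ring carbons carrying at least one
hydrogen that are aromatic or sp² (the latter admits the C−H of quinone
rings); N−H and O−H hydrogens are never substituted under the default
site policy (`allowed_sites="ring_carbon"`; `"any_h"` relaxes this).
"Up to two" substituents means combinations with repetition over the
substituent set placed on distinct sites. Dedup is global across
skeletons: if two skeleton+substituent routes reach the same canonical
structure, the first-encountered skeleton (spec order) is recorded as
parent and the collision is logged. Output ordering is deterministic
(skeleton order, then canonical structure), so identical specs yield
byte-identical libraries.

The enumeration is validated against an independent oracle that places
substituents by explicit graph surgery and deduplicates with
Weisfeiler–Lehman-hashed VF2 isomorphism (networkx), with no canonical
SMILES anywhere in the oracle path: benzene × 12 substituents × ≤2
placements gives 247 unique molecules on both routes.

### Substituent set

The strong acceptor (−NO2, −CN, −S(O2)OH, −CF3) and strong donor
(−NH2, −N(CH3)2, −OH, −OCH3) classes are fixed. The remaining four
groups of the twelve — F, Cl, CH3, COOH — are the package's choice of
common small non-aromatic substituents of intermediate electronic
character; analyses conditioned on donor/acceptor class are insensitive
to this choice by construction.

### Skeleton pool

A curated 11-skeleton pool ships with the package: benzene,
naphthalene, azulene, 1,4-benzoquinone, 1,4-naphthoquinone, furan,
pyrrole, pyridine, thiophene, 2,1,3-benzothiadiazole and
1,3,4-oxadiazole. It spans the structural axes the analyses probe —
plain hydrocarbons, a non-aromatic-ring aromatic, quinones, π-excessive
and π-deficient heteroaromatics, and the deep-−EA azole motifs — while
keeping the full enumerated library at 7601 molecules, small enough for
the whole pipeline to run in seconds.

## Hückel surrogate backend

The cheap property backend is a topological Hückel π-electron model:
on-site energies α_X = α + h_X·β and couplings β_XY = k_XY·β with
α = 0, β = −1, so orbital energies come out in units of |β| with
bonding levels negative. π centers are aromatic atoms, atoms in
C/N/O/S double bonds (bringing in quinone C=C/C=O and nitro N=O), and
lone-pair donor heteroatoms singly bonded to a center (amine N, phenol
O, halogens); each center contributes 1 electron if it carries a double
bond, aromatic C and pyridinic N contribute 1, pyrrolic N and aromatic
O/S contribute 2, and single-bonded donors contribute 2. h/k default to
the Van Catledge consensus table (e.g. h = 0.51 pyridinic N, 1.37
pyrrolic N, 0.97 carbonyl O; k = 1.02 C−N(1e), 0.89 C−N(2e), 1.06
C=O), shipped as an editable YAML. Unparameterized centers/bonds fall
back to h = 0.5, k = 0.7.

Frontier levels are found by Aufbau filling; an odd electron count
makes the singly occupied level both HOMO and LUMO. Affine maps convert
levels to eV proxies; the defaults anchor benzene (HOMO/LUMO = ∓1 |β|)
at −IP = −9.2 eV, −EA = +0.5 eV, ΔO = 4.8 eV. These anchors are
illustrative plumbing, not predictions: the surrogate exists to give
the pipeline deterministic, chemically *ordered* inputs (donors raise
the HOMO, electron-poor rings lower the LUMO, quinones have small
gaps), not quantitative chemistry. A gap floor of 0.05 eV keeps
degenerate open-shell cases from producing non-positive gaps.

Exact properties the tests rely on: the benzene spectrum equals the
6-cycle closed form 2cos(2πk/6) = {±2, ±1, ±1}; alternant-hydrocarbon
spectra are symmetric about zero (pairing theorem); the eigenvalue sum
equals the matrix trace.

## Synthetic data generator

`SynthConfig` defines the study conditions for offline testing:

* **Base skeleton properties** — one draw per skeleton from a
  trivariate Gaussian, mean (−7.0, −1.8, 4.0) eV, SDs (0.8, 0.9, 0.7),
  correlations corr(−IP,−EA) = 0.6, corr(−IP,ΔO) = −0.35,
  corr(−EA,ΔO) = +0.35 — −IP and −EA move together, and the gap grows
  as −IP deepens and −EA shallows. A modelling choice, not a measured
  covariance.
* **Substituent shifts** — mean first-substituent shifts (eV): strong
  acceptors (−0.6, −0.8) on (−IP, −EA), strong donors (+0.7, +0.5),
  others 0; per-instance Gaussian jitter SD 0.15 eV; gap shifts are
  zero-mean (SD 0.15 eV), substituents having no systematic gap
  effect. Shift magnitude scales linearly with the parent's own level
  (slope 0.25 per eV, clipped to [0.1, 3]): −IP shifts grow for
  deeper-−IP parents, −EA shifts for shallower-−EA parents — the
  substituent bites hardest when it counteracts the skeleton's natural
  electron richness or poverty. The second substituent's shift is
  multiplied by 0.7 (attenuation in (0,1]; "less than additive").
  Substituent multisets are stored sorted, and "first/second" means
  position in that order.
* **Cheap→reference relation** — reference = a·cheap + b + ε with
  near-unity slopes (0.95, 0.92, 1.08), rigid shifts (+0.35, −0.55,
  −0.20 eV) and Gaussian noise SDs (0.25, 0.15, 0.26 eV). The noise
  SDs are set so the implied calibrated MAE (σ√(2/π) ≈ 0.20, 0.12,
  0.21 eV) matches the error scale typical of tight-binding-to-DFT
  calibration of these quantities.

All randomness flows through one `numpy` generator seeded from the
config; identical configs give identical tables, and invalid configs
(negative SDs, zero attenuation, class shifts with the wrong sign,
non-PSD covariance) are rejected before any sampling. What the
generator does *not* emulate: real covariance between substituent
effects and skeleton identity beyond the linear level dependence,
heavy-tailed calibration residuals, systematic (non-rigid) curvature in
the cheap→reference relation, and conformational noise. Tests passing
on synthetic data therefore validate the statistical machinery, not
quantum-chemical accuracy.

## Calibration

One independent OLS fit per property, cheap as predictor and reference
as response (`scipy.stats.linregress`); no multivariate coupling.
Stored diagnostics: slope/intercept standard errors, MAE and RMSE of
calibrated-vs-reference, and of raw-vs-reference. OLS guarantees tested
as invariants: residuals sum to zero, RMSE(calibrated) ≤ RMSE(raw) on
the training set, refitting calibrated outputs gives slope 1 /
intercept 0. Fits are rejected for n < 2 or zero predictor variance.
Applying a calibration requires records at the "cheap" level and
relabels them "calibrated"; calibrated optical gaps are floored at
0.05 eV so the positivity invariant survives affine maps.

## Fragment census

Every heavy atom contributes its radius-0 environment (the atom) and
its radius-1 environment (atom + immediate neighbours + connecting
bonds, via RDKit's atom-environment extraction). Keys are canonical
fragment SMILES normalised through one canonicalizer
(parse-without-sanitization → canonical SMILES), so `CC(=O)C` and
`CC(C)=O` are one key and query spelling never matters. Keys are
strings, not hashed bit positions: a folded fingerprint's bit length
adds collision ambiguity and nothing else to a census, so it plays no
role here. Isomeric environments (`nsn` vs `nns`) are distinct keys.

The filter keeps radius-1 fragments with exactly three heavy atoms in
the ring system whose center is a heteroatom or a carbonyl-like carbon
(carbon bonded to a heteroatom having no other heavy neighbour, as in
−C(=O)−). Ring-system membership means membership in a ring of the
source molecule; for the quinone carbonyl environment `CC(=O)C` the
three carbons are ring atoms and the exocyclic O is not counted, which
is exactly what admits it at three. Flags are evaluated in the source
molecule at extraction time. Census membership is verified against
direct RDKit substructure search for every retained fragment over the
fixture library.

## Landscape analytics

* **Histograms** — `numpy.histogram2d`; counts conserve n for any
  binning (property-tested, plus a naive double-loop oracle).
* **KDE** — Gaussian kernel. A string bandwidth is a
  `scipy.stats.gaussian_kde` rule (default Silverman); a numeric
  bandwidth is the absolute kernel SD, implemented directly, which also
  covers zero-variance data. The evaluation grid extends 4 kernel
  widths beyond the data, so the density integrates to 1 within 1e-3.
* **Substituent shifts** — per molecule, property minus the parent
  skeleton's property; molecules lacking their own or their parent's
  record are skipped and reported.
* **Topography** — half-open cells (low edge inclusive) of side 0.5 eV
  by default, origin (0,0), both configurable (the defaults reproduce
  a visually useful granularity; no canonical increment exists). Cell
  winner maximises count-in-cell / count-in-dataset per skeleton, so
  normalized prevalence lies in (0,1]; ties break to the lowest
  skeleton id and are logged.
* **Convex hulls** — `scipy.spatial.ConvexHull` on the unique projected
  points; < 3 distinct points or collinear sets yield hulls flagged
  degenerate (vertices = sorted distinct points). Containment uses a
  vectorized cross-product test with 1e-9 tolerance; areas are
  validated against an O(n³) point-in-triangle oracle.
* **Region queries** — strict inequalities only, matching the "<"/">"
  phrasing such queries are stated in; constraints parse from strings
  like `"minus_ip>-6, minus_ea<-4"`.

## Pipeline and problem sizes

`run_pipeline` wires the stages over the bundled pool (or a user
skeleton file), writing every stage table plus a manifest (config,
config hash, seed, version, per-stage summaries). Reruns with the same
config and seed are byte-identical; input paths are validated before
any computation; a failing stage still writes the manifest with the
failure point. The bundled-pool run (7601 molecules) takes ~15 s on one
CPU; the full test suite ~12 s; the acceptance script ~25 s. These
sizes were chosen so a complete run is an interactive operation.

## Known limitations

* The Hückel surrogate has no σ framework, solvation or exchange
  effects; acceptor groups acting through σ withdrawal (e.g. −CF3)
  barely move the −IP proxy, and absolute values are meaningless — only
  orderings are used.
* Fragment flags (ring membership, carbonyl character) are taken from
  the first molecule that exhibits the key; for libraries mixing cyclic
  and acyclic occurrences of the same environment the flags follow the
  first encounter.
* The enumeration supports at most two substituents, per the screening
  design it implements.
* The deposited-data checks (calibration MAEs, 413→29 census, empty
  forbidden regions) only run when the external raw tables are placed
  under `data/external/`; nothing synthetic stands in for them.
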