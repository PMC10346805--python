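# Methods

This note documents the model and procedure behind `pepadsorb`, the choices
made where the workflow admitted several reasonable designs, and what the
desk-scale synthetic tests do and do not demonstrate about real systems.

## Adsorption-center identification

A host structure carries per-atom partial charges in units of elementary
charge e (in practice Mulliken charges from an electronic-structure
calculation; the package treats them as input data). The center search:

1. **Screening window.** Candidate atoms have charge inside
   `[lower, upper]`, default **[−1.0, −0.1] e**. The canonical screening
   band for strongly charged centers is −0.5 to −1.0 e, but observed center
   sets include members near −0.1 e and the band is explicitly
   structure-dependent; the wider default covers all five reference
   peptides' center sets. The window applies to *individual* atom charges;
   the group's excess charge is the sum over members. (Whether screening
   should act on atom or group charge is not fixed by the workflow's
   description; atom-level screening followed by summation is the simplest
   consistent reading.)
2. **Grouping.** Candidates are clustered by single linkage at the
   `grouping_radius`, default **1.8 Å** — the covalent-neighbour scale, so a
   carboxylate's two oxygens merge but chemically separate sites do not.
   The 1–3-atom cap is enforced by keeping a too-large cluster's three most
   negative members and returning the remainder to the candidate pool for
   re-clustering, preserving the screening intent (the most charge-dense
   kernel of the site survives).
3. **Ranking and labels.** Groups are ordered by summed excess charge
   ascending (most negative first); ties break on the group centroid's
   lexicographic (x, y, z) order, which makes the result independent of the
   input atom ordering. The top `k` (default **8**, matching the reference
   studies' per-peptide center count) are labelled `a, b, c, …` in rank
   order. Published per-structure letterings are positional, not
   rank-based; the shipped fixture tables therefore keep their original
   letters, while freshly computed centers always carry rank-order labels.

## Energy model

The pipeline is agnostic to the energy backend; an `EnergyModel` maps one or
more structures to a total energy in eV and must be evaluable on an isolated
molecule as well as a complex (binding energies need both). Backends may
provide analytic gradients (eV/Å) and post-evaluation per-atom charges.

The built-in **classical model** is:

- **Intermolecular**, over all host–analyte atom pairs:
  12-6 Lennard-Jones `4ε[(σ/r)¹² − (σ/r)⁶]` with UFF-derived per-element
  σ/ε for H, C, N, O, S (packaged in `data/classical_params.yaml`;
  Lorentz–Berthelot combination), plus Coulomb `k q᷊ᵢqⱼ/r` with
  k = **14.3996 eV·Å·e⁻²**.
- **Intramolecular**: an elastic network — a harmonic spring
  (k = **2.0 eV/Å²**) on every pair closer than **3.0 Å** in the reference
  geometry captured at model construction. This gives each molecule a
  deformable but shape-retaining skeleton, so "geometric adaptability"
  (volume change on binding) is expressible without a bonded force field.
  At the reference geometry the intramolecular energy is exactly zero, so
  isolated-molecule reference energies vanish and every converged docking
  yields E_bind ≤ 0.
- **No polarization**: charges are fixed inputs and `charges()` echoes
  them. Charge-redistribution metrics are therefore only meaningful with an
  external engine or with engine-style charge fixtures.

This classical surrogate is *not* a tight-binding method and its absolute
binding energies are not comparable to published quantum values; it exists
to make the workflow's algorithmics (center search, pose scan, optimizer,
bookkeeping, reporting) fully testable offline. The
`external_engine_adapter` defines the contract for plugging in a quantum
engine (construction fails fast if the executable is missing; the engine
prints a total energy in eV, optionally per-atom charges).

## Pose generation and optimization

At each center the analyte's centroid is placed at
`center_centroid + d·û`, where `û` points from the host centroid through the
center (outward approach) and d = **3.0 Å** (just outside van der Waals
contact for these parameters); **24** uniformly random orientations are
drawn from a seeded generator. Poses with any host–analyte pair closer than
0.8 Å are discarded; a center where every pose clashes is marked failed.
The defaults trade pose coverage against cost; with 24 orientations the
deep-well recovery experiment below succeeds in ≥95% of seeds.

Each surviving pose is relaxed by a limited-memory quasi-Newton (L-BFGS,
history 10) descent with Armijo backtracking; *all* atomic coordinates of
both molecules vary. Accepted steps never increase the energy. Convergence
is declared when the energy decrease of an accepted step falls below
`tolerance × n_atoms`, with tolerance default **10⁻⁴ eV/atom** (the
convergence metric itself — per-atom energy change — is this package's
stated choice; it is configurable). Hard cap: 2000 iterations. A failed
line search (no step satisfies Armijo above 10⁻¹²) is treated as numerical
stationarity. Non-finite energies raise, carrying the last valid geometry.

Isolated-molecule reference energies in
`E_bind = E_complex − (E_host + E_analyte)` come from independent
minimization of host and analyte alone under the same model — standard
binding-energy practice. Ties for the most active center break on label
order, everywhere.

## Metric panel

- **Volume adaptability**: host volume is the product of coordinate extents
  (axis-aligned bounding box) in the input frame, all atoms included —
  coordinate extrema are the only reproducible definition absent a stated
  frame convention, and before/after volumes are compared in the same
  frame. Negative ΔV = contraction. Hydrogens are included; this is a
  deliberate choice and flagged here because the alternative (heavy atoms
  only) changes Vp₀ but barely changes ΔV.
- **Hydrogen-bond contacts**: distance-only classification of every H in
  either molecule against N/O acceptors in the other, windows **N–H
  1.942–2.108 Å** and **O–H 1.998–2.690 Å** by default. These windows are
  observed physisorption ranges adopted as defaults, not physical criteria;
  both are configurable. No angular criterion is applied.
- **Charge transfer**: Σq(analyte, adsorbed) − Σq(analyte, isolated), on
  analyte atoms only.
- **Unit conversion**: 1 eV = **23.060548 kcal/mol** (CODATA-derived),
  applied unrounded and formatted to two decimals only in reports. This
  constant reproduces all reported eV↔kcal/mol pairs within 0.01.

Volume reports are emitted in Å³ only.

## Synthetic data

`make_host` emulates the structural premise of the screening step: a
peptide-scale molecule (default **80 atoms** in a 20 Å cube, ≥1.0 Å atom
spacing, rejection-sampled) carrying `n_wells` localized charge wells —
1–3-atom clusters, mutually ≥8 Å apart, holding a summed charge of
**−0.7 e** each by default (configurable per well) — on a near-neutral
background. Background charges are drawn from a normal with SD **0.05 e**
*truncated at ±1.9 SD* so that background atoms never enter the default
screening window: the premise being emulated is precisely that only the
wells are adsorption centers. The residual is removed by a uniform shift of
the background, making the molecule exactly neutral. Well atoms are
assigned O (70%) or N; the rest follow peptide-like element frequencies.
Everything is deterministic per seed.

What this generator does **not** emulate: real covalent topology and
geometry, conformational ensembles, charge distributions computed from an
electronic structure, or sulfur-specific effects. Passing the recovery
experiments therefore shows that the *algorithm* finds engineered wells and
energy-favourable centers under controlled conditions — not that it would
rank real peptides as a quantum treatment would.

Analyte geometries are idealized rigid structures (standard bond lengths
and angles, generated once from canonical connectivity and frozen into the
package) with simple zero-sum dipolar reference charges per molecule.
Stored molar masses follow the reference values where published (note the
lightest analyte's stored mass, 18.039 g/mol, corresponds to NH₄ although
the shipped geometry is NH₃; the published value is kept as the reference).

The `synthetic_*` fixture files are constructed stand-ins: the
DSWAADIP/ethanol complex realizes the published 1.700 Å minimum distance
with an H···H closest pair, the CIHNP/acetone energy triple differences to
the published −0.71 eV, and the engine-style charge tables transfer net
charges inside the published [−0.100, +0.035] e range. Their absolute
coordinates/energies are synthetic, as their names and headers state.

## Problem sizes and numerical choices

- Recovery experiments run 100 seeds (center recovery on single-well hosts;
  deep-well selection with one −0.9 e and three −0.15 e single-atom wells,
  acetone probe, default 24 orientations); the acceptance bar is ≥95%.
- Optimizer descent is checked over 50 seeded starts; gradient correctness
  against central finite differences (step 10⁻⁵ Å, relative error < 10⁻⁴)
  over random configurations.
- Pipeline reruns must be byte-identical for identical config + seed: a
  single master seed feeds crc-keyed, stage-local substreams, and reports
  use fixed column order and "." decimals.
- Degenerate inputs: a single-atom structure has zero volume; an empty
  screening result returns an empty list with a warning; a center where all
  poses clash is excluded from the argmin; ties always break on label order.

## Known limitations

- The classical model's energetics are qualitative; no self-consistent
  charges, dispersion beyond 12-6, entropy, or solvent.
- No global conformational search: the pose sweep plus local minimization
  finds nearby minima only.
- Bounding-box volume is frame-dependent by construction; comparisons are
  only meaningful within a shared frame.
- H-bond classification by distance alone will admit geometrically poor
  contacts that an angular criterion would reject.
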