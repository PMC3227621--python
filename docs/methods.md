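# Methods

## System and scope

The pipeline implements the analysis layer of a structure-based short-
peptide screen against a protein–protein interface: the Elk-1 ETS domain
homodimer is the motivating system (an ~85-residue winged helix-turn-helix
DNA-binding domain whose α1β1 loop, residues ~16–23, forms the dimer
interface). The molecular-dynamics engine, the docking engine and its
scoring functions, conformer generation and tautomer enumeration are all
upstream tools and deliberately out of scope; the pipeline consumes their
outputs (PDB structures, multi-model PDB or dihedral-table trajectories,
delimited score tables) and produces the interface tables, cluster
assignments, rankings and fingerprints.

## Structures and geometry

PDB ATOM records are read into a minimal chain→residue→atom model.
Hydrogens, waters and HETATM groups are dropped: every downstream operation
is defined on protein heavy atoms and crystal structures rarely resolve
hydrogens. Alternative locations are resolved to the highest-occupancy
conformer; exact ties go to altloc `A`, then lexicographically — a fixed,
order-independent rule so re-parsing is idempotent.

Superposition is least-squares (Kabsch) via SVD with reflection correction,
so the returned rotation always has determinant +1; an improper fit would
be physically meaningless for chiral molecules. Degenerate (collinear)
point sets are rejected rather than silently fitted. RMSD conventions:
global backbone RMSD is computed after a Cα fit; the per-residue value is
the RMSD over that residue's four main-chain atoms (N, CA, C, O) *without*
refitting, then averaged over frames with its SD. The profile code accepts
an optional fit-residue subset so a locally mobile region can be excluded
from the global fit.

Radius of gyration defaults to all protein heavy atoms, mass-weighted, with
both choices exposed as flags — reported RoG values in the literature
rarely state the selection, so the default is a documented convention, not
a claim about any particular published number.

Torsions follow the IUPAC convention (cis = 0°, range (−180°, 180°],
sign by the standard atan2 formulation). Note the convention's actual
symmetries, which the property tests assert: a torsion is *invariant*
under traversal reversal (a,b,c,d → d,c,b,a) and under rigid motion, and
changes sign under mirror reflection.

## Interface analysis

Contacts and hydrogen bonds are purely geometric, using LIGPLOT-style
heavy-atom distance windows: non-bonded contacts 2.90–3.90 Å, hydrogen
bonds 2.70–3.35 Å restricted to donor/acceptor-typed pairs. A fixed
donor/acceptor table covers the 20 standard residues (backbone amide N
donates except proline; backbone carbonyl O and OXT accept; His and the
Ser/Thr/Tyr hydroxyls act as both). No D–H–A angle term is applied by
default — the distance windows are the whole criterion — because donor
hydrogens are generally absent from the inputs; this is deliberately
simpler than HBPLUS's full criteria.

Accessible surface area uses Shrake–Rupley quadrature: each atom's solvent
sphere (van der Waals radius + 1.4 Å probe) is sampled at 960
deterministic golden-spiral points and the exposed fraction scaled to the
sphere area. Radii are a NACCESS-like Chothia set (C 1.87, N 1.65, O 1.40,
S 1.85, P 1.90 Å), configurable. At 960 points the isolated-sphere error
is below 0.5% and halving/doubling the point count moves toy-system totals
by under 1%; an independent library implementation (biotite) agrees within
1% at matched radii.

Per-residue interface contributions are ΔASA = ASA(chain alone) −
ASA(chain in complex), clipped at zero (complexation can only bury
surface; small negatives are quadrature noise). The percentage denominator
is the chain's *total* buried area over all residues with ΔASA > 0, so the
percent column always sums to 100 even when only a subset of residues is
tabulated; a flag averages the percentages over both chains of a homodimer.

## Trajectory clustering

Backbone φ/ψ series are extracted per frame for a chosen residue range.
Dispersion is the circular standard deviation √(−2 ln R̄) (R̄ = mean
resultant length), which respects wraparound; an unwrap-then-arithmetic
variant is available and agrees to <2% at small dispersion (σ ≈ 5–10°).

Clustering is single-pass leader clustering in time order: a frame joins
the first cluster whose *founding* frame lies within the threshold
(distance = RMS of wrapped per-angle differences over the 2k selected
angles), else founds a new cluster. After the pass, centres are recomputed
as per-angle circular means and each cluster's representative is the
member frame nearest its centre (ties → earliest). The algorithm is
deterministic given frame order and directly implements
"threshold defines cluster size" semantics. The default threshold is the
mean circular SD of the selected angles over the whole series — a
data-derived radius that sits between thermal within-state spread and
between-state separation for metastable loops, which is exactly the regime
in which representative-conformer extraction is meaningful. For residues
i..j the clustered angles are φ and ψ of those residues only (boundary
torsions shared with flanking residues are not included).

## Peptide libraries and HAC

Libraries are exhaustive over the 20 genetically encoded amino acids:
20ⁿ sequences in lexicographic order. The heavy atom count of a linear
peptide is composition-only: Σ(free-amino-acid heavy atoms) − (n−1),
one water oxygen lost per peptide bond. The per-residue table (G 5 … W 15)
equals the heavy atoms of the free amino acids' molecular formulas and is
validated in tests against 38 published (sequence, HAC) pairs.

SMILES are assembled from per-residue templates as zwitterionic parents at
pH 7.4: ammonium N-terminus ([NH3+], or ring [NH2+] for proline),
carboxylate C-terminus, Asp/Glu deprotonated, Lys/Arg protonated, His
neutral (standard pKa). Tautomer enumeration is intentionally not
performed — tautomer counts are tool- and version-dependent — but every
record carries a `tautomer_id` so externally enumerated tautomer score
rows flow through ranking and are collapsed to the best-scoring state per
peptide. Emitted SMILES are checked (via RDKit, an independent parser)
to contain exactly the composition-derived heavy atom count. The sanity
filter rejects protonated carbonyls, deprotonated amines, anionic amides
and structures lacking formally charged termini, as substructure/formal-
charge checks; template parents always pass.

## SILE ranking

Scores follow the docking convention (more negative = better);
affinity = |score|. Ligand efficiency LE = affinity/HAC over-corrects for
size in wide-HAC screens, so ranking uses the size-independent form
SILE = affinity / HAC^(1−x). The exponent x is fitted by ordinary least
squares of ln(LE_max) on ln(HAC), where LE_max is the maximum LE at each
distinct HAC pooled across all receptor conformations (no binning —
every distinct HAC contributes one point). x = −slope, k = intercept; a
warning is raised outside [0, 1]. The generic literature value 0.7 is the
documented fallback when no fit is wanted. Di- and tri-peptide tables are
fitted and ranked separately. Ranks (1 = best) are assigned per receptor
by descending affinity and descending SILE, ties broken by lexicographic
sequence for determinism. When all HACs are equal the two rankings
coincide exactly; multiplying all scores by a positive constant leaves x
and all orderings unchanged (the scale moves into k).

## Fingerprints

An interaction fingerprint records, per docked complex, every receptor
residue hydrogen-bonded to the peptide in either donor/acceptor direction
(a flag widens this to all non-bonded contacts). The class comes from the
peptide-side atom: N/CA/C/O/OXT are backbone ("mainchain"), everything
else is side chain ("specific"); a residue receiving both kinds is "both"
and counts as specific. A residue is counted once regardless of how many
bonds reach it. Specificity defined this way measures sequence-dependent
recognition: a poly-glycine peptide can never make a specific contact.

## Synthetic data: what it emulates and what it does not

* `gen_scores` emulates the additive size bias of docking scores: per-HAC
  efficiencies undershoot a power-law envelope exp(k)·HAC^(−x_true)
  (exponential log-depth, mean 0.4; lognormal wiggle σ = noise_sigma,
  default 0.05), with one peptide per HAC forced exactly onto the
  envelope so the fit target is well-posed — the envelope fit uses only
  the maxima, so the generator controls them directly. Defaults: 20 HAC
  values (10–29), 50 peptides per HAC.
* `gen_dihedrals` emulates a metastable loop: a weighted mixture of
  angular states with von Mises noise (κ = 33 ≈ 10° thermal spread, the
  magnitude typical of stable backbone torsions), returning planted labels
  for recovery scoring.
* `gen_toy_complex` lays out donor/acceptor pairs at exact distances,
  20 Å apart so pairs never interfere.

All generators are pure functions of (config, seed). What passing tests on
them shows: the fitting, clustering and counting machinery recovers known
ground truth under realistic noise at study-scale sizes (10⁴ frames,
10³–10⁴ score rows). What they do not show: behaviour on correlated MD
noise (frames here are i.i.d., real trajectories are autocorrelated and
states are visited in contiguous runs), on real docking score
distributions, or on crystallographic pathologies (missing atoms, altloc
chains, non-standard residues) beyond the cases the parsers explicitly
handle.

## Numerical choices and limitations

* Angles are held in degrees in (−180°, 180]; all differences are wrapped
  before use.
* ASA quadrature noise bounds the ΔASA ≥ 0 clip at ~0.1 Ų; percentages
  are reported to 4 decimals and sum to 100 ± 0.01.
* Cluster founding depends on frame order (inherent to leader
  clustering); on well-separated states the final labelling is
  order-insensitive in practice, and centres/representatives are always
  recomputed from full membership.
* The envelope fit needs ≥ 2 distinct HAC values and strictly positive
  LE_max; peptides with zero affinity never enter the envelope.
* Published screen-specific exponents (e.g. 0.649/0.665 for di-/tri-
  peptide screens) are not reproducible without the original score
  tables; the pipeline instead proves exponent *recovery* on synthetic
  screens with known truth, and ships 0.7 as the generic fallback.
* Analysis drivers run at 10⁴ frames and 400×12 score rows — sizes at
  which every stage completes in seconds while keeping binomial noise on
  occupancies well under the 2-point reporting tolerance.
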