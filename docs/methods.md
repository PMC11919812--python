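# Methods

This note documents the model behind the detector, the numerical choices,
what the synthetic fixtures do and do not emulate, and the known
limitations.

## The detection model

An intramolecular isopeptide bond is identified by the spatial
arrangement of a three-residue motif: the bond-forming lysine, the
bond-accepting asparagine/aspartate, and the catalytic aspartate or
glutamate whose carboxylate hydrogen-bonds the reacting amine. The three
recognized triad chemistries are Lys–Asn–Asp, Lys–Asp–Glu and
Lys–Asn–Glu; each bond is also assigned a domain topology, CnaA-like or
CnaB-like, inherited from the closest-matching template.

**Template matching.** A template stores only labeled side-chain atoms:
Lys CB/CG/CD/CE/NZ; acceptor Asn/Asp CB/CG/OD1; catalytic Asp
CB/CG/OD1/OD2 or Glu CB/CG/CD/OE1/OE2. The acceptor carries no second
hetero-atom on the acyl carbon because in the bonded state the amide
nitrogen of the cross-link belongs to the lysine NZ. The search
enumerates residue triples with strict type matching per role, prunes
candidates whose pairwise inter-atom distances deviate from the
template's by more than `distance_tolerance`, and scores survivors by
Kabsch-superposition RMSD. Asp OD1/OD2 and Glu OE1/OE2 are tried under
both namings (deposited naming is arbitrary) and the lower-RMSD
assignment kept. Cross-chain triads are allowed. Per site only the
lowest-RMSD template is retained, ties broken by lexicographic template
id.

*Parameters.* `rmsd_cutoff` = 2.0 Å: matches worse than this are noise
under every template geometry we generate. `distance_tolerance` = 3.0 Å:
this is a pre-screen, not a filter of record — the RMSD cutoff is what
bounds reported matches. The slack is calibrated so that planted sites
remain recoverable up to 0.5 Å per-atom coordinate noise: the screen
takes the maximum absolute deviation over all ~78 atom pairs of a
12–13-atom correspondence, and the maximum of that many pair deviations
(each with standard deviation σ√2) demands roughly 4σ√2 of slack at
σ = 0.5 Å. Both are exposed as CLI flags.

**Identity exclusion (evaluation mode).** When benchmarking against
structures that also sourced the templates, any match whose template
flank sequence aligns to the target-site flank at > 30% identity is
discarded before best-hit reduction. The flank is the window from 20
residues upstream of the first triad residue to 20 downstream of the
last, in modeled-sequence order, truncated at chain ends; for cross-chain
sites the window is built on the lysine's chain. Identity uses an optimal
global alignment without terminal gap penalties (BLOSUM62, gap open 10 /
extend 1), with identity = identical columns / alignment length. The
threshold is strict: exactly 30.0% is retained. Plain prediction runs do
not apply the exclusion.

**Features and classifier.** SASA is Shrake–Rupley with a deterministic
Fibonacci point lattice (default 500 points/atom, probe 1.4 Å, Bondi-type
element radii); hydrogens are ignored, HETATM ligands occlude. Residue
rASA divides by the Rost–Sander maximum for the residue type; the site
feature is the arithmetic mean over the triad (symmetric and bounded; the
reduction is a package choice). The classifier is an L2-regularized
(C = 1.0) logistic regression over (RMSD, rASA) with no feature
standardization; it is persisted as a plain-text parameter file and
applied as a closed-form sigmoid, so predictions do not depend on the
fitting library. The decision rule is strictly `p > threshold` (default
0.5): a probability exactly at the threshold is a negative call.

**Geometry QC.** The bond length is the NZ–CG distance (NZ–CD for a
glutamate acceptor); its Z-score against the reference mean/SD flags
|Z| > 4, strictly, two-sided. Pseudo-dihedrals treat the cross-link as a
peptide-bond analogue along CD–CE–NZ–C(acyl)–CB–CA: pseudo-φ =
CD–CE–NZ–C, pseudo-ω = CE–NZ–C–CB (torsion about the amide C–N),
pseudo-ψ = NZ–C–CB–CA; IUPAC sign convention, range (−180°, 180°]. Six
kernel-density models (three angle pairs × two topologies) score the
pairs; the outlier cutoff per model is the 5th percentile of the
reference sample's own log-likelihoods, so ≈5% of reference geometries
flag by construction. A site flagged by any component (Z-score or any
pair) is reported `outlier`. QC runs only for sites classified as bonds;
measurements with missing atoms are reported as NA and never flag.

*KDE numerics.* Each angle dimension is re-centered on its circular mean
before the Euclidean KDE is fitted — without this, a trans-ω population
straddling ±180° inflates the sample covariance (and hence Scott's-rule
bandwidth) by more than an order of magnitude and destroys sensitivity.
Samples still within 20° of the re-centered cut are mirrored across it,
and likelihoods are rescaled so the density integrates to ~1 over one
period (verified to 2% by quadrature in the tests). This is a pragmatic
alternative to a fully toroidal (von Mises) estimator, adequate for
unimodal reference distributions; a multimodal reference spread around
the circle would need the toroidal treatment.

## Structure handling

gemmi parses both PDB and mmCIF natively (no conversion step). Only the
first coordinate model is kept; NMR ensembles are not averaged. Waters
are dropped; other HETATM residues are retained, flagged nonstandard,
excluded from matching, and included as SASA occluders. Alternate
locations resolve to the highest-occupancy conformer, ties keeping the
first in file order. Author numbering is reported in outputs. The output
TSV has a fixed documented column order and deterministic row order, so
reruns are byte-identical.

## Synthetic fixtures

The generator builds every input the pipeline consumes, from internal
coordinates (natural-extension-reference-frame placement with standard
bond lengths and angles), deterministically per seed.

* **Planted positives**: an idealized bonded triad reproducing a
  requested bond length and pseudo-dihedral triple exactly at zero noise,
  embedded in a 55-residue chain whose remaining residues are a
  backbone-only self-avoiding walk placed away from the site (sequence
  context without spurious matchable side chains). Burial is emulated by
  a carbon lattice filling a 2.5–5.5 Å shell around the triad, which
  drives triad rASA near zero the way hydrophobic-core packing does.
  Noise is i.i.d. isotropic Gaussian on every atom.
* **Decoys**: self-avoiding CA walks dressed with full side chains
  (including Lys/Asn/Asp/Glu, so the matcher is genuinely exercised),
  rejection-validated to produce zero template hits at the configured
  search settings.
* **Templates**: six ideal-geometry triads (2 topologies × 3 triad
  chemistries) with random flank sequences standing in for the template
  parents' sequence context.
* **Geometry reference**: 500 samples per topology with dihedrals drawn
  from per-topology wrapped normals — CnaA-like centered at
  (φ, ψ, ω) = (−120°, 130°, 180°) (trans), CnaB-like at (−75°, 150°, 0°)
  (cis), SDs 12°/12°/8° — and bond lengths from N(1.33 Å, 0.05 Å).
* **Default classifier**: fitted on simulated site features (positives
  RMSD ~ N(0.3, 0.1), rASA ~ N(0.1, 0.05); negatives RMSD ~ N(1.5, 0.2),
  rASA ~ N(0.5, 0.1); 500 per class), emulating the separation between
  true buried bonds and incidental surface matches. The model file is
  labeled synthetic-trained and is replaceable via `--model`.

The standard evaluation corpus is 20 planted positives at σ = 0.2 Å
(buried) plus 50 decoys of 60 residues; these sizes keep the whole suite
and the acceptance script fast while leaving every statistic
well-determined.

**What passing on fixtures does not show.** The fixtures contain no
crystallographic artifacts beyond hand-written parser cases (altlocs,
HETATMs), no homologs, no near-miss triads (e.g. unbonded Lys/Asn pairs
at hydrogen-bond distance), and their feature distributions are cleanly
separated by construction. Perfect recall/precision on the corpus
validates the machinery end to end — matching, burial scoring,
classification, bookkeeping — not the hardness of the real PDB-scale
discrimination problem, which depends on a curated template set and a
classifier trained on real bonds.

## Numerical and degenerate-input choices

* Fibonacci sphere lattice fixed in the lab frame: SASA is
  bit-reproducible per orientation; rigid rotations re-sample each sphere,
  changing totals by < 0.5% (per-residue jitter ~1–2%) at 500 points.
* Kabsch RMSD via `scipy.spatial.transform.Rotation.align_vectors`
  (proper rotations only); an explicit SVD implementation serves as a
  test oracle.
* Dihedral of collinear atoms is undefined; the generator never emits
  them, and parser-sourced degenerate quadruples surface as NaN from the
  normalization rather than being silently clamped.
* Residues missing every heavy atom get NaN SASA and are flagged;
  residue types without a Rost–Sander maximum raise an error naming the
  residue.
* Empty match sets, empty chains and header-only outputs are valid;
  a run fails only when every input structure fails to parse.

## Limitations

* The bundled model, templates and reference are synthetic stand-ins;
  real-data use requires dropping in curated equivalents (the file
  schemas are documented in the module docstrings).
* The KDE is Euclidean-with-recentering, not toroidal.
* Only 3-residue templates are supported; this is a bond detector, not a
  general motif-search engine.
* Multi-model files contribute model 1 only.
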