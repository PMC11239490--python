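# Methods

## Scope and model of the problem

glycrunch implements a complete desk-scale pipeline for structural glycomics
by LC–MS/MS: glycans are rooted labeled trees (nodes = monosaccharides with
optional site modifications, edges = glycosidic linkages, root = reducing
end), MS2 spectra are peak lists with precursor m/z and retention time, and
structure assignment is a multiclass classification over a reference library,
followed by domain-knowledge curation. The package contains its own simulator
of in-silico fragmented spectra so that every stage — parsing, mass
arithmetic, fragment enumeration, annotation, binning, training, inference —
is exercised end to end without any external data.

## Glycan representation

IUPAC-condensed strings are parsed into trees; the canonical serialization
sorts the children of every node by (linkage label, canonical subtree string),
which makes structure equality, deduplication and round-tripping well defined.
A reduced (alditol) reducing end is written with a trailing `-ol`. Wildcard
linkages (`?1-?`) compare as literal strings in canonicalization and match any
linkage during subgraph embedding when wildcards are enabled.

Motif fingerprints count monosaccharides and linkage-typed disaccharide
motifs (child+linkage+parent) against a vocabulary built from the reference
library and then frozen; out-of-vocabulary motifs at inference are ignored so
that the distance geometry is stable. We count linkage-typed disaccharides; a
linkage-agnostic alternative would merge, e.g., Galβ1-3GalNAc and
Galβ1-4GalNAc motifs and coarsen the structure distance. Structure distance is
cosine distance between fingerprints; composition distance is cosine distance
between residue-class count vectors. A glycan whose motifs are entirely
out-of-vocabulary has a zero fingerprint; its distance is defined as 0 to an
identical glycan and 1 to anything else.

Biosynthetic precursors are the single-leaf deletions of a structure
(deduplicated by canonical form); the biosynthetic network implied by a set of
observed structures is the transitive closure of these deletions. This
encodes the assumption that glycans are extended one monosaccharide at a time,
so observed structures imply their intermediates.

## Mass arithmetic

Element masses are CODATA/IUPAC monoisotopic values; residues are dehydrated
formulas (Hex C6H10O5, HexNAc C8H13NO5, dHex C6H10O4, Neu5Ac C11H17NO8,
Neu5Gc C11H17NO9, Pen C5H8O4, Kdn C9H14O8; sulfation +SO3, phosphorylation
+HPO3). An intact glycan is the residue sum plus one water, plus 2 H for an
alditol. Ionization: deprotonation in negative mode at any charge; acetate
([M+OAc]−, modeled as acetic-acid attachment then deprotonation) and sodium
([M−2H+Na]−, [M+Na]+) adducts at charge 1. Permethylation is supported as a
per-residue methyl-site bookkeeping table (documented in `masses.py`); the
reference configuration throughout is underivatized, reduced, negative mode.

Composition inference from a precursor m/z enumerates bounded compositions
(Hex ≤ 9, HexNAc ≤ 7, dHex ≤ 4, Neu5Ac ≤ 4, Neu5Gc ≤ 2, S ≤ 2) over charges
1..max and rank matches by absolute error. Exact isobaric degeneracies exist —
Hex+Neu5Ac has the same elemental formula as dHex+Neu5Gc — so ties are broken
by parsimony: fewer residue classes, then fewer rare residues (Neu5Gc, Kdn,
Pen, S, P). The default matching tolerance is 0.5 Da everywhere.

## Fragment enumeration and annotation

Every fragment of a tree glycan is an induced connected subgraph plus a record
of boundary cleavages. Subgraphs are enumerated deterministically by a
per-node memoized product over children (a connected subgraph is its top node
plus, independently per child, an optional connected subgraph of that child's
subtree); this is exhaustive and reproducible, and is cross-checked in the
test suite against brute-force subset enumeration.

Cleavage bookkeeping (neutral masses): fragment = retained residue masses
+ H2O, −H2O per B, Z or A cleavage, +2H when an intact reduced root is
retained. This makes B_i/Y_(n−i) and C_i/Z_(n−i) pairs sum exactly to the
intact neutral mass. Cross-ring (A/X) cleavages split a residue's ring at a
bond pair into two arcs whose elemental formulas sum exactly to the residue
formula (atom-partition convention, no hydrogen transfer); the supported pairs
are 0,2 / 2,4 / 0,3 / 1,5 for hexoses and HexNAc, 0,2 for sialic acids, with
the arc formulas and their glycosylation positions tabulated in
`masses.RING_ARCS`. A ring cut is only generated when every retained child of
the residue attaches to the retained arc and every lost child to the lost arc
("physically possible given the linkage positions"); children at unknown
positions block ring cuts; no ring cut is generated at a reduced (open-chain)
reducing end. These arc masses are a documented bookkeeping convention, not a
gas-phase mechanism model.

Naming follows Domon–Costello: B/C/A indices count residues from the
non-reducing terminus of the cleaved branch (the height of the subtree below
the cleavage), Y/Z/X indices count from the reducing end (the depth of the
residue bearing the loss), branch designators α, β, … rank branches by
decreasing subtree mass at each branch point, ring bonds are rendered as
superscript prefixes ("0,2A2"), multiple cleavages join with "/" and the
intact species is "M". Names parse back to their cleavage records, which the
suite verifies for every enumerated fragment of three test glycans.

Annotation matches peaks to theoretical fragments within a tolerance and ranks
ambiguous assignments by tiers: fewer cleavages, glycosidic before cross-ring,
fewer global modifications (−H2O, −2H2O always; −CO2 for sialylated
fragments), more corroboration (other peaks carrying the complementary ion or
same-series sub/super-fragments), smaller mass error, name. The tier weights
are a documented stand-in for likelihood priors we cannot derive from first
principles. Fragments with numerically identical m/z (e.g. Z and Y−H2O of the
same subgraph — literally the same molecule under this bookkeeping) are
treated as the same ion species when the simulator's self-consistency is
scored.

## Spectrum processing

MS2 spectra are read from mzML (a minimal namespace-aware lxml reader covering
the msconvert subset: ms level, scan start time with minute/second units,
selected ion m/z and intensity, base64/zlib 32- or 64-bit arrays), mzXML (via
pyteomics), or a plain TSV peak-list dialect (`scan_id, precursor_mz, rt_min,
mz, intensity[, precursor_intensity]`) used for fixtures. Per spectrum the
1,000 highest-intensity peaks are kept and spectra eluting before 2 min are
dropped as noise. Intensities are normalized by total ion intensity;
retention times are divided by max(max RT, 30 min), missing values mapping to
zero.

Binning: 2,048 equal half-open windows over [39.714, 3000) — nominal width
1.45 Da — with intensities summed per window and one m/z remainder per window
(offset of the window's highest peak from the left edge), which lets the model
recover exact peak locations despite the coarse binning. Isomer-group
averaging operates on the binned grid (deterministic and order-independent):
the averaged spectrum is the bin-wise mean, the representative "median"
spectrum the bin-wise median, peak positions are rebuilt as left edge + mean
remainder, the precursor m/z is the member median and precursor intensities
are summed for abundance estimation.

## Classifier

The network consumes the two-channel binned signal (normalized intensities ×
a fixed input gain of 100, and remainders in bin-width units), precursor m/z
(scaled by 3000) and normalized retention time, plus five embedded categorical
codes (glycan class, ion mode, trap, LC type, derivatization). Architecture:
initial convolution + leaky ReLU; six residual dilated convolutions (dilations
1, 2, 4, 8, 16, 32); max pooling (kernel 20); linear projection to a
1,024-dimensional trunk; scalars via linear → layer norm → leaky ReLU to 24
dimensions each; 24-dimensional categorical embeddings; concatenation; two
fully connected blocks (linear, layer norm, leaky ReLU, dropout 0.2); final
linear to one score per library glycan.

The implementation is pure NumPy with hand-written backward passes
(channels-last convolutions via strided im2col), gradient-checked against
finite differences in the test suite. Two numerical choices matter and are
deliberate:

- the trunk projection is layer-normalized before concatenation so that the
  spectral features and the 24-dimensional scalar branches enter the head at
  comparable scale — otherwise the retention-time input is numerically drowned
  out at initialization and isomers that differ only in elution learn slowly;
- scalar-branch biases are initialized to −w·u with u ~ U(0,1), placing each
  feature's sign change inside the unit interval the inputs live in; with zero
  biases the layer normalization of w·x collapses the branch to sign(x).

Convolution channel count (8) and kernel size (9) are free architecture
parameters chosen for CPU-scale training and exposed in `ModelConfig`; no
particular total parameter count is targeted.

Losses: PolyLoss (cross-entropy with label smoothing 0.1 plus ε·(1 − Σ q·p),
ε = 1, smoothing applied to the targets first) plus two distance terms — the
expected structure distance and expected composition distance to the target
under the predicted distribution, each averaged over the batch. With all-zero
distances the total reduces exactly to PolyLoss. The distance terms penalize
confident but structurally remote predictions, so residual errors concentrate
on near neighbors.

Training: AdamW (weight decay 2e-5), learning rate reduced to a fifth after 4
epochs without test-loss improvement, early stopping after 12 stale epochs
with best-weights restore, batch 256, up to 200 epochs — these corpus-scale
defaults are kept in `TrainConfig`. Sharpness-aware minimization is exposed as
a flag but off by default and not implemented at desk scale. Augmentation
(training-time and test-time): low-intensity peak removal, intensity jitter,
new-peak addition on the binned grid, precursor acetate/sodium adduct shifts,
precursor jitter ±0.5 Da and retention-time jitter ±10%. Inference calibrates
logits by dividing by a Platt factor of 1.15 before the softmax (monotone, so
the single-pass arg-max is unchanged) and averages probabilities over five
augmented inferences.

## Inference pipeline

Raw file → MS2 extraction → precursor grouping (new group at sorted-precursor
discontinuities strictly greater than 0.5 Da) → retention chunks of 0.5 min
(floor rule) → per-entity averaged + median spectra → top-25 calibrated
predictions → domain filters: score below 0.01; wrong glycan class unless the
score exceeds 0.2 (O-glycan preparations frequently carry remnant N-glycans);
precursor mass mismatch at every charge up to the configured maximum;
missing diagnostic ions (a shipped CSV table maps residue classes to required
fragment m/z — Neu5Ac 290.09, Neu5Gc 306.08, Fuc 145.05, Kdn 249.06, sulfate
96.96; all [M−H]−) → deduplication of windows with identical ordered
predictions within one gap width → biosynthetic rescoring: processing rows
from the largest glycan (neutral mass, ties by node count), each candidate
gains +0.1 per unique lower-mass top-1 prediction that embeds into it
(wildcard linkages allowed), candidates are re-sorted, renormalized to sum 1
and cut to the top 5 (renormalize-then-cut; the alternative order would leave
sub-unit sums). The glycan class of a candidate is called from its reducing
end (GalNAc → O, GlcNAc → N, otherwise free oligosaccharide).

Zero-shot extension for spectra left without candidates: (a) biosynthetic
intermediates implied by the strong top-1 predictions whose mass matches
within 0.5 Da at any charge (evidence "medium"); (b) single Neu5Ac↔Neu5Gc
swaps (±15.995 Da) and, for O-glycans, GlcNAc↔GlcNAc6S swaps on residues
attached to the reducing-end GalNAc, gated by the corresponding diagnostic
ions (evidence "weak"); (c) reference-library mass matches (evidence "weak").
Additions re-pass the domain filters, and rescoring bonuses then count
strong-evidence rows only. Relative abundances are summed precursor
intensities per row, normalized over the sample; missing when no precursor
intensities are available.

The predictor is an interface: the neural model (with calibration and TTA)
and a training-free cosine baseline — cosine similarity between the binned
spectrum and deterministic noiseless theoretical spectra of each library
glycan — both implement it, so the pipeline is testable without training.

## Synthetic data

The generator emulates the study conditions end to end. Libraries grow from
class cores (reduced GalNAc for O-glycans; Manβ1-4GlcNAcβ1-4GlcNAc for
N-glycans; glucose for free oligosaccharides) by random biosynthetically
plausible single-residue additions from a curated rule table, never attaching
two children at one position, up to 8 residues, deduplicated canonically and
deterministic per seed.

Spectra: peaks are the theoretical fragment m/z values of the generating
glycan (default: charges 1, up to 2 cleavages, glycosidic only), each kept
with probability 0.8, jittered by N(0, 0.02 Da), with intensities
exp(−1.2 × events)·U(0.5, 1) where events = cleavages + 0.5 per global
modification, plus 15 uniform decoy peaks at 20% relative intensity.
Precursor m/z is the exact [M−H]− of the glycan; retention times are Gaussian
per glycan (σ = 0.05 min) around means drawn uniformly over 3–25 min;
precursor intensities are log-uniform-ish draws standing in for MS1. Training
corpora group spectra into pseudo-samples (one simulated run per replicate
index, sharing each glycan's retention mean) and the train/test split assigns
whole pseudo-samples, so no sample spans the split.

What the simulator does not emulate: learned or mechanistic fragment
intensities (linkage isomers therefore produce identical fragment m/z sets
and are separable only by retention time — which mirrors the real role of LC
but makes the simulated isomer problem purely chromatographic), isotope
envelopes, profile peak shapes, charge-state envelopes, co-isolation chimeras
and retention drift between samples. Passing tests therefore demonstrate the
correctness of the machinery and the learnability of the mapping under these
conditions, not instrument-level performance on real data.

## Desk-scale benchmark conditions

The toy learnability experiment trains the full architecture on 20 O-glycan
classes × 50 simulated spectra (default noise model, 80/20 sample-level
split). Because the corpus-scale optimizer defaults (learning rate 1e-4,
batch 256) give only four optimizer steps per epoch at a thousand spectra, the
toy runs use learning rate 2e-3, batch 64, up to 30 epochs (patience 10,
early stop 25), chosen once for this problem size; augmentation stays on, as
in full-scale training. The paired comparison trains the same split and seeds
with and without the distance losses and compares held-out accuracy and the
mean structural distance of the errors; if both models were error-free the
distance comparison would be vacuous (equality at zero). Note that at this
scale the residual errors are retention-time confusions between linkage
isomers with identical simulated fragment masses — classes that are already
each other's structurally nearest neighbours — so the error-distance benefit
of the distance losses is expected to saturate in a way it does not in a
large, structurally diverse class space. `scripts/acceptance.py` recomputes all
benchmark quantities from scratch at a caller-supplied seed; the annotation
self-consistency check runs 20 glycans at tolerance 0.01 Da with noiseless
simulator settings.

## Known limitations

- Cross-ring masses are bookkeeping, adequate for enumeration/annotation
  consistency but not for quantitative comparison with measured A/X ions.
- The prioritization tiers approximate, not reproduce, expert likelihoods.
- Permethylation site counts ignore topology (linkage-dependent site loss).
- The class call from the reducing end is a heuristic; it cannot distinguish,
  e.g., free oligosaccharides from glycosphingolipid-derived ones.
- Batch alignment across samples, database-backed candidate search and
  taxonomy filtering are out of scope.
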