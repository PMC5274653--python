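# Methods

This note records the models, rules and numerical choices behind `templex`,
including the decisions taken where more than one reasonable design exists.

## Data model

A PDBx/mmCIF entry is reduced to *unit molecules*: one per non-water
`label_asym_id` of the asymmetric unit. Waters (HOH/DOD/WAT) are dropped at
parse time, which also means water-mediated interfaces are invisible by
construction. Polymer sequences use the entity's canonical one-letter code
when `_entity_poly` provides it; otherwise they are rebuilt from the atoms
over `label_seq_id`, with unmodelled positions written as `X` so numbering
is never disturbed. Non-standard residues map to their parent one-letter
code through a fixed table (MSE→M, SEP→S, …), else `X`, keeping sequences
alignable. Only the first model of multi-model (NMR) entries is ingested —
a single-conformer database is the simplest consistent choice — and for
alternate locations the highest-occupancy atom wins.

Molecule types drive the seven interaction classes. Polymers are typed by
their entity (`polypeptide` → protein, nucleotide entities → nucleotide).
A single-atom component whose element is in the configurable monatomic
ion set is a *metal*; a single-component molecule whose code is on the
precipitant list is a *precipitant*; other single-component molecules are
*compounds*; multi-residue non-polymers (peptide ligands, glycans) are
*other*. The precipitant class has no canonical membership in the
literature, so the shipped list (GOL, EDO, SO4, ACT, …) covers common
crystallization additives and can be replaced by a one-code-per-line file.

## Biological units and contacts

Every declared assembly candidate is kept — there is no reliable criterion
for selecting a single "correct" biological unit. Operator expressions are
expanded with comma lists, numeric ranges and juxtaposed groups; a
composite label `i-j` denotes operator *i* applied **after** operator *j*
(matrix product Rᵢ·Rⱼ, translation Rᵢ·tⱼ + tᵢ), following the PDBx
convention for juxtaposed generator groups. Non-numeric operator ids
("PAU", "XAU") are opaque. Entries with no assembly category get a
synthesized identity assembly over all molecules so downstream stages
always have a biological unit.

Two assembly molecules contact when any heavy-atom pair is within the
cutoff (default 4.0 Å, inclusive). The implementation uses a scipy KD-tree
but is contractually identical to the all-pairs scan (tested against an
independent O(n²) oracle). Both sides' interface residue lists are stored
in one symmetric record; a pair recurring in several assembly candidates
is stored once with the accumulated assembly-id list. Single-residue
components are reported as residue 1, consistent with the PDB files written
for them.

## Sequence search and clustering

The homolog search contract is blastp's: local alignments ranked by
E-value, threshold E < 10⁻⁴, with an optional overall-identity filter. Two
backends satisfy it. The `blastp` backend shells out to NCBI BLAST+. The
`internal` backend uses Biopython's PairwiseAligner (Smith–Waterman,
BLOSUM62, gap open −11 / extend −1) and converts raw scores to E-values
with the Karlin–Altschul gapped BLOSUM62 constants (λ = 0.267, K = 0.041)
over search space m×N. The two agree on hit sets at fixture scale; exact
E-values differ in ways irrelevant to thresholding at 10⁻⁴. Identity is
computed over gapless aligned pairs; coverage as aligned positions over
sequence length.

`cluster95` links two sequences when identity ≥ 95 % and the aligned region
covers ≥ 80 % of the **shorter** sequence (the literature does not specify
which length; measuring on the shorter one makes near-identical fragments
cluster with their parents, which is what redundancy reduction wants, and
the choice is configurable). Connected components under single linkage are
the clusters; the label is the lexicographically smallest member id, making
the partition order-invariant.

The *contact-site identity* of an alignment against a template interface is
the percentage of aligned template contact positions with an identical
query residue. Contact positions falling outside the aligned region leave
the denominator; if none is aligned the value is undefined (reported as
such, never as 0), and an empty interface is an error.

## Prediction services and redundancy reduction

A protein query yields one prediction record per (homolog alignment,
contact partner). Template interface residues are mapped through the
alignment onto query coordinates; records whose interface lies entirely
outside the alignment are kept but flagged, so a "full" listing remains
faithful. Binding-site Tanimoto comparisons are made on query-mapped
positions — the only coordinate system in which sites from different
templates are commensurable.

Redundancy rules: within one interaction class, records are single-linkage
clustered when (1) the contact-molecule type key is identical — cluster95
label for proteins, component code for compounds/metals/precipitants,
sequence for nucleotides, description text otherwise — and (2) the
binding-site Tanimoto is strictly greater than 0.2. The representative is
the lowest-E-value record; ties break toward higher contact-site identity,
then lexicographic template id (the representative choice is not specified
in the literature; this one is deterministic and quality-directed).
Monomer templates are kept greedily in E-value order when they align
strictly more than 10 query positions not covered by previously kept
templates.

For two-protein queries, a template is a contacting protein pair in some
assembly with one side homologous to each query. Homo mode uses one
homolog list on both sides and includes same-molecule pairs under different
operators (crystallographic homodimers); hetero mode requires the two
template chains to be in different cluster95 clusters and tries both
assignments of queries to chains.

## Chemical similarity

The descriptor is the multiset of (atom class, atom class, topological
distance) triples over all heavy-atom pairs, with atom class = (element,
heavy-neighbor count, aromatic flag) and distances capped at 10 bonds;
similarity is the multiset Tanimoto Σmin/Σmax. Atom-pair dialects differ
between programs, so the dialect string is exposed as
`chem.DESCRIPTOR_DIALECT` and printed alongside similarity values. The 0.7
search threshold reflects the empirical rule that >0.7 2D similarity
predicts a template-placed conformation within ~2 Å; lower-similarity
templates trigger a warning rather than a refusal.

The maximum common substructure is found by a connected build-up search:
mappings grow by element-consistent atom pairs adjacent (in both graphs) to
the mapped core, with sibling-branch exclusion so each mapping is
enumerated once, a simple min-remaining upper bound for pruning, and a node
budget (default 5·10⁵) after which the best-so-far correspondence is
returned flagged approximate. Bond orders are deliberately not compared —
aromatic/single assignment is unreliable across SDF/MOL2/PDB sources — and
ties between equal-size solutions resolve to the lexicographically smallest
pair list for determinism. The search is exact at desk scale (verified
against an independent exhaustive oracle up to 12 atoms).

## Modeling

*Sequence-replaced models* rewrite residue names and numbers of aligned
template residues to the query and move nothing: substituted side chains
are knowingly wrong and query insertions have no atoms. Unaligned template
residues are kept and flagged. *Template-based docking* fits each query
monomer on the Cα atoms of aligned residues (an all-atom option exists; the
choice of fitting atoms is not dictated by the approach) using a Kabsch
SVD superposition — proper rotation enforced via the determinant sign —
then counts inter-chain heavy-atom pairs closer than 2.0 Å as clashes,
reported but never repaired, since conformational change on association is
outside the model. Fits require ≥ 3 non-collinear points (rank check at
1e-8); fewer is an error, not a silent degenerate fit. *Compound
placement* is rigid superposition over the MCS correspondence (≥ 3 matched
atoms); flexible dihedral refinement is out of scope. Model PDB files
carry a remark block with the template id and the `contact/all` identity
pair. MODELLER input (PIR alignment with `/` chain breaks plus a driver
script) is emitted as text and never executed.

## Synthetic data

The fixture generator emulates the features of real entries that this
pipeline actually consumes: multiple polymer chains, het compounds and
metals at controlled distances from controlled residues, unmodelled
residues, waters, multiple symmetry operators (rotations + translations),
composite operator expressions and multiple assembly candidates. Chains
are idealized five-atom residues (N, CA, C, O, CB within 1.4 Å of centers
4.8 Å apart) along a helically twisted axis — the twist guarantees Cα sets
are never collinear, so rigid fitting is well-posed. It does **not**
emulate real stereochemistry, side-chain diversity, crystallographic
headers, or sequence composition biases; passing closure tests therefore
demonstrates the correctness of bookkeeping, geometry and rule logic, not
performance on real structures (real-entry counts are exercised by a
separate network-dependent check). Ground truth is computed inside the
generator by plain all-pairs distance scans and sequential application of
its own operator matrices, independent of the package's KD-tree and matrix
composition paths. Generation is deterministic: one spec, one byte stream.

Homolog-pair fixtures place exactly ⌊L·(100−t)/100⌉ substitutions, so
identity targets are exact to one substitution.

## Problem sizes and defaults

Tests and the acceptance script run on 20 generated entries (chains of
~8–20 residues, 1–3 molecules per entry, up to 3 operators and 2
assemblies), 50 random contact instances, 100 random superposition
instances and 30 random MCS pairs of ≤ 12 atoms — sizes chosen so the
whole battery completes in seconds while every rule and boundary (95 %/80 %
clustering, Tanimoto 0.2 and 0.7, 10-residue monomer rule, 4 Å cutoff) is
exercised on both sides. All thresholds live in `RunConfig` with the
defaults above and are CLI-overridable; the effective configuration is
logged with every run.

## Known limitations

- The internal aligner's E-values use fixed Karlin–Altschul constants, not
  composition-adjusted statistics; borderline hits near the 10⁻⁴ threshold
  may differ from blastp.
- Bond perception for component SDF export and compound graphs from
  coordinates relies on RDKit's connectivity perception; exotic
  coordination chemistry may be mis-bonded (a warning is emitted when
  perception fails).
- Contacts are residue-level only; no H-bond/hydrophobic typing, no
  interface areas.
- Classical-PDB output truncates multi-character asym_ids to one chain
  character and refuses molecules beyond 99 999 atoms.
- Exit codes: 0 ok, 1 user error, 2 internal error; argument-parse errors
  exit 2 via the CLI framework's own convention.
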