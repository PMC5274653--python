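# templex

Search and model 3D structures of molecular complexes — protein–protein,
protein–compound, protein–metal and protein–nucleotide — from a local,
self-built contact database, in the spirit of template-based complex
modeling servers.

Most proteins act by binding something: another protein, a small compound, a
metal ion, a nucleic acid. Experimental complex structures cover only a
fraction of the known interactions, but if a *homolog* of your protein has
been solved in complex with some molecule, that template predicts both the
binding partner and the binding site. `templex` is a library plus CLI for
structural bioinformaticians who want that inference pipeline offline and
scriptable: build the database from PDBx/mmCIF files, query it with
sequences and compounds, and generate template-based 3D models.

## What it computes

**Database.** Each mmCIF entry is decomposed into *unit molecules* (one per
non-water `label_asym_id`). Every declared biological-unit candidate is
expanded by its symmetry operators — including composite operator
expressions such as `(1-2)(61-62)` — into *assembly molecules*, and two
assembly molecules are recorded as contacting when any heavy-atom pair lies
within 4 Å. Four relational tables (`unitmol`, `asmblmol`, `assembly`,
`contact`) hold the result in one SQLite file. Residue numbering is
`label_seq_id` everywhere, so PDB, FASTA and table coordinates always agree.

**Protein query.** Homologs are local alignments with E-value < 10⁻⁴
(blastp, or a built-in Smith–Waterman with BLOSUM62 and Karlin–Altschul
E-values). Everything touching a homolog is a predicted contact molecule of
the query, classified into seven interaction classes (hetero/homo oligomer,
nucleotide, other polymer, compound, metal, precipitant), where "same
protein" means joint membership in a *cluster95* single-linkage cluster
(identity ≥ 95 %, aligned coverage ≥ 80 %). Redundant predictions are
merged when their contact-molecule type key matches and the binding-site
Tanimoto coefficient |A∩B|/|A∪B| exceeds 0.2. Each prediction carries two
quality numbers, printed as `contact/all` (e.g. `79.4/68.6`): the sequence
identity over the aligned template *interface* residues and over all
aligned residues — the former is the better predictor of model quality.

**Compound query.** Compounds are compared as heavy-atom graphs by an
atom-pair descriptor (element, heavy-degree, aromaticity, topological
distance ≤ 10) with multiset Tanimoto similarity (default threshold 0.7),
and by a maximum-common-substructure search whose atom correspondences
anchor rigid placement of a query compound onto a template ligand.

**Models.** Three flavors: *sequence-replaced* models (template coordinates,
query residue names/numbers — instant, residue-level), *template-based
docked* models (query monomers rigidly fitted by least-squares/Kabsch on
aligned Cα atoms; inter-chain clashes counted, never repaired), and rigid
compound placements. A MODELLER script plus PIR alignment is emitted as
text for full-atom modeling.

## Worked example

Generate six synthetic entries (known ground truth), build the database,
and query it with the sequence of one fixture chain:

```sh
templex make-fixtures --out demo/cif --n 6 --seed 3
templex build-db --mmcif-dir demo/cif --out demo/contacts.sqlite
# -> 9x02: unitmols=3 assemblies=1 asmblmols=3 contacts=3  (one line per entry)

templex contacts-for-protein --mmcif-dir demo/cif \
    --query WFAFMWEWWQKH --out demo/pred --backend internal
# -> 2 predictions, 2 representative complexes -> demo/pred
```

`demo/pred/summary_bars.tsv` then contains:

```text
interaction_class  type    template  homolog_mol  contact_mol  evalue    identity_contact/identity_all  aligned_query_range  contact_sites_on_query  cluster_size
hetero_oligomer    9x02_B  9x02      A_1          B_1          2.86e-09  100.0/100.0                    1-12                 1,2,...,12              1
metal              ZN      9x02      A_1          C_1          2.86e-09  100.0/100.0                    1-12                 4                       1
```

The query matched chain A of entry 9x02 at 100 % identity; that chain
touches a second protein (class `hetero_oligomer`, type key = the partner's
cluster95 label `9x02_B`) across its whole length, and a zinc ion (class
`metal`, type key `ZN`) through residue 4 — so position 4 of the *query* is
predicted to be a metal site. `site_table.tsv` shows the same information
one-site-per-row (position 4 lists `9x02_B:1;ZN:1`), which is the view to
use when annotating point mutations.

Modeling a homo-multimer from a query sequence:

```sh
templex model-homo --mmcif-dir demo/cif --query <SEQ> --out demo/homo
# -> 1 templates; model from 9x01 -> demo/homo
```

writes `templates.tsv` (template `9x01`, chains `A_1`/`A_2`, identities
`100.0/100.0`), the sequence-replaced model `model_seqrep.pdb` whose remark
block records template and identities, the PIR alignment and a MODELLER
driver script. With `--structure monomer.pdb` it also writes a docked model
with per-chain fit RMSD and the inter-chain clash count.

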