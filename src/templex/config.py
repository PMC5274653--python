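"""Run-wide configuration and small chemical vocabularies.

Every numeric threshold used by the search and modeling services lives in
:class:`RunConfig` so that nothing is hard-coded in the pipeline: the contact
cutoff, homolog E-value ceiling, sequence-identity filter, redundancy
thresholds and the compound-similarity cutoff are all user-overridable from
the CLI and are logged with every run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

# Three-letter -> one-letter codes for the 20 standard amino acids plus a few
# frequent modified residues mapped to their parent (BLAST-compatible output).
STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues -> parent
    "MSE": "M", "SEC": "C", "CSO": "C", "CME": "C", "OCS": "C",
    "SEP": "S", "TPO": "T", "PTR": "Y", "MLY": "K", "KCX": "K",
    "HYP": "P", "PCA": "Q", "FME": "M",
}

AA_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

NUCLEOTIDE_COMPS = {
    "A": "A", "C": "C", "G": "G", "U": "U", "I": "I", "N": "N",
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U", "DI": "I", "DN": "N",
}

WATER_COMPS = {"HOH", "DOD", "WAT", "H2O"}

# Monatomic cation/anion elements treated as the "metal" interaction class
# when they occur as single-atom components.
METAL_ELEMENTS = {
    "LI", "NA", "K", "RB", "CS", "BE", "MG", "CA", "SR", "BA",
    "MN", "FE", "CO", "NI", "CU", "ZN", "CD", "HG", "AL", "GA",
    "IN", "TL", "PB", "AG", "AU", "PT", "PD", "IR", "OS", "RU",
    "RH", "W", "MO", "V", "CR", "TI", "Y", "LA", "CE", "SM",
    "EU", "GD", "TB", "YB", "LU", "U", "TH",
    "F", "CL", "BR", "I",  # monatomic halide anions
}

# Default precipitant/cryoprotectant component codes.  The interaction class
# exists in the literature but has no canonical membership list, so this set
# covers the usual crystallization additives and is user-editable via
# RunConfig.precipitant_path (one code per line, '#' comments).
DEFAULT_PRECIPITANTS = frozenset({
    "GOL", "EDO", "PEG", "PG4", "PGE", "1PE", "P6G", "2PE", "MPD",
    "SO4", "PO4", "ACT", "CIT", "FLC", "TRS", "EPE", "MES", "BME",
    "DTT", "DMS", "NO3", "FMT", "ACY", "IMD", "TAR", "MLI", "PGO",
    "BTB", "CAC", "MRD", "SCN", "AZI", "BCT", "CO3", "NH4", "UNX",
})


def load_precipitants(path: Optional[str | Path]) -> frozenset[str]:
    """Read a precipitant code list (one 3-letter code per line).

    ``None`` returns the shipped default set.
    """
    if path is None:
        return DEFAULT_PRECIPITANTS
    codes = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip().upper()
        if line:
            codes.add(line)
    return frozenset(codes)


@dataclasses.dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with literature defaults.

    contact_cutoff
        Heavy-atom distance (Å) below which two assembly molecules contact.
    evalue_max
        Homologs are alignments with E-value strictly below this.
    min_identity_pct
        Optional extra filter on overall alignment identity (0 disables).
    cluster_identity_min / cluster_coverage_min
        Single-linkage thresholds (%, %) defining the cluster95 "same
        protein" relation.
    site_tanimoto_min
        Binding-site Tanimoto threshold (exclusive) linking redundant
        predicted complexes.
    compound_tanimoto_min
        Chemical atom-pair-descriptor Tanimoto threshold for "similar
        compound" hits.
    monomer_new_residues_min
        A monomer template is kept only if it aligns strictly more than this
        many query residues not covered by previously kept templates.
    """

    contact_cutoff: float = 4.0
    evalue_max: float = 1e-4
    min_identity_pct: float = 0.0
    cluster_identity_min: float = 95.0
    cluster_coverage_min: float = 80.0
    site_tanimoto_min: float = 0.2
    compound_tanimoto_min: float = 0.7
    monomer_new_residues_min: int = 10
    precipitant_path: Optional[str] = None
    search_backend: str = "auto"  # auto | internal | blastp
    seed: int = 0

    def precipitants(self) -> frozenset[str]:
        return load_precipitants(self.precipitant_path)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
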