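"""Shared builder for hand-made prediction records used in rule tests."""

from templex.mmcif_model import UnitMol
from templex.predict import PredictionRecord
from templex.seqsearch import Alignment


def make_record(type_key, sites, evalue=1e-10, ident_contact=50.0,
                cls="compound", template=("1abc", "A")):
    n = 30
    aln = Alignment("q", template, [(i, i) for i in range(1, n + 1)], 80.0,
                    evalue, 90.0, 100.0, 100.0, "A" * n, "A" * n,
                    identity_contact=ident_contact)
    meta = UnitMol("1abc", "Z", "compound", type_key, None, "", [])
    return PredictionRecord("q", ("1abc", "1"), ("A", "1"), ("Z", "1"), meta,
                            aln, cls, sorted(sites), type_key)
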