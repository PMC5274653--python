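"""Independent oracles and record builders used by the acceptance script."""

import numpy as np

from templex.mmcif_model import UnitMol
from templex.predict import PredictionRecord
from templex.seqsearch import Alignment


def quaternion_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Optimal superposition rmsd via Horn's quaternion eigenvalue method."""
    m = moving - moving.mean(axis=0)
    f = fixed - fixed.mean(axis=0)
    r = m.T @ f
    k = np.array([
        [r[0, 0] + r[1, 1] + r[2, 2], r[1, 2] - r[2, 1], r[2, 0] - r[0, 2], r[0, 1] - r[1, 0]],
        [r[1, 2] - r[2, 1], r[0, 0] - r[1, 1] - r[2, 2], r[0, 1] + r[1, 0], r[2, 0] + r[0, 2]],
        [r[2, 0] - r[0, 2], r[0, 1] + r[1, 0], r[1, 1] - r[0, 0] - r[2, 2], r[1, 2] + r[2, 1]],
        [r[0, 1] - r[1, 0], r[2, 0] + r[0, 2], r[1, 2] + r[2, 1], r[2, 2] - r[0, 0] - r[1, 1]],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    return float(np.sqrt(max(((m ** 2).sum() + (f ** 2).sum() - 2 * lam) / len(m), 0.0)))


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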