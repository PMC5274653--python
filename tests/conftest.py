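import pytest

from templex import fixtures as fx
from templex.contacts import build_database
from templex.mmcif_model import parse_entry


@pytest.fixture(scope="session")
def demo_entries():
    """Twenty varied synthetic entries with their ground-truth records."""
    out = []
    for spec in fx.demo_specs(20, seed=7):
        text, truth = fx.make_entry(spec)
        out.append((parse_entry(text), truth))
    return out


@pytest.fixture(scope="session")
def demo_store(demo_entries):
    store, _ = build_database([e for e, _ in demo_entries])
    yield store
    store.close()


@pytest.fixture()
def simple_spec():
    """One 10-residue chain plus a 3-atom ligand 3.5 Å from residue 7."""
    return fx.FixtureSpec(
        pdb_id="9abc",
        chains=[fx.ChainSpec("A", 10)],
        hets=[fx.HetSpec("B", "LIG", ("C", "N", "O"), near=("A", 7, 3.5))],
        include_waters=True,
    )


@pytest.fixture()
def simple_entry(simple_spec):
    text, truth = fx.make_entry(simple_spec)
    return parse_entry(text), truth
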