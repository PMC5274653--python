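"""Expand operator expressions and build biological-unit molecules.

A biological unit is generated from the asymmetric unit by applying the
declared symmetry operators to unit molecules.  Generator rows may carry
composite operator expressions: comma lists ("1,2,3"), parenthesized ranges
("(1-60)") and juxtaposed groups ("(1-2)(61-62)") whose Cartesian product
yields composed operators with labels such as "1-61".  A label "i-j" means
operator i is applied after operator j, following the PDBx convention for
juxtaposed generator groups.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Optional

import numpy as np

from .mmcif_model import Atom, Entry, Operator, UnitMol


class OperExpressionError(ValueError):
    """Malformed or unresolvable operator expression."""


@dataclasses.dataclass
class AsmblMol:
    """A unit molecule placed into a biological unit by a symmetry operator.

    Uniquely keyed by (pdb_id, asym_id, oper_expression); the transform is
    rigid, so internal geometry equals the source unit molecule's.
    """

    pdb_id: str
    asym_id: str
    oper_expression: str
    atoms: list[Atom]
    unitmol: Optional[UnitMol] = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.pdb_id, self.asym_id, self.oper_expression)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


def compose(first: Operator, second: Operator, label: Optional[str] = None) -> Operator:
    """Operator applying ``second`` first, then ``first`` (first ∘ second)."""
    rot = first.rotation @ second.rotation
    trans = first.rotation @ second.translation + first.translation
    return Operator(label or f"{first.oper_id}-{second.oper_id}", rot, trans)


_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")


def _expand_items(items: str) -> list[str]:
    """Expand a comma list with numeric ranges into operator ids."""
    out: list[str] = []
    for item in items.split(","):
        item = item.strip()
        if not item:
            raise OperExpressionError(f"empty item in expression {items!r}")
        m = _RANGE_RE.match(item)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if hi < lo:
                raise OperExpressionError(f"descending range {item!r}")
            out.extend(str(k) for k in range(lo, hi + 1))
        else:
            out.append(item)
    return out


def _split_groups(expr: str) -> list[str]:
    """Split an expression into juxtaposed parenthesized groups."""
    expr = expr.strip()
    if not expr:
        raise OperExpressionError("empty operator expression")
    if "(" not in expr:
        return [expr]
    groups = []
    pos = 0
    while pos < len(expr):
        if expr[pos] != "(":
            raise OperExpressionError(f"malformed expression {expr!r}")
        end = expr.find(")", pos)
        if end < 0:
            raise OperExpressionError(f"unbalanced parentheses in {expr!r}")
        groups.append(expr[pos + 1:end])
        pos = end + 1
    return groups


def expand_oper_expression(
    expr: str, operators: list[Operator]
) -> list[tuple[str, Operator]]:
    """Expand an ``_pdbx_struct_assembly_gen`` operator expression.

    Returns (label, composed operator) pairs.  Juxtaposed groups produce the
    Cartesian product, left group applied last; labels join ids with '-'.
    Non-numeric oper_ids ("PAU", "XAU", …) are opaque identifiers.
    """
    by_id = {op.oper_id: op for op in operators}

    def resolve(oper_id: str) -> Operator:
        try:
            return by_id[oper_id]
        except KeyError:
            raise OperExpressionError(f"undeclared oper_id {oper_id!r}") from None

    expanded: list[tuple[str, Operator]] = []
    groups = [_expand_items(g) for g in _split_groups(expr)]
    # Cartesian product, left fold: ((g0 ∘ g1) ∘ g2) ...
    combos: list[tuple[str, Operator]] = [(i, resolve(i)) for i in groups[0]]
    for group in groups[1:]:
        combos = [
            (f"{label}-{j}", compose(op, resolve(j), label=f"{label}-{j}"))
            for label, op in combos
            for j in group
        ]
    expanded.extend(combos)
    return expanded


def apply_operator(u: UnitMol, op: Operator, label: str) -> AsmblMol:
    """Rigidly transform a unit molecule: x ↦ R·x + t; metadata unchanged."""
    atoms = [
        Atom(a.atom_name, a.element, a.comp_id, a.seq_id, op.apply(a.xyz))
        for a in u.atoms
    ]
    return AsmblMol(u.pdb_id, u.asym_id, label, atoms, unitmol=u)


def build_assembly(entry: Entry, assembly_id: str) -> list[AsmblMol]:
    """Construct every molecule of one biological-unit candidate.

    One AsmblMol per (asym_id, expanded operator) of each generator row;
    duplicate keys across rows collapse to a single molecule.
    """
    adef = entry.assembly(assembly_id)  # KeyError on unknown id
    out: dict[tuple[str, str, str], AsmblMol] = {}
    for asym_id, expr in adef.members:
        u = entry.unitmol(asym_id)
        for label, op in expand_oper_expression(expr, entry.operators):
            mol = apply_operator(u, op, label)
            out[mol.key] = mol
    return list(out.values())
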