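"""Molecular descriptor table construction.

Hair incorporation is governed chiefly by lipophilicity, basicity and
molecular mass, so the default descriptor family is restricted to those
axes: Crippen logP, topological polar surface area, molecular weight,
H-bond donor/acceptor counts, ionisable-group counts (SMARTS-based acidic
and basic groups) and a crude net-charge-at-pH-7.4 proxy (basic minus
acidic groups). An external descriptor CSV bypasses computation entirely
and is preserved bit-exactly, for parity studies against other backends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors
from rdkit.Chem import Lipinski
from rdkit.Chem.Crippen import MolLogP

from .panel import SubstanceRecord

__all__ = ["DescriptorTable", "DESCRIPTOR_FAMILY", "compute_descriptors",
           "build_descriptor_table"]

log = logging.getLogger(__name__)

DESCRIPTOR_FAMILY = (
    "crippen_logp",
    "tpsa",
    "mol_wt",
    "h_bond_donors",
    "h_bond_acceptors",
    "acidic_group_count",
    "basic_group_count",
    "net_charge_ph74_proxy",
)

# ionisable groups: carboxylic acids and N-H sulfonamides deprotonate near
# physiological pH; non-amide, non-sulfonylated, non-aromatic amines protonate
_ACIDIC_SMARTS = (
    Chem.MolFromSmarts("[CX3](=O)[OX2H1]"),            # carboxylic acid
    Chem.MolFromSmarts("[SX4](=O)(=O)[NX3;H1,H2]"),    # sulfonamide N-H
)
_BASIC_SMARTS = (
    Chem.MolFromSmarts("[NX3;H2,H1,H0;!$(NC=O);!$(NS(=O)=O);!$(Nc);!$(N=*);!n]"),
)


def compute_descriptors(smiles: str) -> dict[str, float]:
    """Descriptor values for one structure; raises ValueError if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    acidic = sum(len(mol.GetSubstructMatches(p)) for p in _ACIDIC_SMARTS)
    basic = sum(len(mol.GetSubstructMatches(p)) for p in _BASIC_SMARTS)
    return {
        "crippen_logp": float(MolLogP(mol)),
        "tpsa": float(RDDescriptors.TPSA(mol)),
        "mol_wt": float(RDDescriptors.MolWt(mol)),
        "h_bond_donors": float(Lipinski.NumHDonors(mol)),
        "h_bond_acceptors": float(Lipinski.NumHAcceptors(mol)),
        "acidic_group_count": float(acidic),
        "basic_group_count": float(basic),
        "net_charge_ph74_proxy": float(basic - acidic),
    }


@dataclass
class DescriptorTable:
    """Feature matrix with per-feature kind and provenance bookkeeping."""

    values: pd.DataFrame                       # index = substance names
    feature_kinds: dict[str, str] = field(default_factory=dict)
    provenance: str = "computed"               # "computed" or "supplied"
    excluded: tuple[str, ...] = ()             # substances with unusable structures

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if not self.feature_kinds:
            self.feature_kinds = {
                c: ("numeric" if pd.api.types.is_numeric_dtype(self.values[c])
                    else "categorical")
                for c in self.values.columns
            }
        if self.values.isna().any().any():
            raise ValueError("descriptor table contains missing cells")

    @property
    def substances(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


def build_descriptor_table(
    substances: list[SubstanceRecord] | None = None,
    descriptor_csv: str | Path | None = None,
) -> DescriptorTable:
    """Build the table from structures, or pass an external CSV through.

    With structures, substances whose SMILES cannot be parsed are excluded
    and logged rather than failing the whole table.
    """
    if (substances is None) == (descriptor_csv is None):
        raise ValueError("provide exactly one of substances or descriptor_csv")
    if descriptor_csv is not None:
        frame = pd.read_csv(descriptor_csv, index_col=0, float_precision="round_trip")
        return DescriptorTable(values=frame, provenance="supplied")
    rows, index, excluded = [], [], []
    for rec in substances:
        try:
            rows.append(compute_descriptors(rec.smiles))
            index.append(rec.name)
        except ValueError:
            log.warning("excluding %s: unusable structure", rec.name)
            excluded.append(rec.name)
    frame = pd.DataFrame(rows, index=index, columns=list(DESCRIPTOR_FAMILY))
    return DescriptorTable(values=frame, provenance="computed",
                           excluded=tuple(excluded))
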