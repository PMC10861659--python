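"""The 17-drug model panel and related domain types.

The panel covers four classes of the WADA Prohibited List: S1 anabolic
agents (S1.1 steroids, S1.2 other anabolic agents), S3 beta-2 agonists,
S4 hormone and metabolic modulators, and S5 diuretics and masking agents.
Each record carries the structure (SMILES), a computed octanol-water logP,
and hair/plasma detection labels from the rat study read-out; urine and
faeces statuses are stored as unknown unless supplied by the user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem
from rdkit.Chem.Crippen import MolLogP

__all__ = [
    "SubstanceRecord",
    "HairSegmentProfile",
    "MATRICES",
    "WADA_CLASSES",
    "REPORTED_DEGREES",
    "load_model_panel",
    "load_segment_profiles",
    "assign_vehicle",
]

#: Biological matrices handled throughout the pipeline.
MATRICES = ("plasma", "urine", "faeces", "hair")

#: Prohibited-list classes represented on the panel.
WADA_CLASSES = ("S1.1", "S1.2", "S3", "S4", "S5")

#: logP cut for vehicle choice during mixture preparation: below the cut the
#: drug dissolves in DMSO, at/above it in corn oil (the final diluent).
VEHICLE_LOGP_CUT = 3.25

#: Group-mean incorporation degrees, (pg/mg)/(ng.h/mL), for the substances
#: whose means are reported individually.
REPORTED_DEGREES = {
    "stanozolol": 0.26,
    "clenbuterol": 0.11,
    "furosemide": 0.42,
    "probenecid": 0.66,
}


@dataclass(frozen=True)
class SubstanceRecord:
    """One panel drug: identity, class, structure, and detection labels.

    ``hair_label`` is "positive"/"negative"/"unknown"; ``matrix_detected``
    maps matrix name to True/False/None (None = not stated).
    """

    name: str
    wada_class: str
    smiles: str
    logp: float
    hair_label: str
    matrix_detected: dict[str, Optional[bool]]

    def __post_init__(self) -> None:
        if self.wada_class not in WADA_CLASSES:
            raise ValueError(f"unknown WADA class {self.wada_class!r}")
        if self.hair_label not in ("positive", "negative", "unknown"):
            raise ValueError(f"bad hair_label {self.hair_label!r}")
        hair = self.matrix_detected.get("hair")
        if hair is not None and self.hair_label != "unknown":
            if hair != (self.hair_label == "positive"):
                raise ValueError(
                    f"{self.name}: hair_label inconsistent with matrix_detected"
                )

    @property
    def usable_structure(self) -> bool:
        return Chem.MolFromSmiles(self.smiles) is not None


@dataclass
class HairSegmentProfile:
    """Segmental hair analysis result for one human subject.

    Segments are contiguous 2-cm pieces ordered proximal (scalp) to distal;
    concentrations are pg/mg, with None meaning not detected (censored).
    """

    subject_id: str
    drug: str
    segments: list[tuple[float, float, Optional[float]]]
    use_duration_weeks: Optional[float] = None
    cosmetic_treatment: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        prev_end = None
        for lo, hi, conc in self.segments:
            if not lo < hi:
                raise ValueError(f"{self.subject_id}: segment {lo}-{hi} inverted")
            if prev_end is not None and lo < prev_end:
                raise ValueError(f"{self.subject_id}: overlapping segments")
            if conc is not None and conc < 0:
                raise ValueError("negative concentration")
            prev_end = hi


# name, class, SMILES, hair detected, plasma detected.
# Hair negatives: terbutaline, salbutamol, chlorothiazide (14/17 positive).
# Plasma negatives additionally: methyltestosterone, testosterone,
# hydrochlorothiazide, canrenone (10/17 positive) -- so the incorporation
# degree is calculable for exactly 10 substances.
_PANEL = [
    ("stanozolol", "S1.1",
     "C[C@]12CC[C@H]3[C@@H](CC[C@H]4CC5=C(C[C@]34C)C=NN5)[C@@H]1CC[C@@]2(C)O",
     True, True),
    ("methyltestosterone", "S1.1", "CC12CCC3C(C1CCC2(C)O)CCC4=CC(=O)CCC34C",
     True, False),
    ("testosterone", "S1.1", "CC12CCC3C(C1CCC2O)CCC4=CC(=O)CCC34C",
     True, False),
    ("clenbuterol", "S1.2", "CC(C)(C)NCC(O)c1cc(Cl)c(N)c(Cl)c1", True, True),
    ("terbutaline", "S3", "CC(C)(C)NCC(O)c1cc(O)cc(O)c1", False, False),
    ("salbutamol", "S3", "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1", False, False),
    ("tamoxifen", "S4",
     "CC/C(=C(\\c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1", True, True),
    ("clomifene", "S4",
     "CCN(CC)CCOc1ccc(cc1)C(=C(Cl)c1ccccc1)c1ccccc1", True, True),
    ("anastrozole", "S4", "CC(C)(C#N)c1cc(Cn2cncn2)cc(c1)C(C)(C)C#N",
     True, True),
    ("GW1516", "S4",
     "Cc1cc(OCC(=O)O)ccc1SCc1sc(nc1C)-c1ccc(cc1)C(F)(F)F", True, True),
    ("letrozole", "S4", "N#Cc1ccc(cc1)C(n1cncn1)c1ccc(cc1)C#N", True, True),
    ("trimetazidine", "S4", "COc1ccc(CN2CCNCC2)c(OC)c1OC", True, True),
    ("furosemide", "S5", "NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl",
     True, True),
    ("hydrochlorothiazide", "S5", "NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O",
     True, False),
    ("canrenone", "S5",
     "CC12CCC3C(C1CCC24CCC(=O)O4)C=CC5=CC(=O)CCC35C", True, False),
    ("chlorothiazide", "S5", "NS(=O)(=O)c1cc2c(cc1Cl)N=CNS2(=O)=O",
     False, False),
    ("probenecid", "S5", "CCCN(CCC)S(=O)(=O)c1ccc(cc1)C(=O)O", True, True),
]


def load_model_panel() -> list[SubstanceRecord]:
    """Return the embedded 17-drug panel with detection labels.

    14 substances are hair-positive and 10 are positive in both hair and
    plasma (the set for which an incorporation degree is calculable).
    Urine/faeces statuses ship as unknown.
    """
    records = []
    for name, klass, smiles, hair, plasma in _PANEL:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - fixture is pre-validated
            raise ValueError(f"unusable structure for {name}")
        records.append(
            SubstanceRecord(
                name=name,
                wada_class=klass,
                smiles=smiles,
                logp=float(MolLogP(mol)),
                hair_label="positive" if hair else "negative",
                matrix_detected={
                    "hair": hair,
                    "plasma": plasma,
                    "urine": None,
                    "faeces": None,
                },
            )
        )
    names = [r.name for r in records]
    assert len(set(names)) == len(names)
    return records


def assign_vehicle(logp: float) -> str:
    """Vehicle used to dissolve a drug for the gavage mixture.

    Drugs with logP below 3.25 go into DMSO, the rest into corn oil
    (corn oil being the final diluent, the boundary maps to it).
    """
    if not math.isfinite(logp):
        raise ValueError("logp must be finite")
    return "dmso" if logp < VEHICLE_LOGP_CUT else "corn_oil"


def load_segment_profiles() -> list[HairSegmentProfile]:
    """Human segmental hair profiles (diuretics / masking agents study).

    Only individually printed concentrations ship as numbers: subject F1
    (letrozole, permed and dyed hair, proximal 0-6 cm segments) and subject
    F6 (hydrochlorothiazide after 5 weeks of use). Subjects F3 and M1 had
    used their drugs for under 5 weeks and no segment was positive; their
    durations are stored as a synthetic stand-in value of 4.0 weeks since
    only "less than 5 weeks" is stated.
    """
    return [
        HairSegmentProfile(
            subject_id="F1", drug="letrozole",
            segments=[(0, 2, 1608.0), (2, 4, 950.0), (4, 6, 507.0)],
            use_duration_weeks=None,
            cosmetic_treatment=frozenset({"perm", "dye"}),
        ),
        HairSegmentProfile(
            subject_id="F3", drug="furosemide",
            segments=[(0, 2, None), (2, 4, None)],
            use_duration_weeks=4.0,
        ),
        HairSegmentProfile(
            subject_id="M1", drug="furosemide",
            segments=[(0, 2, None), (2, 4, None)],
            use_duration_weeks=4.0,
        ),
        HairSegmentProfile(
            subject_id="F6", drug="hydrochlorothiazide",
            segments=[(0, 2, 93.0)],
            use_duration_weeks=5.0,
            cosmetic_treatment=frozenset({"perm", "dye"}),
        ),
    ]
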