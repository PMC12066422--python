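"""Compound data model, ADME parameter derivations, and the built-in library.

A :class:`CompoundRecord` carries every drug-specific quantity the simulator
needs: fraction unbound in plasma (``f_up``), blood-to-plasma concentration
ratio (``bpr``), first-order gastrointestinal absorption rate constant
(``gi_ka``, 1/h), apparent clearance (``cl_app``, L/h), steady-state volume of
distribution per kg (metadata), tissue:plasma partition coefficients (``kp``)
with a global ``kp_scaler``, and the in-vitro IC50 values toward aldosterone
synthase (CYP11B2) and 11β-hydroxylase (CYP11B1) in nmol/L.

The module also implements the standard derivation formulas used to obtain
those parameters from raw measurables::

    f_up  = 1 - ppbr
    CL_app = Vss * 0.693 / half_life
    log10(Peff) = 0.6795 * log10(Papp) - 0.3355
    gi_ka = 2 * Peff / r            (small-intestinal radius r = 1.25 cm)

and the two-factor calibration transform (Kp_scaler * 0.85, CL_app / 4.7)
obtained by fitting the model drug against clinical data.

Five aldosterone-synthase-inhibitor records (Baxdrostat, BI689648,
Lorundrostat, Dexfadrostat, and the 11β-hydroxylase inhibitor LCI699 as the
non-selective control) ship as a built-in fixture library.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml
from rdkit import Chem
from rdkit.rdBase import BlockLogs

#: The 11 tissues whose partition coefficients are tabulated per compound.
KP_TISSUES: tuple[str, ...] = (
    "bone",
    "brain",
    "adipose",
    "heart",
    "kidney",
    "gut",
    "liver",
    "lung",
    "muscle",
    "skin",
    "spleen",
)

#: Default small-intestinal radius (cm): diameter 2.5 cm.
INTESTINAL_RADIUS_CM = 1.25

# Conventional (IUPAC 2007) average atomic weights for the elements common in
# drug-like molecules; anything rarer falls back to RDKit's periodic table.
_ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.00794,
    "B": 10.811,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "F": 18.9984032,
    "Si": 28.0855,
    "P": 30.973762,
    "S": 32.065,
    "Cl": 35.453,
    "Br": 79.904,
    "I": 126.90447,
}


@dataclass(frozen=True)
class CalibrationFactors:
    """Multiplicative Kp adjustment and clearance divisor.

    The defaults (0.85, 4.7) are the factors obtained by calibrating the
    model drug against observed clinical exposure; they are applied uniformly
    to every compound.
    """

    kp_factor: float = 0.85
    cl_divisor: float = 4.7

    def __post_init__(self) -> None:
        if not self.kp_factor > 0:
            raise ValueError(f"kp_factor must be > 0, got {self.kp_factor}")
        if not self.cl_divisor > 0:
            raise ValueError(f"cl_divisor must be > 0, got {self.cl_divisor}")


@dataclass(frozen=True)
class CompoundRecord:
    """All drug-specific PBPK/PD parameters for one molecule."""

    name: str
    smiles: str
    mw: float  # g/mol
    f_up: float  # fraction unbound in plasma
    bpr: float  # blood:plasma concentration ratio
    gi_ka: float  # 1/h
    cl_app: float  # L/h
    vss_per_kg: float  # L/kg (metadata; distribution volume emerges from Kp)
    kp: Mapping[str, float]  # tissue -> tissue:plasma partition coefficient
    kp_scaler: float
    ic50_cyp11b1: float  # nmol/L, 11β-hydroxylase
    ic50_cyp11b2: float  # nmol/L, aldosterone synthase
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        def _positive(fname: str, value: float) -> None:
            if not value > 0:
                raise ValueError(f"{self.name or 'record'}: {fname} must be > 0, got {value}")

        if not 0 < self.f_up <= 1:
            raise ValueError(f"{self.name}: f_up must be in (0, 1], got {self.f_up}")
        for fname in ("mw", "bpr", "gi_ka", "cl_app", "vss_per_kg", "kp_scaler",
                      "ic50_cyp11b1", "ic50_cyp11b2"):
            _positive(fname, getattr(self, fname))
        kp = dict(self.kp)
        if sorted(kp) != sorted(KP_TISSUES):
            raise ValueError(
                f"{self.name}: kp must cover exactly {sorted(KP_TISSUES)}, got {sorted(kp)}"
            )
        for tissue, value in kp.items():
            _positive(f"kp[{tissue}]", value)
        object.__setattr__(self, "kp", kp)
        object.__setattr__(self, "smiles", "".join(self.smiles.split()))

    @property
    def selectivity_index(self) -> float:
        """IC50(CYP11B1) / IC50(CYP11B2); higher = more selective for AS."""
        return self.ic50_cyp11b1 / self.ic50_cyp11b2


# ---------------------------------------------------------------------------
# parameter-derivation formulas
# ---------------------------------------------------------------------------

def fup_from_ppbr(ppbr: float) -> float:
    """Fraction unbound in plasma from the plasma protein binding ratio."""
    if not 0 <= ppbr < 1:
        raise ValueError(f"ppbr must be in [0, 1), got {ppbr}")
    return 1.0 - ppbr


def clapp_from_vss_halflife(vss: float, half_life: float) -> float:
    """Apparent clearance (L/h) from Vss (L) and elimination half-life (h)."""
    if not vss > 0:
        raise ValueError(f"vss must be > 0, got {vss}")
    if not half_life > 0:
        raise ValueError(f"half_life must be > 0, got {half_life}")
    return vss * 0.693 / half_life


def peff_from_papp(papp: float) -> float:
    """Effective intestinal permeability from apparent (Caco-2) permeability.

    Log-linear regression ``log10(Peff) = 0.6795*log10(Papp) - 0.3355``; both
    operands are in the as-published units of the source regression.
    """
    if not papp > 0:
        raise ValueError(f"papp must be > 0, got {papp}")
    return 10.0 ** (0.6795 * math.log10(papp) - 0.3355)


def gika_from_peff(peff: float, radius: float = INTESTINAL_RADIUS_CM) -> float:
    """First-order GI absorption rate constant: ``2 * Peff / radius``."""
    if not peff > 0:
        raise ValueError(f"peff must be > 0, got {peff}")
    if not radius > 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    return 2.0 * peff / radius


def mw_from_smiles(smiles: str) -> float:
    """Average molecular weight (g/mol) of a SMILES string, to 2 decimals.

    Whitespace embedded in the SMILES is ignored.  Hydrogens implicit in the
    SMILES are counted.  Masses are summed from a conventional average
    atomic-weight table (see module source); elements outside the table use
    RDKit's periodic table.
    """
    cleaned = "".join(smiles.split())
    with BlockLogs():
        mol = Chem.MolFromSmiles(cleaned)
    if mol is None:
        raise ValueError(f"could not parse SMILES {cleaned!r}")
    pt = Chem.GetPeriodicTable()
    h_mass = _ATOMIC_WEIGHTS["H"]
    total = 0.0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        total += _ATOMIC_WEIGHTS.get(sym, pt.GetAtomicWeight(sym))
        total += atom.GetTotalNumHs() * h_mass
    return round(total, 2)


def apply_calibration(
    record: CompoundRecord, factors: CalibrationFactors = CalibrationFactors()
) -> CompoundRecord:
    """Return a copy with ``kp_scaler * kp_factor`` and ``cl_app / cl_divisor``.

    All other fields are unchanged and full precision is kept internally;
    round for reporting only.
    """
    prov = dict(record.provenance)
    prov["calibration"] = f"kp_scaler*{factors.kp_factor:g}, cl_app/{factors.cl_divisor:g}"
    return dataclasses.replace(
        record,
        kp_scaler=record.kp_scaler * factors.kp_factor,
        cl_app=record.cl_app / factors.cl_divisor,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# compound-sheet round trip
# ---------------------------------------------------------------------------

def record_to_sheet(record: CompoundRecord, path: str | Path | None = None) -> dict:
    """Serialise a record to the compound-sheet mapping (optionally to YAML)."""
    sheet = {
        "name": record.name,
        "smiles": record.smiles,
        "mw": record.mw,
        "f_up": record.f_up,
        "bpr": record.bpr,
        "gi_ka": record.gi_ka,
        "cl_app": record.cl_app,
        "vss_per_kg": record.vss_per_kg,
        "kp_scaler": record.kp_scaler,
        "ic50_cyp11b1": record.ic50_cyp11b1,
        "ic50_cyp11b2": record.ic50_cyp11b2,
        "kp": dict(record.kp),
        "provenance": dict(record.provenance),
    }
    if path is not None:
        with open(path, "w") as fh:
            yaml.safe_dump(sheet, fh, sort_keys=False)
    return sheet


def record_from_sheet(source: str | Path | Mapping) -> CompoundRecord:
    """Read a compound sheet (YAML file or mapping) back into a record."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            sheet = yaml.safe_load(fh)
    else:
        sheet = dict(source)
    try:
        return CompoundRecord(
            name=sheet["name"],
            smiles=sheet["smiles"],
            mw=float(sheet["mw"]),
            f_up=float(sheet["f_up"]),
            bpr=float(sheet["bpr"]),
            gi_ka=float(sheet["gi_ka"]),
            cl_app=float(sheet["cl_app"]),
            vss_per_kg=float(sheet["vss_per_kg"]),
            kp={t: float(v) for t, v in sheet["kp"].items()},
            kp_scaler=float(sheet["kp_scaler"]),
            ic50_cyp11b1=float(sheet["ic50_cyp11b1"]),
            ic50_cyp11b2=float(sheet["ic50_cyp11b2"]),
            provenance=dict(sheet.get("provenance", {})),
        )
    except KeyError as exc:
        raise ValueError(f"compound sheet missing required field: {exc}") from exc


# ---------------------------------------------------------------------------
# built-in five-compound library
# ---------------------------------------------------------------------------

# Published parameter sheets for the five compounds.  SMILES are kept exactly
# as published (embedded spaces included; normalised on record construction).
_LIBRARY_DATA: tuple[dict, ...] = (
    dict(
        name="Baxdrostat",
        smiles="CCC(=O)NC1CCCC2 = C1C = NC = C2C3 = CC4 = C(C=C3)N(C(=O)CC4)C",
        mw=363.50, f_up=0.26, bpr=0.96, gi_ka=0.96, cl_app=14.83, vss_per_kg=1.37,
        kp=dict(bone=2.55, brain=45.07, adipose=18.05, heart=7.31, kidney=7.12,
                gut=9.81, liver=4.75, lung=9.41, muscle=8.02, skin=37.69, spleen=5.39),
        kp_scaler=0.16, ic50_cyp11b1=1310.0, ic50_cyp11b2=13.0,
        provenance=dict(f_up="literature", ic50="human clinical data",
                        other_adme="ML-predicted"),
    ),
    dict(
        name="BI689648",
        smiles="COCC1 = CC(=CN = C1)C2 = CC3 = C(N=C2)N(CCC3)C (=O)N",
        mw=298.36, f_up=0.18, bpr=1.04, gi_ka=0.73, cl_app=14.32, vss_per_kg=1.29,
        kp=dict(bone=0.24, brain=0.22, adipose=1.29, heart=0.37, kidney=0.28,
                gut=0.30, liver=0.23, lung=0.26, muscle=0.13, skin=0.39, spleen=0.19),
        kp_scaler=3.75, ic50_cyp11b1=310.0, ic50_cyp11b2=2.1,
        provenance=dict(ic50="monkey adrenal homogenate", other_adme="ML-predicted"),
    ),
    dict(
        name="Lorundrostat",
        smiles=("CC1 = CC = C(C=C1)C2 = CN = NC(=N2)N3CCN(CC3)CC(=O)"
                "NC4CCC(CC4)NC(=O)C"),
        mw=451.6, f_up=0.11, bpr=0.66, gi_ka=0.36, cl_app=39.36, vss_per_kg=1.54,
        kp=dict(bone=0.33, brain=0.29, adipose=2.20, heart=0.46, kidney=0.30,
                gut=0.36, liver=0.26, lung=0.30, muscle=0.19, skin=0.46, spleen=0.22),
        kp_scaler=3.33, ic50_cyp11b1=475.0, ic50_cyp11b2=1.27,
        provenance=dict(ic50="monkey adrenal homogenate", other_adme="ML-predicted"),
    ),
    dict(
        name="Dexfadrostat",
        smiles="C1CC(N2C = NC = C2C1)C3 = CC = C(C=C3)C#N",
        mw=223.27, f_up=0.18, bpr=0.74, gi_ka=0.86, cl_app=71.11, vss_per_kg=1.67,
        kp=dict(bone=1.21, brain=1.03, adipose=11.88, heart=1.55, kidney=0.81,
                gut=0.98, liver=0.76, lung=0.31, muscle=0.34, skin=1.05, spleen=0.41),
        kp_scaler=0.91, ic50_cyp11b1=94.0, ic50_cyp11b2=2.5,
        provenance=dict(ic50="monkey adrenal homogenate", other_adme="ML-predicted"),
    ),
    dict(
        name="LCI699",
        smiles="C1CC2 = CN = CN2C1C3 = C(C=C(C=C3)C#N)F",
        mw=227.24, f_up=0.20, bpr=0.77, gi_ka=1.63, cl_app=95.05, vss_per_kg=1.58,
        kp=dict(bone=0.73, brain=0.63, adipose=6.58, heart=0.97, kidney=0.55,
                gut=0.64, liver=0.50, lung=0.29, muscle=0.25, skin=0.73, spleen=0.31),
        kp_scaler=1.46, ic50_cyp11b1=77.0, ic50_cyp11b2=10.0,
        provenance=dict(ic50="monkey adrenal homogenate", other_adme="ML-predicted",
                        note="11β-hydroxylase inhibitor used as non-selective control"),
    ),
)

COMPOUND_NAMES: tuple[str, ...] = tuple(d["name"] for d in _LIBRARY_DATA)


def load_compound_library() -> list[CompoundRecord]:
    """Return the five built-in compound records (uncalibrated parameters).

    Record validation doubles as the fixture integrity check: a corrupted
    value raises ``ValueError`` naming the offending field.
    """
    return [CompoundRecord(**entry) for entry in _LIBRARY_DATA]


def get_compound(name: str, calibrated: bool = False) -> CompoundRecord:
    """Look up one library compound by (case-insensitive) name."""
    for record in load_compound_library():
        if record.name.lower() == name.lower():
            return apply_calibration(record) if calibrated else record
    raise KeyError(
        f"unknown compound {name!r}; known compounds: {', '.join(COMPOUND_NAMES)}"
    )
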