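"""Virtual reference human for whole-body PBPK simulation.

The whole-body model perfuses 14 tissue compartments in parallel between an
arterial and a mixed-venous blood pool, with the lung in series (venous blood
passes through the lung before reaching the arterial pool).  The drug-specific
rate equations need, for every tissue, a volume ``V_T`` (L) and a blood flow
``Q_T`` (L/h), plus the two blood-pool volumes.  Those anatomical constants are
collected here in a :class:`VirtualSubject`.

The default subject is a conventional 70 kg reference adult assembled from
standard physiology tables (see ``docs/methods.md`` for the values and their
provenance); both volumes and flows scale linearly with body weight.  The
``rest_of_body`` compartment absorbs the flow not assigned to a named organ so
that the non-lung flows always sum to cardiac output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

#: The 14 tissue compartments, in canonical state-vector order.
TISSUES: tuple[str, ...] = (
    "lung",
    "heart",
    "brain",
    "muscle",
    "adipose",
    "skin",
    "spleen",
    "pancreas",
    "liver",
    "stomach",
    "gut",
    "bone",
    "kidney",
    "rest_of_body",
)

#: Reference body weight (kg) for the built-in physiology table.
REFERENCE_BODY_WEIGHT = 70.0

#: Cardiac output of the 70 kg reference subject, L/h (5.6 L/min whole blood).
REFERENCE_CARDIAC_OUTPUT = 336.0

#: Total blood volume (L) at 70 kg, split venous:arterial = 3:1.
REFERENCE_BLOOD_VOLUME = 5.2

# Tissue volumes (L) at 70 kg.  Perfused-tissue volumes from conventional
# reference-adult tables; rest_of_body holds a nominal residual so that the
# perfused total (tissues + blood, 68.77 L) stays below body weight.
_REFERENCE_VOLUMES: dict[str, float] = {
    "lung": 0.50,
    "heart": 0.33,
    "brain": 1.45,
    "muscle": 29.00,
    "adipose": 14.30,
    "skin": 3.30,
    "spleen": 0.18,
    "pancreas": 0.10,
    "liver": 1.80,
    "stomach": 0.15,
    "gut": 1.65,
    "bone": 8.50,
    "kidney": 0.31,
    "rest_of_body": 2.00,
}

# Regional blood flows as fractions of cardiac output (non-lung tissues).
# rest_of_body takes the residual fraction so the split sums to exactly 1.
_FLOW_FRACTIONS: dict[str, float] = {
    "heart": 0.040,
    "brain": 0.120,
    "muscle": 0.170,
    "adipose": 0.050,
    "skin": 0.050,
    "spleen": 0.020,
    "pancreas": 0.010,
    "liver": 0.065,
    "stomach": 0.010,
    "gut": 0.140,
    "bone": 0.050,
    "kidney": 0.190,
}
_FLOW_FRACTIONS["rest_of_body"] = 1.0 - sum(_FLOW_FRACTIONS.values())

_FLOW_BALANCE_RTOL = 1e-9


@dataclass(frozen=True)
class TissueSpec:
    """One perfused tissue compartment: volume (L) and blood flow (L/h)."""

    name: str
    volume: float
    blood_flow: float

    def __post_init__(self) -> None:
        if self.name not in TISSUES:
            raise ValueError(
                f"unknown tissue {self.name!r}; expected one of {', '.join(TISSUES)}"
            )
        if not self.volume > 0:
            raise ValueError(f"tissue {self.name!r}: volume must be > 0, got {self.volume}")
        if not self.blood_flow > 0:
            raise ValueError(
                f"tissue {self.name!r}: blood_flow must be > 0, got {self.blood_flow}"
            )


@dataclass(frozen=True)
class VirtualSubject:
    """Anatomical parameter set for one virtual human.

    Invariants enforced on construction:

    * exactly the 14 canonical tissues, each with positive volume and flow;
    * flow balance — the non-lung flows sum to the lung flow (cardiac
      output), so the venous pool receives exactly what the lung carries;
    * positive venous and arterial blood volumes.
    """

    body_weight: float
    tissues: tuple[TissueSpec, ...]
    venous_volume: float
    arterial_volume: float

    def __post_init__(self) -> None:
        if not self.body_weight > 0:
            raise ValueError(f"body_weight must be > 0, got {self.body_weight}")
        if not self.venous_volume > 0 or not self.arterial_volume > 0:
            raise ValueError("blood-pool volumes must be > 0")
        names = tuple(t.name for t in self.tissues)
        if sorted(names) != sorted(TISSUES):
            missing = set(TISSUES) - set(names)
            extra = set(names) - set(TISSUES)
            raise ValueError(
                f"subject must define exactly the 14 tissues; missing={sorted(missing)}, "
                f"extra={sorted(extra)}"
            )
        by_name = {t.name: t for t in self.tissues}
        object.__setattr__(self, "tissues", tuple(by_name[n] for n in TISSUES))
        co = self.cardiac_output
        non_lung = sum(t.blood_flow for t in self.tissues if t.name != "lung")
        if not math.isclose(non_lung, co, rel_tol=_FLOW_BALANCE_RTOL):
            raise ValueError(
                f"flow imbalance: non-lung flows sum to {non_lung} L/h but lung "
                f"(cardiac output) is {co} L/h"
            )

    @property
    def cardiac_output(self) -> float:
        """Cardiac output (L/h); by construction the lung blood flow."""
        return self.tissue("lung").blood_flow

    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def total_volume(self) -> float:
        """Perfused volume: all tissue volumes plus both blood pools (L)."""
        return sum(t.volume for t in self.tissues) + self.venous_volume + self.arterial_volume

    def scaled(self, body_weight: float) -> "VirtualSubject":
        """Linearly rescale all volumes and flows to a new body weight."""
        if not body_weight > 0:
            raise ValueError(f"body_weight must be > 0, got {body_weight}")
        k = body_weight / self.body_weight
        return VirtualSubject(
            body_weight=body_weight,
            tissues=tuple(
                TissueSpec(t.name, t.volume * k, t.blood_flow * k) for t in self.tissues
            ),
            venous_volume=self.venous_volume * k,
            arterial_volume=self.arterial_volume * k,
        )


def reference_subject(body_weight: float = REFERENCE_BODY_WEIGHT) -> VirtualSubject:
    """Build the reference adult, linearly scaled to ``body_weight`` (kg).

    Volumes and flows scale proportionally from the documented 70 kg baseline
    (linear allometry).  Raises ``ValueError`` for non-positive weight.
    """
    if not body_weight > 0:
        raise ValueError(f"body_weight must be > 0, got {body_weight}")
    k = body_weight / REFERENCE_BODY_WEIGHT
    tissues = []
    for name in TISSUES:
        flow = (
            REFERENCE_CARDIAC_OUTPUT
            if name == "lung"
            else REFERENCE_CARDIAC_OUTPUT * _FLOW_FRACTIONS[name]
        )
        tissues.append(TissueSpec(name, _REFERENCE_VOLUMES[name] * k, flow * k))
    return VirtualSubject(
        body_weight=body_weight,
        tissues=tuple(tissues),
        venous_volume=REFERENCE_BLOOD_VOLUME * 0.75 * k,
        arterial_volume=REFERENCE_BLOOD_VOLUME * 0.25 * k,
    )


def subject_from_config(source: str | Path | Mapping) -> VirtualSubject:
    """Load a physiology override from a YAML mapping or file.

    Expected layout::

        body_weight: 70.0
        venous_volume: 3.9
        arterial_volume: 1.3
        tissues:
          lung: {volume_L: 0.5, flow_L_per_h: 336.0}
          heart: {volume_L: 0.33, flow_L_per_h: 13.44}
          ...   # all 14 tissues required

    The result is validated against the same invariants as the built-in
    subject (all volumes/flows positive, flow balance, 14 tissues).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    try:
        tissues = tuple(
            TissueSpec(name, float(spec["volume_L"]), float(spec["flow_L_per_h"]))
            for name, spec in cfg["tissues"].items()
        )
        return VirtualSubject(
            body_weight=float(cfg["body_weight"]),
            tissues=tissues,
            venous_volume=float(cfg["venous_volume"]),
            arterial_volume=float(cfg["arterial_volume"]),
        )
    except KeyError as exc:
        raise ValueError(f"physiology config missing required key: {exc}") from exc


def subject_to_config(subject: VirtualSubject) -> dict:
    """Inverse of :func:`subject_from_config` (round-trips exactly)."""
    return {
        "body_weight": subject.body_weight,
        "venous_volume": subject.venous_volume,
        "arterial_volume": subject.arterial_volume,
        "tissues": {
            t.name: {"volume_L": t.volume, "flow_L_per_h": t.blood_flow}
            for t in subject.tissues
        },
    }
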