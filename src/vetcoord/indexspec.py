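"""Declarative indicator-system specification.

An :class:`IndexSpec` describes the two evaluation subsystems as data, not
code: which indicators belong to which subsystem, the display unit of each,
and whether the indicator is benefit-type (``"+"``, larger is better) or
cost-type (``"-"``, smaller is better).  The default specification mirrors
the published provincial index system: four veterinary-workforce (VHR)
indicators from yearbook statistics and eight public-attention (PAAW)
indicators from search-interest keywords.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

VALID_ATTRIBUTES = ("+", "-")


@dataclass(frozen=True)
class Indicator:
    """One indicator: identifier, human label, display unit, attribute sign."""

    id: str
    label: str
    unit: str = ""
    attribute: str = "+"

    def __post_init__(self) -> None:
        if self.attribute not in VALID_ATTRIBUTES:
            raise ValueError(
                f"indicator {self.id!r}: attribute must be '+' or '-', "
                f"got {self.attribute!r}"
            )


@dataclass(frozen=True)
class IndexSpec:
    """Mapping of subsystem name -> ordered list of indicators."""

    subsystems: Mapping[str, tuple[Indicator, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, inds in self.subsystems.items():
            if not inds:
                raise ValueError(f"subsystem {name!r} has no indicators")
            for ind in inds:
                if ind.id in seen:
                    raise ValueError(f"duplicate indicator id {ind.id!r}")
                seen.add(ind.id)

    @property
    def subsystem_names(self) -> tuple[str, ...]:
        return tuple(self.subsystems)

    def indicators(self, subsystem: str) -> tuple[Indicator, ...]:
        return self.subsystems[subsystem]

    def attributes(self, subsystem: str) -> dict[str, str]:
        """indicator id -> '+' / '-' for one subsystem."""
        return {ind.id: ind.attribute for ind in self.subsystems[subsystem]}

    def subsystem_of(self) -> dict[str, str]:
        """indicator id -> subsystem name."""
        return {
            ind.id: name
            for name, inds in self.subsystems.items()
            for ind in inds
        }

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "subsystems": {
                name: [
                    {
                        "id": i.id,
                        "label": i.label,
                        "unit": i.unit,
                        "attribute": i.attribute,
                    }
                    for i in inds
                ]
                for name, inds in self.subsystems.items()
            }
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "IndexSpec":
        subs = {}
        for name, inds in d["subsystems"].items():
            subs[name] = tuple(
                Indicator(
                    id=i["id"],
                    label=i.get("label", i["id"]),
                    unit=i.get("unit", ""),
                    attribute=i.get("attribute", "+"),
                )
                for i in inds
            )
        return cls(subsystems=subs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IndexSpec":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"index specification file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text(encoding="utf-8")))

    @classmethod
    def uniform(
        cls, counts: Mapping[str, int] | None = None, attribute: str = "+"
    ) -> "IndexSpec":
        """Anonymous spec with ``counts[sub]`` same-sign indicators per subsystem."""
        counts = dict(counts or {"VHR": 4, "PAAW": 8})
        subs = {
            name: tuple(
                Indicator(id=f"{name}_{k + 1}", label=f"{name} indicator {k + 1}",
                          attribute=attribute)
                for k in range(n)
            )
            for name, n in counts.items()
        }
        return cls(subsystems=subs)


def default_index_spec() -> IndexSpec:
    """The published two-subsystem provincial index system.

    VHR: workforce size, technical structure, work efficiency and incentive
    indicators of township animal husbandry and veterinary stations.
    PAAW: annual search-interest indices for eight animal-health keywords.
    All twelve indicators are benefit-type ("+").
    """
    vhr = (
        Indicator("vhr_staff", "Number of staff in township stations", "person"),
        Indicator("vhr_senior_share",
                  "Proportion of staff with senior professional titles", "%"),
        Indicator("vhr_output_per_staff", "Annual average output per staff", "RMB"),
        Indicator("vhr_salary", "Annual average salary of staff", "RMB"),
    )
    paaw = (
        Indicator("paaw_avian_influenza", "Avian influenza", "index points"),
        Indicator("paaw_fmd", "Foot-and-mouth disease", "index points"),
        Indicator("paaw_pig_disease", "Pig diseases", "index points"),
        Indicator("paaw_chicken_disease", "Chicken diseases", "index points"),
        Indicator("paaw_quarantine", "Animal quarantine", "index points"),
        Indicator("paaw_epidemic_prevention", "Animal epidemic prevention",
                  "index points"),
        Indicator("paaw_husbandry_vet", "Animal husbandry and veterinary",
                  "index points"),
        Indicator("paaw_livestock_station", "Livestock station", "index points"),
    )
    return IndexSpec(subsystems={"VHR": vhr, "PAAW": paaw})
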