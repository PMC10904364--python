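"""Marker panel metadata.

A seqIF acquisition cycles through staining/imaging/elution rounds; each
marker is imaged in one fluorescence channel (TRITC or Cy5) during one cycle,
and its single-cell readout is averaged over one subcellular compartment:
the segmented nucleus for nuclear factors (transcription factors, ki67-type
proliferation markers, T-cell markers read on the nuclear mask) or the
approximated cytoplasm ring for membrane/cytoplasmic markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

NUCLEUS = "nucleus"
CYTOPLASM = "cytoplasm"

#: Channel names of the non-marker planes, in stack order.
DAPI_CHANNEL = "DAPI"
AF_CHANNELS = ("AF_TRITC", "AF_Cy5")


@dataclass(frozen=True)
class MarkerDef:
    """One marker: name, fluorescence channel, acquisition cycle, compartment."""

    name: str
    channel: str
    cycle: int
    compartment: str
    display_max: float | None = None

    def __post_init__(self) -> None:
        if self.compartment not in (NUCLEUS, CYTOPLASM):
            raise ValueError(
                f"marker {self.name!r}: compartment must be {NUCLEUS!r} or "
                f"{CYTOPLASM!r}, got {self.compartment!r}"
            )


@dataclass
class MarkerPanel:
    """Ordered collection of :class:`MarkerDef` with unique names."""

    markers: list[MarkerDef] = field(default_factory=list)
    channels: tuple[str, ...] = ("TRITC", "Cy5")

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        for m in self.markers:
            if m.channel not in self.channels:
                raise ValueError(
                    f"marker {m.name!r}: channel {m.channel!r} not in "
                    f"declared channel set {self.channels}"
                )

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.markers)

    def nuclear_markers(self) -> list[str]:
        return [m.name for m in self.markers if m.compartment == NUCLEUS]

    def cytoplasmic_markers(self) -> list[str]:
        return [m.name for m in self.markers if m.compartment == CYTOPLASM]

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "markers": [
                {
                    "name": m.name,
                    "channel": m.channel,
                    "cycle": m.cycle,
                    "compartment": m.compartment,
                    **({"display_max": m.display_max} if m.display_max else {}),
                }
                for m in self.markers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        return cls(
            markers=[MarkerDef(**m) for m in d["markers"]],
            channels=tuple(d.get("channels", ("TRITC", "Cy5"))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def lung_tme_panel() -> MarkerPanel:
    """The 15-marker immune/tumor-microenvironment panel used for rule-based
    phenotyping of lung tumor TMAs.

    FoxP3, IDO-1, ki67, CD3, CD4 and CD8 are read on the nuclear mask; all
    other markers on the approximated cytoplasm compartment.
    """
    nuclear = {"FoxP3", "IDO-1", "ki67", "CD3", "CD4", "CD8"}
    order = [
        "CD45", "CD3", "CD4", "CD8", "FoxP3", "CD20", "CD68", "CD11c",
        "CD16", "HLA-DR", "PanCK", "ki67", "PD-L1", "aSMA", "CD31",
    ]
    markers = [
        MarkerDef(
            name=n,
            channel="TRITC" if i % 2 == 0 else "Cy5",
            cycle=i // 2 + 1,
            compartment=NUCLEUS if n in nuclear else CYTOPLASM,
        )
        for i, n in enumerate(order)
    ]
    return MarkerPanel(markers=markers)


def phantom_panel() -> MarkerPanel:
    """Compact 5-marker panel matching the default synthetic tissue phantom."""
    defs = [
        ("PanCK", "TRITC", 1, CYTOPLASM),
        ("CD3", "Cy5", 1, NUCLEUS),
        ("CD4", "TRITC", 2, NUCLEUS),
        ("CD8", "Cy5", 2, NUCLEUS),
        ("CD68", "TRITC", 3, CYTOPLASM),
    ]
    return MarkerPanel(markers=[MarkerDef(*d) for d in defs])
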