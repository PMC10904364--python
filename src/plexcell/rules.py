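"""Rule-tree cell classification over binarized marker calls.

A :class:`RuleSet` is a binary decision tree: each internal node tests one
marker's positivity and descends to its ``if_positive`` or ``if_negative``
child; leaves carry phenotype labels. A cell whose path reaches a missing
child is labelled ``Unknown``, so partial trees are legal and every cell
receives exactly one label. Trees are validated at load time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = ["RuleNode", "RuleSet", "classify_tree", "apply_probability_cutoff",
           "lung_tme_ruleset", "phantom_ruleset"]

UNKNOWN = "Unknown"


@dataclass
class RuleNode:
    """Internal node (``marker`` set) or leaf (``label`` set)."""

    marker: str | None = None
    if_positive: "RuleNode | None" = None
    if_negative: "RuleNode | None" = None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None


class RuleSet:
    """Validated phenotyping decision tree."""

    def __init__(self, root: RuleNode, markers: list[str] | None = None):
        self.root = root
        self.markers = self._collect_markers(root)
        if markers is not None:
            unknown = set(self.markers) - set(markers)
            if unknown:
                raise ValueError(
                    f"ruleset references markers absent from panel: {sorted(unknown)}"
                )

    @staticmethod
    def _collect_markers(root: RuleNode) -> list[str]:
        markers: list[str] = []
        seen: set[int] = set()

        def walk(node: RuleNode, depth: int) -> None:
            if id(node) in seen:
                raise ValueError("ruleset tree contains a cycle")
            seen.add(id(node))
            if depth > 64:
                raise ValueError("ruleset tree too deep (cycle?)")
            if node.is_leaf:
                if node.marker is not None:
                    raise ValueError("a node cannot be both leaf and internal")
                return
            if node.marker is None:
                raise ValueError("internal node missing marker")
            if node.marker not in markers:
                markers.append(node.marker)
            for child in (node.if_positive, node.if_negative):
                if child is not None:
                    walk(child, depth + 1)

        walk(root, 0)
        return markers

    # -- serialization ------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict, markers: list[str] | None = None) -> "RuleSet":
        def build(nd: dict) -> RuleNode:
            if "label" in nd:
                extra = set(nd) - {"label"}
                if extra:
                    raise ValueError(f"leaf node has extra keys: {extra}")
                return RuleNode(label=str(nd["label"]))
            if "marker" not in nd:
                raise ValueError(f"node needs 'marker' or 'label': {nd}")
            return RuleNode(
                marker=str(nd["marker"]),
                if_positive=build(nd["if_positive"]) if nd.get("if_positive") else None,
                if_negative=build(nd["if_negative"]) if nd.get("if_negative") else None,
            )

        return cls(build(d), markers=markers)

    def to_dict(self) -> dict:
        def dump(node: RuleNode) -> dict:
            if node.is_leaf:
                return {"label": node.label}
            d: dict = {"marker": node.marker}
            if node.if_positive is not None:
                d["if_positive"] = dump(node.if_positive)
            if node.if_negative is not None:
                d["if_negative"] = dump(node.if_negative)
            return d

        return dump(self.root)

    @classmethod
    def from_yaml(cls, path, markers: list[str] | None = None) -> "RuleSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), markers=markers)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- classification -----------------------------------------------------
    def classify_one(self, calls: dict[str, int]) -> str:
        node = self.root
        while not node.is_leaf:
            child = node.if_positive if calls[node.marker] else node.if_negative
            if child is None:
                return UNKNOWN
            node = child
        return node.label  # type: ignore[return-value]


def classify_tree(binary: pd.DataFrame, rules: RuleSet) -> pd.Series:
    """Label every cell by descending the rule tree on its binary profile.

    Vectorized by profile: with k markers there are at most 2^k distinct
    paths, each classified once.
    """
    missing = [m for m in rules.markers if m not in binary.columns]
    if missing:
        raise ValueError(f"binary matrix missing rule markers: {missing}")
    sub = binary[rules.markers].to_numpy(dtype=np.int8)
    profiles, inverse = np.unique(sub, axis=0, return_inverse=True)
    labels = np.array(
        [
            rules.classify_one(dict(zip(rules.markers, prof)))
            for prof in profiles
        ],
        dtype=object,
    )
    return pd.Series(labels[inverse], index=binary.index, name="phenotype")


def apply_probability_cutoff(
    labels: pd.Series, probabilities: pd.Series, cutoff: float = 0.5
) -> pd.Series:
    """Post-rule for probabilistic assignments: below-cutoff cells become
    ``Unknown``. (Adapter for external probabilistic cell typers.)"""
    out = labels.copy()
    out[probabilities < cutoff] = UNKNOWN
    return out


def phantom_ruleset() -> RuleSet:
    """Ruleset matching the default synthetic phantom's phenotypes."""
    return RuleSet.from_dict(
        {
            "marker": "PanCK",
            "if_positive": {"label": "Tumor"},
            "if_negative": {
                "marker": "CD3",
                "if_positive": {
                    "marker": "CD8",
                    "if_positive": {"label": "T cytotoxic"},
                    "if_negative": {
                        "marker": "CD4",
                        "if_positive": {"label": "T helper"},
                    },
                },
                "if_negative": {
                    "marker": "CD68",
                    "if_positive": {"label": "Macrophage"},
                    "if_negative": {"label": "Other"},
                },
            },
        }
    )


def lung_tme_ruleset() -> RuleSet:
    """Default immune-lineage tree over the 15-marker lung TME panel.

    Epithelial tumor cells gate first on PanCK; leukocytes on CD45, then the
    T/B/myeloid lineages; stromal and vascular cells on aSMA/CD31. The exact
    topology is configuration — edit the YAML export to match a study.
    """
    treg = {
        "marker": "FoxP3",
        "if_positive": {"label": "T regulatory"},
        "if_negative": {"label": "T helper"},
    }
    tcell = {
        "marker": "CD8",
        "if_positive": {"label": "T cytotoxic"},
        "if_negative": {
            "marker": "CD4",
            "if_positive": treg,
            "if_negative": {"label": "T cell other"},
        },
    }
    myeloid = {
        "marker": "CD68",
        "if_positive": {"label": "Macrophage"},
        "if_negative": {
            "marker": "CD11c",
            "if_positive": {"label": "Dendritic cell"},
            "if_negative": {
                "marker": "CD16",
                "if_positive": {"label": "NK/monocyte"},
                "if_negative": {"label": "Leukocyte other"},
            },
        },
    }
    leukocyte = {
        "marker": "CD3",
        "if_positive": tcell,
        "if_negative": {
            "marker": "CD20",
            "if_positive": {"label": "B cell"},
            "if_negative": myeloid,
        },
    }
    root = {
        "marker": "PanCK",
        "if_positive": {"label": "Tumor"},
        "if_negative": {
            "marker": "CD45",
            "if_positive": leukocyte,
            "if_negative": {
                "marker": "aSMA",
                "if_positive": {"label": "Stromal"},
                "if_negative": {
                    "marker": "CD31",
                    "if_positive": {"label": "Endothelial"},
                },
            },
        },
    }
    return RuleSet.from_dict(root)
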