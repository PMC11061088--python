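"""The concept inventory: named concepts with perceptual meaning.

Property concepts template exactly one feature dimension with a Gaussian
around a prototypical value; object concepts may template several feature
dimensions at once; relation and action concepts refer to a patterned
relational template.  The default inventory is the minimal set the
architecture's example phrases need, and is extensible via JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

__all__ = ["ConceptDef", "ConceptInventory", "default_inventory", "SHAPE_CLASSES"]

KINDS = ("property", "object", "spatial_relation", "movement_relation", "action")

# categorical shape axis: well-separated Gaussian centers per class
SHAPE_CLASSES = ("ball", "tree", "lake", "house", "cube", "star")
SHAPE_SPACING = 20.0
SHAPE_WIDTH = 4.0


def shape_center(shape: str) -> float:
    return 10.0 + SHAPE_SPACING * SHAPE_CLASSES.index(shape)


@dataclass(frozen=True)
class ConceptDef:
    """One named concept and its patterned connectivity."""

    name: str
    kind: str
    # feature dim name -> (prototype center, Gaussian width)
    feature_templates: dict[str, tuple[float, float]] = dc_field(default_factory=dict)
    relation_template_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown concept kind {self.kind!r}")
        if self.kind == "property" and len(self.feature_templates) != 1:
            raise ValueError("property concepts template exactly one feature dim")
        if self.kind in ("spatial_relation", "movement_relation", "action"):
            if self.relation_template_id is None:
                raise ValueError(f"{self.kind} concept needs a relation template")


class ConceptInventory:
    def __init__(self, concepts: dict[str, ConceptDef] | None = None):
        self.concepts: dict[str, ConceptDef] = dict(concepts or {})

    def add(self, c: ConceptDef) -> "ConceptInventory":
        self.concepts[c.name] = c
        return self

    def __getitem__(self, name: str) -> ConceptDef:
        if name not in self.concepts:
            raise KeyError(f"unknown concept {name!r}")
        return self.concepts[name]

    def __contains__(self, name: str) -> bool:
        return name in self.concepts

    def of_kind(self, *kinds: str) -> list[ConceptDef]:
        return [c for c in self.concepts.values() if c.kind in kinds]

    def to_json(self, path: str | Path | None = None) -> str:
        data = {
            name: {
                "kind": c.kind,
                "feature_templates": {k: list(v) for k, v in c.feature_templates.items()},
                "relation_template_id": c.relation_template_id,
            }
            for name, c in self.concepts.items()
        }
        text = json.dumps(data, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ConceptInventory":
        s = str(text_or_path)
        if "\n" not in s and len(s) < 1024 and Path(s).exists():
            s = Path(s).read_text()
        data = json.loads(s)
        inv = cls()
        for name, d in data.items():
            inv.add(
                ConceptDef(
                    name,
                    d["kind"],
                    {k: tuple(v) for k, v in d.get("feature_templates", {}).items()},
                    d.get("relation_template_id"),
                )
            )
        return inv


def default_inventory() -> ConceptInventory:
    inv = ConceptInventory()
    for shape in SHAPE_CLASSES:
        inv.add(
            ConceptDef(shape, "object", {"shape": (shape_center(shape), SHAPE_WIDTH)})
        )
    for name, hue in [("red", 0.0), ("green", 120.0), ("blue", 240.0)]:
        inv.add(ConceptDef(name, "property", {"hue": (hue, 30.0)}))
    # "big"/"small" as absolute size-range prototypes
    inv.add(ConceptDef("big", "property", {"size": (9.0, 1.5)}))
    inv.add(ConceptDef("small", "property", {"size": (2.5, 1.5)}))
    for rel in ("left_of", "right_of", "above", "below"):
        inv.add(ConceptDef(rel, "spatial_relation", relation_template_id=rel))
    inv.add(ConceptDef("approach", "action", relation_template_id="approach"))
    return inv
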