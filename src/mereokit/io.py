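"""Plain-text (YAML/JSON) serialization of models and classification cases.

The document shape for a bare model is::

    entities: {id: [type, ...], ...}
    parts: [[whole, part], ...]
    grains: {id: [id, ...], ...}      # optional explicit grain designation

A *case* document for the classifier additionally carries the type
hierarchy and the composition spec::

    is_a: [[child, parent], ...]
    disjoint: [[a, b], ...]
    coll_types: {Name: {base: Base}, Name2: {base: Base, n: 2}}
    spec: {name: X, closed: true, slots: [[Type, exactly, 2], [Type2, at_least, 1]]}
    level: Atom            # or [Proton, Neutron, Electron]
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import yaml

from .model import (
    ANY,
    FiniteModel,
    TypeName,
    TypeRegistry,
    TypeSpec,
    at_least,
    build_model,
    exactly,
)

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "dump_model",
    "load_model",
    "load_case",
]


def model_to_dict(model: FiniteModel) -> dict:
    doc: dict = {
        "entities": {
            e: sorted(t.name for t in model.instance_of.get(e, ()))
            for e in sorted(model.entities)
        },
        "parts": [list(p) for p in sorted(model.direct_part)],
    }
    if model.grain_designation:
        doc["grains"] = {
            e: sorted(gs) for e, gs in sorted(model.grain_designation.items())
        }
    return doc


def _resolve_type(name: str, registry: Optional[TypeRegistry]) -> TypeName:
    if registry is not None:
        for t in registry.types:
            if t.name == name:
                return t
    return TypeName(name)


def model_from_dict(doc: dict, registry: Optional[TypeRegistry] = None) -> FiniteModel:
    types = {
        e: {_resolve_type(n, registry) for n in (names or [])}
        for e, names in doc.get("entities", {}).items()
    }
    edges = [tuple(p) for p in doc.get("parts", [])]
    grains = {e: set(gs) for e, gs in doc.get("grains", {}).items()} or None
    return build_model(types, edges, grains)


def _load_doc(path: Union[str, Path]) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_model(model: FiniteModel, path: Union[str, Path]) -> None:
    path = Path(path)
    doc = model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))


def load_model(
    path: Union[str, Path], registry: Optional[TypeRegistry] = None
) -> FiniteModel:
    return model_from_dict(_load_doc(path), registry)


def _registry_from_doc(doc: dict) -> TypeRegistry:
    reg = TypeRegistry()
    named: dict[str, TypeName] = {}

    def get(name: str) -> TypeName:
        if name not in named:
            named[name] = TypeName(name)
            reg.add(named[name])
        return named[name]

    for cname, info in (doc.get("coll_types") or {}).items():
        base = get(info["base"])
        n = info.get("n")
        t = (
            TypeName.n_coll(base, n, cname) if n else TypeName.coll(base, cname)
        )
        named[cname] = t
        reg.add(t)
    for child, parent in doc.get("is_a", []):
        reg.add_is_a(get(child), get(parent))
    for a, b in doc.get("disjoint", []):
        reg.add_disjoint(get(a), get(b))
    for names in (doc.get("entities") or {}).values():
        for n in names or []:
            get(n)
    return reg


_CARDS = {"exactly": exactly, "at_least": at_least}


def load_case(path: Union[str, Path]):
    """Load a classification case: (model, registry, spec, level)."""
    doc = _load_doc(path)
    registry = _registry_from_doc(doc)
    model = model_from_dict(doc, registry)
    spec = None
    if "spec" in doc:
        sdoc = doc["spec"]
        slots = []
        for slot in sdoc.get("slots", []):
            tname, card = slot[0], slot[1]
            if card == "any":
                slots.append((_resolve_type(tname, registry), ANY))
            else:
                slots.append((_resolve_type(tname, registry), _CARDS[card](int(slot[2]))))
        spec = TypeSpec(
            _resolve_type(sdoc["name"], registry), slots, sdoc.get("closed", True)
        )
    level = None
    if "level" in doc:
        lv = doc["level"]
        if isinstance(lv, list):
            level = [_resolve_type(n, registry) for n in lv]
        else:
            level = _resolve_type(lv, registry)
    return model, registry, spec, level
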