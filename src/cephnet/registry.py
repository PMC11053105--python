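"""Declarative measurement registry: numbered variables defined as recipes
over geometric primitives, loaded from a versioned YAML file.

A registry is a list of :class:`MeasurementDefinition`.  Each recipe is a
small expression tree referencing landmark names (optionally derived
midpoints, ``"mid(P,Q)"``), constructed lines, or other registered
measurements (``combo`` / ``ratio`` nodes).  Evaluation order is resolved
topologically, so composites may reference any other variable as long as
the dependency graph is acyclic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import geometry
from .landmarks import LandmarkSet

VALID_UNITS = {"deg", "mm", "ratio", "complex"}
_MID_RE = re.compile(r"^mid\(\s*([^,\s]+)\s*,\s*([^,\s)]+)\s*\)$")


class RegistryError(ValueError):
    """Raised for malformed or cyclic measurement registries."""


@dataclass(frozen=True)
class MeasurementDefinition:
    number: int
    name: str
    unit: str
    recipe: Mapping[str, Any]
    sign: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.number):
            raise RegistryError(f"invalid variable number {self.number}")
        if self.unit not in VALID_UNITS:
            raise RegistryError(f"[{self.number}] {self.name}: unknown unit {self.unit!r}")
        if "op" not in self.recipe:
            raise RegistryError(f"[{self.number}] {self.name}: recipe lacks 'op'")

    def dependencies(self) -> list[int]:
        """Numbers of other measurements this recipe references."""
        op = self.recipe["op"]
        if op == "combo":
            return [int(num) for _, num in self.recipe["terms"]]
        if op == "ratio":
            return [int(self.recipe["num"]), int(self.recipe["den"])]
        return []

    def referenced_landmarks(self) -> set[str]:
        names: set[str] = set()

        def add_point(ref: str) -> None:
            m = _MID_RE.match(ref)
            if m:
                names.update(m.groups())
            else:
                names.add(ref)

        def add_line(line) -> None:
            if isinstance(line, Mapping):
                add_point(line["through"])
                for ref in line["perp_to"]:
                    add_point(ref)
            else:
                for ref in line:
                    add_point(ref)

        r = self.recipe
        op = r["op"]
        if op in ("angle", "dist"):
            for ref in r["points"]:
                add_point(ref)
        elif op == "vangle":
            for ref in (*r["u"], *r["v"]):
                add_point(ref)
        elif op == "langle":
            add_line(r["l1"])
            add_line(r["l2"])
        elif op == "point_line":
            add_point(r["point"])
            add_line(r["line"])
        elif op in ("along_diff", "perp_diff"):
            for ref in r["points"]:
                add_point(ref)
            add_line(r["line"])
        return names


def _resolve_point(ref: str, lm: LandmarkSet) -> np.ndarray:
    m = _MID_RE.match(ref)
    if m:
        return geometry.midpoint(lm[m.group(1)], lm[m.group(2)])
    return lm[ref]


def _resolve_line(line, lm: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(line, Mapping):
        through = _resolve_point(line["through"], lm)
        qa, qb = (_resolve_point(p, lm) for p in line["perp_to"])
        return geometry.perpendicular_through(through, qa, qb)
    a, b = (_resolve_point(p, lm) for p in line)
    return a, b


def evaluate_recipe(recipe: Mapping[str, Any], lm: LandmarkSet,
                    computed: Mapping[int, float]) -> float:
    """Evaluate one recipe on a landmark set.

    ``computed`` maps already-evaluated variable numbers to values (for
    combo/ratio nodes).
    """
    op = recipe["op"]
    if op == "angle":
        p, v, q = (_resolve_point(r, lm) for r in recipe["points"])
        return geometry.three_point_angle(p, v, q)
    if op == "vangle":
        ua, ub = (_resolve_point(r, lm) for r in recipe["u"])
        va, vb = (_resolve_point(r, lm) for r in recipe["v"])
        return geometry.vector_angle(ua, ub, va, vb, signed=bool(recipe.get("signed")))
    if op == "langle":
        l1 = _resolve_line(recipe["l1"], lm)
        l2 = _resolve_line(recipe["l2"], lm)
        return geometry.line_angle(*l1, *l2, signed=bool(recipe.get("signed")))
    if op == "point_line":
        p = _resolve_point(recipe["point"], lm)
        a, b = _resolve_line(recipe["line"], lm)
        return geometry.signed_point_line_distance(p, a, b)
    if op == "along_diff":
        p, q = (_resolve_point(r, lm) for r in recipe["points"])
        a, b = _resolve_line(recipe["line"], lm)
        return geometry.projection_coordinate(p, a, b) - geometry.projection_coordinate(q, a, b)
    if op == "perp_diff":
        p, q = (_resolve_point(r, lm) for r in recipe["points"])
        a, b = _resolve_line(recipe["line"], lm)
        return (geometry.signed_point_line_distance(p, a, b)
                - geometry.signed_point_line_distance(q, a, b))
    if op == "dist":
        p, q = (_resolve_point(r, lm) for r in recipe["points"])
        return geometry.point_distance(p, q)
    if op == "combo":
        total = float(recipe.get("const", 0.0))
        for coef, num in recipe["terms"]:
            total += float(coef) * computed[int(num)]
        return total
    if op == "ratio":
        den = computed[int(recipe["den"])]
        if abs(den) < 1e-12:
            raise geometry.DegenerateGeometryError(
                f"ratio denominator [{recipe['den']}] is zero")
        return computed[int(recipe["num"])] / den
    raise RegistryError(f"unknown recipe op {op!r}")


def topological_order(registry: list[MeasurementDefinition]) -> list[MeasurementDefinition]:
    """Order definitions so every combo/ratio dependency precedes its user.

    Raises :class:`RegistryError` on cycles or dangling references.
    """
    by_num = {d.number: d for d in registry}
    if len(by_num) != len(registry):
        raise RegistryError("duplicate variable numbers in registry")
    order: list[MeasurementDefinition] = []
    state: dict[int, int] = {}  # 0 = visiting, 1 = done

    def visit(num: int, chain: tuple[int, ...]) -> None:
        if state.get(num) == 1:
            return
        if state.get(num) == 0:
            raise RegistryError(f"dependency cycle through variables {chain + (num,)}")
        if num not in by_num:
            raise RegistryError(f"recipe references unregistered variable [{num}]")
        state[num] = 0
        for dep in by_num[num].dependencies():
            visit(dep, chain + (num,))
        state[num] = 1
        order.append(by_num[num])

    for d in sorted(registry, key=lambda d: d.number):
        visit(d.number, ())
    return order


def load_registry(path: str | Path | None = None) -> list[MeasurementDefinition]:
    """Load a measurement registry from YAML; default is the bundled v1 file.

    The returned list is sorted by variable number and validated
    (units, recipe ops, acyclic dependencies).
    """
    if path is None:
        text = resources.files("cephnet").joinpath("data/registry_v1.yaml").read_text()
    else:
        text = Path(path).read_text()
    payload = yaml.safe_load(text)
    defs = [
        MeasurementDefinition(
            number=int(e["number"]),
            name=str(e["name"]),
            unit=str(e["unit"]),
            recipe=e["recipe"],
            sign=e.get("sign"),
        )
        for e in payload["measurements"]
    ]
    defs.sort(key=lambda d: d.number)
    topological_order(defs)  # validation only
    return defs
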