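"""Measurement computation: evaluate a registry on landmark sets and
assemble the subjects-by-variables table that feeds the network analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DegenerateGeometryError
from .landmarks import LandmarkSet, MissingLandmarkError
from .registry import MeasurementDefinition, evaluate_recipe, topological_order

log = logging.getLogger(__name__)


@dataclass
class MeasurementTable:
    """Subjects x variables numeric matrix with unit and number metadata.

    Columns are ordered by variable number; all entries are finite
    (complete-case policy: subjects with any failed measurement are
    rejected at construction time).
    """

    data: pd.DataFrame
    units: dict[str, str]
    numbers: dict[str, int]
    rejected_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.data.columns) != sorted(self.data.columns, key=lambda c: self.numbers[c]):
            self.data = self.data[sorted(self.data.columns, key=lambda c: self.numbers[c])]
        if self.data.size and not np.isfinite(self.data.to_numpy(float)).all():
            raise ValueError("measurement table contains non-finite entries")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "subject_id", self.data.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, units: dict[str, str] | None = None,
                 numbers: dict[str, int] | None = None) -> "MeasurementTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")
        if len(set(header)) != len(header):
            raise ValueError("duplicate variable names in table header")
        # round_trip parsing keeps write->read->write byte-identical
        df = pd.read_csv(path, float_precision="round_trip")
        if "subject_id" in df.columns:
            df = df.set_index("subject_id")
        cols = list(df.columns)
        numbers = numbers or {c: i + 1 for i, c in enumerate(cols)}
        units = units or {c: "unknown" for c in cols}
        dropped = df.index[df.isna().any(axis=1)].tolist()
        if dropped:
            log.warning("dropping %d incomplete rows: %s", len(dropped), dropped[:10])
            df = df.dropna()
        return cls(df, units=units, numbers=numbers,
                   rejected_subjects=[str(s) for s in dropped])


def compute_measurement(lm: LandmarkSet, defn: MeasurementDefinition,
                        registry: list[MeasurementDefinition] | None = None) -> float:
    """Evaluate a single measurement for one subject.

    Composite definitions (combo/ratio) need ``registry`` to resolve the
    measurements they reference.
    """
    deps = defn.dependencies()
    computed: dict[int, float] = {}
    if deps:
        if registry is None:
            raise ValueError(
                f"[{defn.number}] {defn.name} references other variables; "
                "pass the full registry")
        by_num = {d.number: d for d in registry}
        for d in topological_order([by_num[n] for n in _closure(deps, by_num)]):
            computed[d.number] = evaluate_recipe(d.recipe, lm, computed)
    return evaluate_recipe(defn.recipe, lm, computed)


def _closure(nums: list[int], by_num: dict[int, MeasurementDefinition]) -> list[int]:
    seen: list[int] = []
    stack = list(nums)
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.append(n)
        stack.extend(by_num[n].dependencies())
    return seen


def compute_table(landmark_sets: list[LandmarkSet],
                  registry: list[MeasurementDefinition]) -> MeasurementTable:
    """Evaluate the full registry on every subject.

    Subjects for which any measurement fails (missing landmark,
    degenerate geometry) are rejected and logged; the returned table is
    complete-case.
    """
    order = topological_order(registry)
    names = [d.name for d in sorted(registry, key=lambda d: d.number)]
    units = {d.name: d.unit for d in registry}
    numbers = {d.name: d.number for d in registry}

    rows: list[dict[str, float]] = []
    index: list[str] = []
    rejected: list[str] = []
    for lm in landmark_sets:
        computed: dict[int, float] = {}
        try:
            for d in order:
                computed[d.number] = evaluate_recipe(d.recipe, lm, computed)
        except (MissingLandmarkError, DegenerateGeometryError) as exc:
            log.warning("rejecting subject %s: %s", lm.subject_id, exc)
            rejected.append(lm.subject_id)
            continue
        by_number = {d.number: computed[d.number] for d in registry}
        rows.append({d.name: by_number[d.number] for d in registry})
        index.append(lm.subject_id)

    df = pd.DataFrame(rows, index=index, columns=names, dtype=float)
    return MeasurementTable(df, units=units, numbers=numbers, rejected_subjects=rejected)


def check_redundancy(table: MeasurementTable, threshold: float = 0.999) -> list[tuple[str, str, float]]:
    """Flag variable pairs that are geometric duplicates (|r| > threshold).

    Mirrors the exclusion rule used to prune variables whose definitions
    are affinely dependent (e.g. an angle sum versus its equivalent
    single angle).  Returns (var1, var2, r) sorted by |r| descending.
    """
    if table.n_subjects < 3:
        raise ValueError("redundancy check needs at least 3 subjects")
    x = table.data.to_numpy(float)
    keep = x.std(axis=0) > 0
    cols = [c for c, k in zip(table.variables, keep) if k]
    r = np.corrcoef(x[:, keep], rowvar=False)
    flags = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(r[i, j]) > threshold:
                flags.append((cols[i], cols[j], float(r[i, j])))
    flags.sort(key=lambda t: -abs(t[2]))
    return flags
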