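"""Synthetic measurement tables with a prescribed block-correlation
structure, plus landmark sets drawn from a perturbable template.

The sampling model is multivariate Gaussian: Pearson correlation fully
parameterizes it, which is exactly the statistic the downstream network
analysis consumes.  Per-variable means/sds only set native units and
carry no analytical weight (Pearson r is affine-invariant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .corrnet import CorrelationMatrix
from .landmarks import REQUIRED_LANDMARKS, LandmarkSet
from .measure import MeasurementTable
from .registry import load_registry

import pandas as pd

#: Max entry displacement tolerated when projecting to the nearest PSD matrix.
PSD_REPAIR_LIMIT = 0.05
_PSD_TOL = 1e-10


class InfeasibleBlockSpecError(ValueError):
    """The requested block correlation structure is not attainable."""


@dataclass(frozen=True)
class BlockSpec:
    """One group of variables sharing a common within-group correlation."""

    group_label: str
    member_variables: tuple[int, ...]
    within_r: float
    between_r: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_variables", tuple(self.member_variables))
        # within_r = 1 is the degenerate perfectly-correlated block
        if not 0.0 < self.within_r <= 1.0:
            raise ValueError(f"block {self.group_label}: within_r must be in (0, 1]")
        if not 0.0 <= self.between_r < 1.0:
            raise ValueError(f"block {self.group_label}: between_r must be in [0, 1)")
        if self.within_r <= self.between_r:
            raise ValueError(
                f"block {self.group_label}: within_r must exceed between_r "
                "(blocks must be separable)")
        if len(set(self.member_variables)) != len(self.member_variables):
            raise ValueError(f"block {self.group_label}: duplicate members")


@dataclass
class GeneratorConfig:
    n_subjects: int
    blocks: list[BlockSpec] = field(default_factory=list)
    unassigned_r: float = 0.0
    seed: int = 0
    means: dict[str, float] | None = None
    sds: dict[str, float] | None = None
    n_variables: int = 65

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be at least 3 (correlation undefined below)")
        if not 0.0 <= self.unassigned_r < 1.0:
            raise ValueError("unassigned_r must be in [0, 1)")
        seen: set[int] = set()
        for b in self.blocks:
            members = set(b.member_variables)
            if members & seen:
                raise ValueError(
                    f"block {b.group_label}: members overlap another block: "
                    f"{sorted(members & seen)}")
            if not members <= set(range(1, self.n_variables + 1)):
                raise ValueError(
                    f"block {b.group_label}: members outside 1..{self.n_variables}")
            seen |= members

    @classmethod
    def from_dict(cls, payload: dict) -> "GeneratorConfig":
        blocks = [
            BlockSpec(
                group_label=str(b["label"]),
                member_variables=tuple(int(m) for m in b["members"]),
                within_r=float(b["within_r"]),
                between_r=float(b["between_r"]),
            )
            for b in payload.get("blocks", [])
        ]
        return cls(
            n_subjects=int(payload["n_subjects"]),
            blocks=blocks,
            unassigned_r=float(payload.get("unassigned_r", 0.0)),
            seed=int(payload.get("seed", 0)),
            means=payload.get("means"),
            sds=payload.get("sds"),
            n_variables=int(payload.get("n_variables", 65)),
        )

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        text = Path(path).read_text()
        payload = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(payload)


@dataclass
class LandmarkTemplate:
    """Mean landmark coordinates (mm) plus per-landmark Gaussian jitter."""

    mean_xy: dict[str, tuple[float, float]]
    perturbation_sd: dict[str, float]

    def __post_init__(self) -> None:
        missing = REQUIRED_LANDMARKS - set(self.mean_xy)
        if missing:
            raise ValueError(f"template missing required landmarks: {sorted(missing)}")
        bad = [k for k, v in self.perturbation_sd.items() if v < 0]
        if bad:
            raise ValueError(f"negative perturbation sd for: {bad}")


# Template coordinates: origin at S, x anterior-positive, y superior-positive.
# Values are implementation-chosen to form a plausible, non-degenerate adult
# lateral configuration; only identities valid for any such configuration are
# relied on downstream.
_TEMPLATE_XY: dict[str, tuple[float, float]] = {
    "S": (0.0, 0.0), "N": (71.0, 8.0), "Or": (52.0, -22.0), "Po": (-38.0, -18.0),
    "Ar": (-15.0, -33.0), "Ba": (-25.0, -40.0), "Pt": (8.0, -25.0),
    "ANS": (68.0, -48.0), "PNS": (18.0, -46.0), "A": (68.0, -55.0),
    "B": (59.0, -98.0), "Pog": (63.0, -110.0), "Gn": (60.0, -115.0),
    "Me": (55.0, -117.0), "Go": (-5.0, -85.0),
    "U1_tip": (69.0, -75.0), "U1_apex": (62.0, -52.0),
    "L1_tip": (66.0, -73.0), "L1_apex": (58.0, -85.0),
    "U6": (20.0, -68.0), "Mo": (25.0, -66.0),
    "Prn": (95.0, -45.0), "Ls": (87.0, -64.0), "Li": (82.0, -82.0),
    "Pog_soft": (75.0, -112.0),
}


def default_template(perturbation_sd: float = 1.0) -> LandmarkTemplate:
    return LandmarkTemplate(
        mean_xy=dict(_TEMPLATE_XY),
        perturbation_sd={k: perturbation_sd for k in _TEMPLATE_XY},
    )


def block_preset(n_subjects: int = 735, seed: int = 0, within_r: float = 0.88,
                 between_r: float = 0.3, unassigned_r: float = 0.1) -> GeneratorConfig:
    """Ten-block preset emulating the observed variable-group structure
    (groups A-1, A-2, B, C, D, E, F, G, H, I over 65 variables)."""
    members = {
        "A-1": (7, 8, 24, 26, 53, 54, 59),
        "A-2": (9, 20, 27, 32, 33),
        "B": (3, 25, 52, 65),
        "C": (4, 16, 17, 23),
        "D": (60, 61, 63, 64),
        "E": (5, 12, 13, 36, 37, 41, 50, 51),
        "F": (39, 42, 43, 48),
        "G": (47, 49, 55),
        "H": (21, 22, 57),
        "I": (11, 18, 28, 46, 58),
    }
    blocks = [
        BlockSpec(label, mem, within_r=within_r, between_r=between_r)
        for label, mem in members.items()
    ]
    return GeneratorConfig(n_subjects=n_subjects, blocks=blocks,
                           unassigned_r=unassigned_r, seed=seed)


def _nearest_psd_correlation(r: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping at 0 followed by correlation re-normalization."""
    vals, vecs = np.linalg.eigh(r)
    vals = np.clip(vals, 0.0, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-15, None))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    return np.clip(fixed, -1.0, 1.0)


def _variable_names(config: GeneratorConfig) -> list[str]:
    if config.n_variables == 65:
        return [d.name for d in load_registry()]
    return [f"V{i:02d}" for i in range(1, config.n_variables + 1)]


def build_target_correlation(config: GeneratorConfig) -> CorrelationMatrix:
    """Target correlation matrix implied by the block design.

    Entries are within_r inside each block, the mean of the two blocks'
    between_r across distinct blocks, and unassigned_r for any pair
    touching an unassigned variable.  The matrix is projected to the
    nearest PSD correlation matrix if necessary; an error is raised if
    that projection moves any entry by more than ``PSD_REPAIR_LIMIT``.
    """
    p = config.n_variables
    r = np.full((p, p), config.unassigned_r, dtype=float)
    block_of = {}
    for b in config.blocks:
        for m in b.member_variables:
            block_of[m] = b
    for i in range(1, p + 1):
        for j in range(1, p + 1):
            if i == j:
                continue
            bi, bj = block_of.get(i), block_of.get(j)
            if bi is not None and bj is not None:
                if bi is bj:
                    r[i - 1, j - 1] = bi.within_r
                else:
                    r[i - 1, j - 1] = (bi.between_r + bj.between_r) / 2.0
    np.fill_diagonal(r, 1.0)

    meta: dict = {"projected": False}
    eigmin = float(np.linalg.eigvalsh(r).min())
    if eigmin < -_PSD_TOL:
        fixed = _nearest_psd_correlation(r)
        move = np.abs(fixed - r)
        if move.max() > PSD_REPAIR_LIMIT:
            iu = np.unravel_index(np.argmax(move), move.shape)
            offenders = sorted(
                {block_of[k + 1].group_label for k in iu if (k + 1) in block_of}
            ) or ["<unassigned background>"]
            raise InfeasibleBlockSpecError(
                f"block spec infeasible: PSD projection moves entry "
                f"({iu[0] + 1}, {iu[1] + 1}) by {move.max():.3f} "
                f"(> {PSD_REPAIR_LIMIT}); offending blocks: {offenders}")
        meta = {"projected": True, "method": "eigenvalue clipping + renormalization",
                "max_entry_move": float(move.max()), "min_eigenvalue_before": eigmin}
        r = fixed
    return CorrelationMatrix(_variable_names(config), r, n_subjects=config.n_subjects,
                             meta=meta)


def _default_units(names: list[str]) -> dict[str, str]:
    try:
        reg = load_registry()
    except Exception:  # pragma: no cover - registry always ships
        return {n: "unknown" for n in names}
    units = {d.name: d.unit for d in reg}
    return {n: units.get(n, "unknown") for n in names}


_UNIT_SD = {"deg": 3.0, "mm": 3.0, "ratio": 0.05, "complex": 4.0, "unknown": 1.0}


def _default_scale(names: list[str]) -> tuple[dict[str, float], dict[str, float]]:
    """Loose location/scale in native units: means from the default landmark
    template, sds by unit class.  No acceptance weight attaches to these."""
    units = _default_units(names)
    sds = {n: _UNIT_SD[units[n]] for n in names}
    means = {n: 0.0 for n in names}
    try:
        from .measure import compute_table

        lm = LandmarkSet({k: np.asarray(v) for k, v in _TEMPLATE_XY.items()},
                         subject_id="template")
        reg = load_registry()
        tbl = compute_table([lm], reg)
        for n in names:
            if n in tbl.data.columns:
                means[n] = float(tbl.data[n].iloc[0])
    except Exception:  # pragma: no cover
        pass
    return means, sds


def _factor(r: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(r)
        return vecs * np.sqrt(np.clip(vals, 0.0, None))


def generate_measurement_table(config: GeneratorConfig) -> MeasurementTable:
    """Sample n_subjects rows from a multivariate normal with the target
    correlation, scaled/shifted to native units.  Bit-identical under a
    fixed seed."""
    target = build_target_correlation(config)
    names = target.variables
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((config.n_subjects, len(names))) @ _factor(target.r).T

    means, sds = _default_scale(names)
    if config.means:
        means.update({k: float(v) for k, v in config.means.items()})
    if config.sds:
        sds.update({k: float(v) for k, v in config.sds.items()})
    x = z * np.array([sds[n] for n in names]) + np.array([means[n] for n in names])

    index = [f"S{i + 1:04d}" for i in range(config.n_subjects)]
    df = pd.DataFrame(x, index=index, columns=names)
    units = _default_units(names)
    numbers = {n: i + 1 for i, n in enumerate(names)}
    return MeasurementTable(df, units=units, numbers=numbers)


def generate_landmark_sets(template: LandmarkTemplate, n: int, seed: int = 0) -> list[LandmarkSet]:
    """n landmark sets = template means + independent Gaussian jitter."""
    rng = np.random.default_rng(seed)
    names = sorted(template.mean_xy)
    out = []
    for i in range(n):
        pts = {}
        for name in names:
            sd = template.perturbation_sd.get(name, 0.0)
            mean = np.asarray(template.mean_xy[name], dtype=float)
            pts[name] = mean + rng.normal(0.0, sd, size=2) if sd > 0 else mean.copy()
        out.append(LandmarkSet(pts, subject_id=f"S{i + 1:04d}"))
    return out
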