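"""Face-centered design (FCD) data model and the embedded pilot dataset.

A two-factor FCD with a replicated center point is the canonical design
here: four factorial corners, four face (axial, alpha = 1) points and one
center, i.e. nine unique coded conditions.  Factor levels live in coded
space [-1, +1] internally; actual units (kPa, degC) appear only at I/O
boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignCondition",
    "FCDDataset",
    "build_fcd",
    "load_dataset",
    "save_dataset",
    "table1",
]


class DesignError(ValueError):
    """Raised for invalid factor specs or malformed design tables."""


@dataclass(frozen=True)
class FactorSpec:
    """An experimental factor with its actual-unit range.

    Coding maps ``low -> -1``, ``(low+high)/2 -> 0`` and ``high -> +1``.
    """

    name: str
    units: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.high > self.low):
            raise DesignError(
                f"factor {self.name!r}: high ({self.high}) must exceed low ({self.low})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, value: float) -> float:
        """Actual units -> coded level."""
        return (value - self.center) / self.half_range

    def decode(self, coded: float) -> float:
        """Coded level -> actual units."""
        return self.center + coded * self.half_range


def code_level(value: float, factor: FactorSpec) -> float:
    """Code an actual-unit value onto the [-1, +1] scale of ``factor``."""
    return factor.code(value)


def decode_level(coded: float, factor: FactorSpec) -> float:
    """Inverse of :func:`code_level`."""
    return factor.decode(coded)


@dataclass
class DesignCondition:
    """One unique factor-level combination with its replicate responses."""

    coded: tuple[float, float]
    actual: tuple[float, float]
    replicate_responses: dict[str, list[float]] = field(default_factory=dict)
    is_center: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        if not self.replicate_responses:
            return 0
        return max(len(v) for v in self.replicate_responses.values())

    def mean(self, response: str) -> float:
        return float(np.mean(self.replicate_responses[response]))


@dataclass
class FCDDataset:
    """A face-centered design: two factors, unique conditions, replicates."""

    factors: tuple[FactorSpec, FactorSpec]
    conditions: list[DesignCondition]
    response_names: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return sum(c.n_replicates for c in self.conditions)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def condition_at(self, coded: tuple[float, float]) -> DesignCondition:
        for c in self.conditions:
            if np.allclose(c.coded, coded):
                return c
        raise KeyError(f"no condition at coded point {coded}")

    def samples(self, response: str) -> tuple[np.ndarray, np.ndarray]:
        """All individual samples for one response.

        Returns ``(X, y)`` where ``X`` is ``(n, 2)`` coded levels (one row
        per replicate) and ``y`` the response values.
        """
        if response not in self.response_names:
            raise KeyError(f"unknown response {response!r}")
        pts, ys = [], []
        for c in self.conditions:
            for v in c.replicate_responses.get(response, []):
                pts.append(c.coded)
                ys.append(v)
        return np.asarray(pts, dtype=float), np.asarray(ys, dtype=float)

    def validate(self, strict_fcd: bool = True) -> list[str]:
        """Invariant check; returns a list of human-readable problems."""
        problems: list[str] = []
        for i, c in enumerate(self.conditions):
            for k, (cv, av) in enumerate(zip(c.coded, c.actual)):
                expect = self.factors[k].code(av)
                if abs(expect - cv) > 1e-9:
                    problems.append(
                        f"condition {i}: coded[{k}]={cv} inconsistent with "
                        f"actual {av} {self.factors[k].units} (expect {expect:.6g})"
                    )
            if c.n_replicates < 1:
                problems.append(f"condition {i}: no replicates")
            for r in self.response_names:
                vals = c.replicate_responses.get(r, [])
                if any(not np.isfinite(v) for v in vals):
                    problems.append(f"condition {i}: non-finite value in {r!r}")
        coded_set = {tuple(np.round(c.coded, 9)) for c in self.conditions}
        if len(coded_set) != len(self.conditions):
            problems.append("duplicate coded conditions")
        if strict_fcd and len(self.conditions) != 9:
            problems.append(
                f"{len(self.conditions)} unique conditions; a 2-factor FCD has 9"
            )
        return problems

    # ---- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        run = 0
        for c in self.conditions:
            run += 1
            for rep in range(c.n_replicates):
                row = {"run_id": run, "replicate_id": rep + 1}
                for f, a in zip(self.factors, c.actual):
                    row[f.name] = a
                for r in self.response_names:
                    row[r] = c.replicate_responses[r][rep]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "factors": [
                {"name": f.name, "units": f.units, "low": f.low, "high": f.high}
                for f in self.factors
            ],
            "response_names": list(self.response_names),
            "conditions": [
                {
                    "coded": list(c.coded),
                    "actual": list(c.actual),
                    "replicates": c.replicate_responses,
                    "is_center": c.is_center,
                    "metadata": c.metadata,
                }
                for c in self.conditions
            ],
            "metadata": self.metadata,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "FCDDataset":
        factors = tuple(FactorSpec(**f) for f in d["factors"])
        conditions = [
            DesignCondition(
                coded=tuple(c["coded"]),
                actual=tuple(c["actual"]),
                replicate_responses={k: list(v) for k, v in c["replicates"].items()},
                is_center=c.get("is_center", False),
                metadata=c.get("metadata", {}),
            )
            for c in d["conditions"]
        ]
        return cls(
            factors=factors,  # type: ignore[arg-type]
            conditions=conditions,
            response_names=list(d["response_names"]),
            metadata=d.get("metadata", {}),
        )

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "FCDDataset":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


# ---- construction ------------------------------------------------------

_FCD_CODED = [
    (-1.0, -1.0),
    (+1.0, -1.0),
    (-1.0, +1.0),
    (+1.0, +1.0),
    (-1.0, 0.0),
    (+1.0, 0.0),
    (0.0, -1.0),
    (0.0, +1.0),
    (0.0, 0.0),
]


def build_fcd(
    factors: tuple[FactorSpec, FactorSpec],
    response_names: list[str] | None = None,
    replicates: tuple[int, int] = (3, 5),
) -> FCDDataset:
    """Skeleton 2-factor FCD: 9 unique conditions, replicate slots planned.

    ``replicates`` gives (non-center, center) replicate counts; the default
    (3, 5) plan yields 4*3 + 4*3 + 5 = 29 sample slots over 13 experiments.
    """
    if len(factors) != 2:
        raise DesignError("a face-centered design here takes exactly two factors")
    conditions = []
    for coded in _FCD_CODED:
        is_center = coded == (0.0, 0.0)
        n_rep = replicates[1] if is_center else replicates[0]
        conditions.append(
            DesignCondition(
                coded=coded,
                actual=tuple(f.decode(c) for f, c in zip(factors, coded)),
                replicate_responses={},
                is_center=is_center,
                metadata={"planned_replicates": n_rep},
            )
        )
    return FCDDataset(
        factors=factors,
        conditions=conditions,
        response_names=list(response_names or []),
    )


def save_dataset(dataset: FCDDataset, path) -> None:
    """Write the long-format CSV design table (one row per replicate)."""
    dataset.to_frame().to_csv(path, index=False)


def load_dataset(
    path,
    factors: tuple[FactorSpec, FactorSpec],
    response_names: list[str],
) -> FCDDataset:
    """Read a long-format CSV design table.

    Required columns: ``run_id``, ``replicate_id``, one column per factor
    (actual units, named as in ``factors``) and one per response.
    Replicates are grouped by identical actual factor levels; factor
    levels must be constant within a ``run_id``.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise DesignError(f"{path}: empty design table")
    needed = ["run_id", "replicate_id"] + [f.name for f in factors] + list(response_names)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DesignError(f"{path}: missing column(s) {missing}")
    for col in [f.name for f in factors] + list(response_names):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise DesignError(f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = pd.to_numeric(df[col])
    fnames = [f.name for f in factors]
    for run_id, grp in df.groupby("run_id"):
        if (grp[fnames].nunique() > 1).any():
            raise DesignError(
                f"{path}: inconsistent factor levels within run_id {run_id}"
            )
    conditions: list[DesignCondition] = []
    for levels, grp in df.groupby(fnames, sort=False):
        actual = tuple(float(v) for v in levels)
        coded = tuple(f.code(a) for f, a in zip(factors, actual))
        conditions.append(
            DesignCondition(
                coded=coded,
                actual=actual,
                replicate_responses={
                    r: [float(v) for v in grp[r]] for r in response_names
                },
                is_center=all(abs(c) < 1e-9 for c in coded),
            )
        )
    return FCDDataset(
        factors=factors, conditions=conditions, response_names=list(response_names)
    )


# ---- embedded pilot dataset --------------------------------------------

PRESSURE = FactorSpec(name="pressure", units="kPa", low=50.0, high=200.0)
TEMPERATURE = FactorSpec(name="temperature", units="degC", low=20.0, high=40.0)

FLUX = "flux"
FOULING_INDEX = "fouling_index"

# Non-center conditions: (coded, mean flux, SD flux, mean FI, SD FI).
# Individual replicate values were not published; each condition carries its
# mean replicated threefold, which preserves every condition sum and hence
# every least-squares fit on the full sample set.  SDs are metadata only.
_T1_NONCENTER = [
    ((-1.0, -1.0), 324.35, 6.97, 84.55, 1.35),
    ((+1.0, -1.0), 302.26, 9.45, 93.28, 0.86),
    ((-1.0, +1.0), 471.78, 11.53, 82.92, 1.04),
    ((+1.0, +1.0), 527.11, 14.07, 94.66, 1.21),
    ((-1.0, 0.0), 608.78, 16.77, 78.21, 0.67),
    ((+1.0, 0.0), 498.88, 3.98, 92.61, 0.66),
    ((0.0, -1.0), 469.00, 12.34, 88.98, 1.08),
    ((0.0, +1.0), 575.90, 3.09, 89.78, 0.80),
]
_T1_CENTER_FLUX = [656.47, 678.96, 639.43, 645.50, 660.21]
_T1_CENTER_FI = [84.10, 86.42, 84.06, 85.56, 85.80]


def table1() -> FCDDataset:
    """The embedded 29-sample pilot design (pressure 50-200 kPa, 20-40 degC).

    Eight non-center conditions store the published condition mean with
    multiplicity three; the five individual center-point replicates are
    stored as measured.  Responses: permeate flux (L h^-1 m^-2) and
    fouling index (%).
    """
    conditions = []
    for coded, fmean, fsd, fim, fisd in _T1_NONCENTER:
        conditions.append(
            DesignCondition(
                coded=coded,
                actual=(PRESSURE.decode(coded[0]), TEMPERATURE.decode(coded[1])),
                replicate_responses={
                    FLUX: [fmean] * 3,
                    FOULING_INDEX: [fim] * 3,
                },
                is_center=False,
                metadata={"sd": {FLUX: fsd, FOULING_INDEX: fisd}},
            )
        )
    conditions.append(
        DesignCondition(
            coded=(0.0, 0.0),
            actual=(PRESSURE.center, TEMPERATURE.center),
            replicate_responses={
                FLUX: list(_T1_CENTER_FLUX),
                FOULING_INDEX: list(_T1_CENTER_FI),
            },
            is_center=True,
        )
    )
    return FCDDataset(
        factors=(PRESSURE, TEMPERATURE),
        conditions=conditions,
        response_names=[FLUX, FOULING_INDEX],
        metadata={"source": "embedded pilot design, single homogenized batch"},
    )
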