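"""Core data types for mouse clinical trials (MCTs).

An MCT follows a panel of mouse tumor models (PDX/CDX/syngeneic); each model
contributes several mice split between a vehicle arm and a treatment arm, and
every mouse carries a longitudinal series of caliper tumor-volume measurements.
The types here are deliberately thin: a :class:`GrowthCurve` is one mouse's
(day, volume) series, an :class:`MCTDataset` is the clustered collection plus
model-level covariates and an optional expression matrix, and a
:class:`ResponseCall` records one categorical response classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

ARMS = ("vehicle", "treatment")

#: Category sets of the four classification methods, ordered from best to worst.
CATEGORY_SETS = {
    "recist": ("CR", "PR", "SD", "PD"),
    "cat3": ("OR", "SD", "PD"),
    "mrecist": ("CR", "PR", "SD", "PD"),
    "cat5": ("MCR", "CR", "PR", "SD", "PD"),
}

#: Objective-response category set per method.
OBJECTIVE_SETS = {
    "recist": frozenset({"CR", "PR"}),
    "mrecist": frozenset({"CR", "PR"}),
    "cat3": frozenset({"OR"}),
    "cat5": frozenset({"MCR", "CR", "PR"}),
}


@dataclass(frozen=True)
class GrowthCurve:
    """One mouse's tumor-volume series.

    Day 0 is treatment initiation; volumes are in mm^3.  A volume of exactly 0
    encodes "no measurable tumor mass" (used by the CR/MCR definitions).
    """

    mouse_id: str
    model_id: str
    arm: str
    days: tuple
    volumes: tuple

    def __post_init__(self):
        days = tuple(int(d) for d in self.days)
        volumes = tuple(float(v) for v in self.volumes)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "volumes", volumes)
        if self.arm not in ARMS:
            raise ValidationError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if len(days) != len(volumes):
            raise ValidationError("days and volumes must have equal length")
        if len(days) == 0:
            raise ValidationError("a growth curve needs at least one measurement")
        if any(d < 0 for d in days):
            raise ValidationError("days must be non-negative")
        if days[0] != 0:
            raise ValidationError("the first measurement must be at day 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(f"days must be strictly increasing for mouse {self.mouse_id}")
        if any(v < 0 for v in volumes):
            raise ValidationError(f"negative volume for mouse {self.mouse_id}")

    @property
    def baseline(self) -> float:
        """Tumor volume at treatment initiation (day 0), mm^3."""
        return self.volumes[0]

    @property
    def last_day(self) -> int:
        return self.days[-1]

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class MCTDataset:
    """Clustered collection of growth curves plus model-level annotations.

    ``model_covariates`` maps model_id to a dict holding at least
    ``cancer_type``; ``expression`` is an optional gene x model DataFrame
    (log2-scale values by convention, not enforced).
    """

    curves: list
    model_covariates: dict
    expression: Optional[pd.DataFrame] = None

    def __post_init__(self):
        seen = set()
        for c in self.curves:
            if c.model_id not in self.model_covariates:
                raise ValidationError(
                    f"model {c.model_id!r} has curves but no covariate row"
                )
            key = (c.model_id, c.mouse_id)
            if key in seen:
                raise ValidationError(f"duplicate mouse {key}")
            seen.add(key)
        if self.expression is not None:
            missing = [m for m in self.model_ids if m not in self.expression.columns]
            if missing:
                raise ValidationError(f"expression matrix missing models: {missing}")

    @property
    def model_ids(self) -> list:
        out = []
        for c in self.curves:
            if c.model_id not in out:
                out.append(c.model_id)
        return out

    @property
    def n_mice(self) -> int:
        return len(self.curves)

    def curves_for(self, model_id: str, arm: Optional[str] = None) -> list:
        """Curves of one model, optionally restricted to an arm."""
        return [
            c
            for c in self.curves
            if c.model_id == model_id and (arm is None or c.arm == arm)
        ]

    def to_long(self) -> pd.DataFrame:
        """Long-format measurement table (one row per mouse per day)."""
        rows = []
        for c in self.curves:
            for d, v in zip(c.days, c.volumes):
                rows.append((c.model_id, c.mouse_id, c.arm, d, v))
        return pd.DataFrame(
            rows, columns=["model_id", "mouse_id", "arm", "day", "volume_mm3"]
        )

    def __eq__(self, other):
        if not isinstance(other, MCTDataset):
            return NotImplemented
        if sorted(self.curves, key=lambda c: (c.model_id, c.mouse_id)) != sorted(
            other.curves, key=lambda c: (c.model_id, c.mouse_id)
        ):
            return False
        if self.model_covariates != other.model_covariates:
            return False
        if (self.expression is None) != (other.expression is None):
            return False
        if self.expression is not None:
            a = self.expression.sort_index().sort_index(axis=1)
            b = other.expression.sort_index().sort_index(axis=1)
            if a.shape != b.shape or not (a.index == b.index).all() or not (
                a.columns == b.columns
            ).all():
                return False
            if not np.allclose(a.to_numpy(), b.to_numpy(), rtol=0, atol=1e-12):
                return False
        return True


@dataclass(frozen=True)
class ResponseCall:
    """A categorical response call for one mouse under one method."""

    method: str
    category: str
    mouse_id: str
    model_id: str

    def __post_init__(self):
        if self.method not in CATEGORY_SETS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.category not in CATEGORY_SETS[self.method]:
            raise ValidationError(
                f"category {self.category!r} not valid for method {self.method!r}"
            )
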