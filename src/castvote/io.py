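"""Scenario specification, profile generators and tabular report writers.

The interchange formats are tidy CSV (with ``#``-prefixed JSON metadata
comment lines) and JSON; scenario files are YAML mapping 1:1 onto
:class:`ScenarioSpec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import yaml

from .chain import DEFAULT_TOL, AbilityProfile

_COMMANDS = (
    "run",
    "simulate",
    "exact",
    "sweep",
    "three-person",
    "expert",
    "effective-n",
)


def generate_profile(kind: str, **params) -> AbilityProfile:
    """Build one of the three stock ability-profile families.

    ``equal``
        Everyone shares ability ``p``; parameters ``p``, ``n``.
    ``one_expert``
        Ability ``q > p`` at position ``expert_order`` among equals;
        parameters ``p``, ``q``, ``expert_order``, ``n``.
    ``random_distinct``
        ``n`` abilities drawn uniformly from ``(low, high)`` by rejection
        until all pairwise gaps reach ``min_gap``; parameters ``n``,
        ``seed``, and optionally ``low`` (0.55), ``high`` (0.95),
        ``min_gap`` (0.01).  Deterministic given ``seed``.
    """
    if kind == "equal":
        p, n = params.pop("p"), params.pop("n")
        _reject_extra(kind, params)
        return AbilityProfile((p,) * int(n))
    if kind == "one_expert":
        p, q = params.pop("p"), params.pop("q")
        order, n = int(params.pop("expert_order")), int(params.pop("n"))
        _reject_extra(kind, params)
        if not q > p:
            raise ValueError(f"expert ability q must exceed p; got q={q!r}, p={p!r}")
        if not 1 <= order <= n:
            raise ValueError(f"expert_order must lie in 1..{n}, got {order}")
        abilities = [p] * n
        abilities[order - 1] = q
        return AbilityProfile(tuple(abilities))
    if kind == "random_distinct":
        n, seed = int(params.pop("n")), params.pop("seed")
        low = params.pop("low", 0.55)
        high = params.pop("high", 0.95)
        min_gap = params.pop("min_gap", 0.01)
        _reject_extra(kind, params)
        if not 0.5 < low < high < 1.0:
            raise ValueError(f"need 0.5 < low < high < 1; got {low!r}, {high!r}")
        rng = np.random.default_rng(seed)
        for _ in range(10_000):
            draw = np.sort(rng.uniform(low, high, size=n))
            if n == 1 or np.min(np.diff(draw)) >= min_gap:
                rng.shuffle(draw)
                return AbilityProfile(tuple(draw.tolist()), strict_distinct=True)
        raise ValueError(
            f"could not draw {n} abilities with pairwise gap >= {min_gap} "
            f"from ({low}, {high})"
        )
    raise ValueError(
        f"unknown profile kind {kind!r}; expected equal, one_expert or "
        "random_distinct"
    )


def _reject_extra(kind: str, params: dict) -> None:
    if params:
        raise TypeError(f"unexpected parameters for {kind!r}: {sorted(params)}")


@dataclass
class ScenarioSpec:
    """Declarative description of one run or sweep.

    ``profile`` is either ``{"abilities": [...]}`` or
    ``{"kind": ..., <kind parameters>}``; remaining fields mirror the CLI
    flags of ``command``.
    """

    command: str
    profile: Optional[dict] = None
    runs: int = 10_000
    seed: int = 0
    tol: float = DEFAULT_TOL
    grid: dict = field(default_factory=dict)
    out: Optional[str] = None
    fmt: str = "csv"

    def __post_init__(self) -> None:
        if self.command not in _COMMANDS:
            raise ValueError(
                f"unknown command {self.command!r}; expected one of {_COMMANDS}"
            )
        if self.fmt not in ("csv", "json"):
            raise ValueError(f"format must be 'csv' or 'json', got {self.fmt!r}")
        if self.profile is not None:
            self.resolve_profile()  # validate eagerly

    def resolve_profile(self) -> AbilityProfile:
        if self.profile is None:
            raise ValueError(f"command {self.command!r} needs a profile")
        spec = dict(self.profile)
        if "abilities" in spec:
            abilities = spec.pop("abilities")
            strict = spec.pop("strict_distinct", False)
            _reject_extra("inline profile", spec)
            return AbilityProfile(tuple(abilities), strict_distinct=strict)
        kind = spec.pop("kind")
        return generate_profile(kind, **spec)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ScenarioSpec":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict):
            raise ValueError(f"scenario file {path} must hold a mapping")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "profile": self.profile,
            "runs": self.runs,
            "seed": self.seed,
            "tol": self.tol,
            "grid": self.grid,
            "out": self.out,
            "fmt": self.fmt,
        }


def load_profile(path: Union[str, Path]) -> AbilityProfile:
    """Read an ability profile from a YAML file.

    Accepts ``{"abilities": [...]}`` (optionally with ``strict_distinct``)
    or ``{"kind": ..., <parameters>}``.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ValueError(f"profile file {path} must hold a mapping")
    if "abilities" in raw:
        return AbilityProfile(
            tuple(raw["abilities"]), strict_distinct=raw.get("strict_distinct", False)
        )
    spec = dict(raw)
    kind = spec.pop("kind")
    return generate_profile(kind, **spec)


def write_report(
    report: Any,
    path: Union[str, Path],
    fmt: str = "csv",
    metadata: Optional[dict] = None,
) -> None:
    """Write a result object to CSV or JSON with embedded metadata.

    ``report`` may be anything with a ``to_frame()`` method, a pandas
    DataFrame, or (for JSON) anything with ``to_dict()`` / a plain dict.
    CSV files carry metadata as leading ``# key: value`` comment lines and
    print floats at 12 significant digits with a deterministic column
    order; JSON files round-trip exactly through :func:`json.load`.
    """
    import pandas as pd

    path = Path(path)
    metadata = dict(metadata or {})
    if fmt == "csv":
        frame = report if isinstance(report, pd.DataFrame) else report.to_frame()
        with open(path, "w") as handle:
            for key, value in metadata.items():
                handle.write(f"# {key}: {json.dumps(value)}\n")
            frame.to_csv(handle, index=False, float_format="%.12g")
        return
    if fmt == "json":
        if isinstance(report, pd.DataFrame):
            data = report.to_dict(orient="records")
        elif hasattr(report, "to_dict"):
            data = report.to_dict()
        elif hasattr(report, "to_frame"):
            data = report.to_frame().to_dict(orient="records")
        else:
            data = report
        with open(path, "w") as handle:
            json.dump({"metadata": metadata, "data": data}, handle, indent=1)
            handle.write("\n")
        return
    raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")


def read_csv_report(path: Union[str, Path]):
    """Read back a CSV report written by :func:`write_report` (drops metadata)."""
    import pandas as pd

    return pd.read_csv(path, comment="#")
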