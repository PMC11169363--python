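"""Parameter hierarchy: fixed / globally fitted / per-subject local constants.

Every model constant carries exactly one provenance tag:

``fixed-data``
    set directly from subject-level measurements (initial blood volume,
    baseline blood pressure, baseline cell counts).
``fixed-literature``
    rates taken as fixed biological constants (cell death rates, cytokine
    half-lives, product concentrations).
``global-fit``
    shared across all subjects and exposed to the calibration machinery.
``local-fit``
    per-subject constants capturing inter-individual variability.

The reference file shipped with the package (``data/default_params.yaml``)
marks exactly 33 keys as fit-eligible (global-fit or local-fit).  Default
values are non-canonical: they were chosen so the model sits at a healthy
steady state and produces physiologically plausible trajectories, not taken
from any fitted cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from types import SimpleNamespace
from typing import Dict, Iterable, Mapping, Optional, Tuple

import yaml

PROVENANCE_TAGS = ("fixed-data", "fixed-literature", "global-fit", "local-fit")


@dataclass(frozen=True)
class NOParams:
    """Nitric-oxide pathway globals, re-tunable in the human calibration stage.

    Rates of NO production by active monocytes, active epithelial cells and
    iNOS, plus the strength of the NO effect on blood pressure.
    """

    K_no_ma: float
    K_no_ep: float
    K_no_inos: float
    K_bloodpressure_no: float

    KEYS = ("no.K_no_ma", "no.K_no_ep", "no.K_no_inos", "no.K_bloodpressure_no")

    def __post_init__(self) -> None:
        for name in ("K_no_ma", "K_no_ep", "K_no_inos", "K_bloodpressure_no"):
            if getattr(self, name) < 0:
                raise ValueError(f"NOParams.{name} must be >= 0")


class ParameterSet:
    """Flat, namespaced parameter table with per-key provenance.

    Keys are ``module.parameter`` strings (e.g. ``coag.k_clot``).  The
    :meth:`namespace` view exposes each key's suffix as an attribute for
    fast access inside the ODE right-hand side.
    """

    def __init__(
        self,
        values: Mapping[str, float],
        provenance: Mapping[str, str],
        local_ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
    ) -> None:
        self.values: Dict[str, float] = dict(values)
        self.provenance: Dict[str, str] = dict(provenance)
        self.local_ranges: Dict[str, Tuple[float, float]] = {
            k: (float(v[0]), float(v[1])) for k, v in (local_ranges or {}).items()
        }
        self.validate()

    # -- construction ---------------------------------------------------
    @classmethod
    def default(cls) -> "ParameterSet":
        """Load the reference parameter file shipped with the package."""
        text = resources.files("hemotwin.data").joinpath("default_params.yaml").read_text()
        return cls._from_mapping(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls._from_mapping(yaml.safe_load(fh))

    @classmethod
    def _from_mapping(cls, doc: Mapping) -> "ParameterSet":
        params = doc["parameters"]
        values = {k: float(v["value"]) for k, v in params.items()}
        provenance = {k: str(v["provenance"]) for k, v in params.items()}
        ranges = doc.get("local_ranges", {})
        return cls(values, provenance, ranges)

    def to_yaml(self, path) -> None:
        doc = {
            "parameters": {
                k: {"value": float(self.values[k]), "provenance": self.provenance[k]}
                for k in sorted(self.values)
            },
            "local_ranges": {k: list(v) for k, v in sorted(self.local_ranges.items())},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        for key, value in self.values.items():
            if not math.isfinite(value):
                raise ValueError(f"parameter {key} is not finite: {value}")
            if value < 0:
                raise ValueError(f"parameter {key} is negative: {value}")
            tag = self.provenance.get(key)
            if tag not in PROVENANCE_TAGS:
                raise ValueError(f"parameter {key} has invalid provenance tag {tag!r}")
        for key, (lo, hi) in self.local_ranges.items():
            if not (lo < hi):
                raise ValueError(f"degenerate local range for {key}: [{lo}, {hi}]")

    # -- access ---------------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def keys(self) -> Iterable[str]:
        return self.values.keys()

    def tagged(self, tag: str) -> Dict[str, float]:
        return {k: v for k, v in self.values.items() if self.provenance[k] == tag}

    def fit_eligible_keys(self) -> Tuple[str, ...]:
        """Keys open to calibration (global-fit or local-fit), sorted."""
        return tuple(
            sorted(k for k, t in self.provenance.items() if t in ("global-fit", "local-fit"))
        )

    def global_fit_keys(self) -> Tuple[str, ...]:
        return tuple(sorted(k for k, t in self.provenance.items() if t == "global-fit"))

    def local_fit_keys(self) -> Tuple[str, ...]:
        return tuple(sorted(k for k, t in self.provenance.items() if t == "local-fit"))

    def no_params(self) -> NOParams:
        return NOParams(*(self.values[k] for k in NOParams.KEYS))

    def with_updates(self, updates: Mapping[str, float]) -> "ParameterSet":
        """Copy with some values replaced; unknown keys are rejected."""
        unknown = set(updates) - set(self.values)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        values = dict(self.values)
        values.update({k: float(v) for k, v in updates.items()})
        return ParameterSet(values, self.provenance, self.local_ranges)

    def namespace(self, overrides: Optional[Mapping[str, float]] = None) -> SimpleNamespace:
        """Attribute view keyed by the suffix after ``module.`` (must be unique)."""
        merged = dict(self.values)
        if overrides:
            merged.update(overrides)
        ns: Dict[str, float] = {}
        for key, value in merged.items():
            suffix = key.split(".", 1)[1]
            if suffix in ns:
                raise ValueError(f"ambiguous parameter suffix {suffix!r}")
            ns[suffix] = value
        return SimpleNamespace(**ns)
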