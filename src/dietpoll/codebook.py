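"""Variable codebook: names, ordered category labels and integer codes.

Every categorical variable used anywhere in the pipeline (profiling
covariates, 24-h recall item flags, outcomes) is integer coded with
consecutive codes starting at 0.  The codebook is the single source of
truth for code/label mappings and variable roles, and is what profile
enumeration and CSV validation check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

ROLES = ("covariate", "item-flag", "outcome", "weight", "meta")


@dataclass(frozen=True)
class Variable:
    """One coded variable: ordered labels, role, consecutive codes from 0."""

    name: str
    labels: tuple[str, ...]
    role: str = "covariate"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for variable {self.name!r}")
        if len(self.labels) == 0:
            raise ValueError(f"variable {self.name!r} has no categories")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate labels in variable {self.name!r}")

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    @property
    def codes(self) -> range:
        return range(len(self.labels))

    def code_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"label {label!r} not in codebook for variable {self.name!r}"
            ) from None

    def label_of(self, code: int) -> str:
        if not 0 <= int(code) < len(self.labels):
            raise KeyError(f"code {code} out of range for variable {self.name!r}")
        return self.labels[int(code)]


@dataclass
class VariableCodebook:
    """Ordered collection of :class:`Variable` definitions."""

    variables: dict[str, Variable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, var in self.variables.items():
            if name != var.name:
                raise ValueError(f"key {name!r} does not match variable name {var.name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    def __getitem__(self, name: str) -> Variable:
        return self.variables[name]

    def add(self, var: Variable) -> None:
        self.variables[var.name] = var

    def names(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.variables)
        return [n for n, v in self.variables.items() if v.role == role]

    @property
    def covariates(self) -> list[str]:
        return self.names("covariate")

    @property
    def item_flags(self) -> list[str]:
        return self.names("item-flag")

    def valid_code(self, name: str, code: int) -> bool:
        return name in self.variables and 0 <= int(code) < self.variables[name].n_categories

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, spec: Mapping[str, Mapping]) -> "VariableCodebook":
        """Build from ``{name: {labels: [...], role: ...}}`` mappings."""
        cb = cls()
        for name, entry in spec.items():
            labels = tuple(str(x) for x in entry["labels"])
            role = str(entry.get("role", "covariate"))
            cb.add(Variable(name=name, labels=labels, role=role))
        return cb

    def to_dict(self) -> dict:
        return {
            name: {"labels": list(v.labels), "role": v.role}
            for name, v in self.variables.items()
        }

    @classmethod
    def from_yaml(cls, path) -> "VariableCodebook":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        if not isinstance(spec, Mapping):
            raise ValueError(f"codebook file {path} is not a mapping")
        return cls.from_dict(spec)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_variables(cls, variables: Iterable[Variable]) -> "VariableCodebook":
        cb = cls()
        for v in variables:
            cb.add(v)
        return cb
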