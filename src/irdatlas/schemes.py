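"""Tissue-group and retinal cell-group schemes.

The bulk scheme maps 53 FANTOM5/HPA tissue sample names onto 13 groups with
"retina" as target; the single-cell scheme collapses 53 cell/cell-subtype
columns into 19 major groups and defines 5 broader groups (unions of major
groups), giving 24 candidate specificity categories. Both ship as editable
YAML package data and can be replaced by the user.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml


def _load_builtin(name: str) -> dict:
    text = resources.files("irdatlas").joinpath("data", name).read_text(encoding="utf-8")
    return yaml.safe_load(text)


@dataclasses.dataclass(frozen=True)
class TissueGroupScheme:
    """13-group aggregation scheme for the bulk tissue expression table."""

    group_names: tuple[str, ...]
    membership: dict[str, str]  # sample name -> group name
    target_group: str = "retina"

    def __post_init__(self):
        if len(set(self.group_names)) != len(self.group_names):
            raise ValueError("duplicate group names")
        if self.target_group not in self.group_names:
            raise ValueError(f"target group {self.target_group!r} not among groups")
        orphan = set(self.membership.values()) - set(self.group_names)
        if orphan:
            raise ValueError(f"membership references unknown group(s) {sorted(orphan)}")

    @property
    def sample_names(self) -> list[str]:
        return list(self.membership)

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.membership.items() if g == group]

    @classmethod
    def from_dict(cls, data: dict) -> "TissueGroupScheme":
        groups = data["groups"]
        membership = {s: g for g, samples in groups.items() for s in samples}
        n_listed = sum(len(s) for s in groups.values())
        if len(membership) != n_listed:
            raise ValueError("a sample name is listed under more than one group")
        return cls(
            group_names=tuple(groups),
            membership=membership,
            target_group=data.get("target_group", "retina"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TissueGroupScheme":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def builtin(cls) -> "TissueGroupScheme":
        return cls.from_dict(_load_builtin("fantom5_tissues.yaml"))


@dataclasses.dataclass(frozen=True)
class CellGroupScheme:
    """53-subtype / 19-major-group / 5-broader-group retinal cell scheme."""

    major_groups: tuple[str, ...]
    subtype_membership: dict[str, str]  # subtype column -> major group
    broader_groups: dict[str, tuple[str, ...]]  # broader name -> member majors

    def __post_init__(self):
        orphan = set(self.subtype_membership.values()) - set(self.major_groups)
        if orphan:
            raise ValueError(f"subtypes reference unknown major group(s) {sorted(orphan)}")
        for name, members in self.broader_groups.items():
            if name in self.major_groups:
                raise ValueError(f"broader group {name!r} shadows a major group")
            bad = set(members) - set(self.major_groups)
            if bad:
                raise ValueError(f"broader group {name!r} has unknown member(s) {sorted(bad)}")

    @property
    def subtype_names(self) -> list[str]:
        return list(self.subtype_membership)

    @property
    def candidate_categories(self) -> tuple[str, ...]:
        """The 19 major + 5 broader candidate specificity categories."""
        return self.major_groups + tuple(self.broader_groups)

    def members_of(self, candidate: str) -> tuple[str, ...]:
        """Major groups covered by a candidate category (itself, if major)."""
        if candidate in self.broader_groups:
            return self.broader_groups[candidate]
        if candidate in self.major_groups:
            return (candidate,)
        raise KeyError(f"unknown candidate category {candidate!r}")

    def subtypes_of(self, major: str) -> list[str]:
        return [s for s, g in self.subtype_membership.items() if g == major]

    @classmethod
    def from_dict(cls, data: dict) -> "CellGroupScheme":
        majors = data["major_groups"]
        membership = {s: g for g, subs in majors.items() for s in subs}
        n_listed = sum(len(s) for s in majors.values())
        if len(membership) != n_listed:
            raise ValueError("a subtype name is listed under more than one major group")
        return cls(
            major_groups=tuple(majors),
            subtype_membership=membership,
            broader_groups={k: tuple(v) for k, v in data["broader_groups"].items()},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CellGroupScheme":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def builtin(cls) -> "CellGroupScheme":
        return cls.from_dict(_load_builtin("retina_cell_types.yaml"))
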