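"""Experimental framework for an EMA study.

An EMA study is described by its test *phases*, one or more nominal
*situation dimensions* (each with an ordered list of categories), a set of
rated *attributes* (each with an ordered ordinal response scale), and the
participant *groups*.  The joint situation categories are the Cartesian
product of the dimension categories, enumerated row-major in the declared
dimension order; their count is ``K``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["EmaFrame", "EmaRecord", "EmaDataset", "ConfigurationError", "build_frame"]


class ConfigurationError(ValueError):
    """Raised for an invalid study configuration."""


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ConfigurationError(f"duplicate {what} label(s): {dupes}")
    return labels


@dataclass(frozen=True)
class EmaFrame:
    """Immutable description of the study design.

    Parameters
    ----------
    phases
        Ordered test-phase labels, length ``T >= 1``.
    situation_dims
        Ordered mapping ``dimension name -> ordered category labels``;
        every dimension needs at least one category.
    attributes
        Ordered mapping ``attribute name -> ordered response labels``;
        every attribute needs at least two response categories.
    groups
        Participant-group labels (defaults to a single group ``"group"``).
    """

    phases: tuple[str, ...]
    situation_dims: Mapping[str, tuple[str, ...]]
    attributes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    groups: tuple[str, ...] = ("group",)

    def __init__(
        self,
        phases: Sequence[str],
        situation_dims: Mapping[str, Sequence[str]],
        attributes: Mapping[str, Sequence[str]] | None = None,
        groups: Sequence[str] = ("group",),
    ):
        phases = tuple(_check_unique(list(phases), "phase"))
        if not phases:
            raise ConfigurationError("at least one phase is required")
        if not situation_dims:
            raise ConfigurationError("at least one situation dimension is required")
        dims = {}
        for name, cats in situation_dims.items():
            cats = tuple(_check_unique(list(cats), f"category (dimension {name!r})"))
            if not cats:
                raise ConfigurationError(f"situation dimension {name!r} has no categories")
            dims[str(name)] = cats
        _check_unique(list(dims), "situation dimension")
        attrs = {}
        for name, scale in (attributes or {}).items():
            scale = tuple(_check_unique(list(scale), f"response (attribute {name!r})"))
            if len(scale) < 2:
                raise ConfigurationError(
                    f"attribute {name!r} needs >= 2 response categories, got {len(scale)}"
                )
            attrs[str(name)] = scale
        _check_unique(list(attrs), "attribute")
        groups = tuple(_check_unique(list(groups), "group"))
        if not groups:
            raise ConfigurationError("at least one group is required")
        object.__setattr__(self, "phases", phases)
        object.__setattr__(self, "situation_dims", dims)
        object.__setattr__(self, "attributes", attrs)
        object.__setattr__(self, "groups", groups)

    # -- dimension bookkeeping ------------------------------------------------

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def dim_sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.situation_dims.values())

    @property
    def n_cells(self) -> int:
        """Joint situation-category count K = product of dimension sizes."""
        return int(np.prod(self.dim_sizes, dtype=np.int64))

    @property
    def attribute_levels(self) -> dict[str, int]:
        return {a: len(s) for a, s in self.attributes.items()}

    def cell_labels(self) -> list[tuple[str, ...]]:
        """Joint situation cells, row-major over the declared dimension order."""
        return list(itertools.product(*self.situation_dims.values()))

    def cell_names(self, sep: str = "/") -> list[str]:
        return [sep.join(c) for c in self.cell_labels()]

    def cell_index(self, situation: Mapping[str, str] | Sequence[str]) -> int:
        """Row-major index of a joint situation cell.

        ``situation`` is either a mapping ``dimension -> category`` or a
        sequence of categories in declared dimension order.
        """
        if isinstance(situation, Mapping):
            cats = [situation[d] for d in self.situation_dims]
        else:
            cats = list(situation)
        if len(cats) != len(self.situation_dims):
            raise ValueError("situation does not name every dimension")
        k = 0
        for (dim, labels), cat in zip(self.situation_dims.items(), cats):
            try:
                j = labels.index(cat)
            except ValueError:
                raise ValueError(f"unknown category {cat!r} in dimension {dim!r}") from None
            k = k * len(labels) + j
        return k

    def phase_index(self, phase: str) -> int:
        try:
            return self.phases.index(phase)
        except ValueError:
            raise ValueError(f"unknown phase {phase!r}") from None

    # -- (de)serialization ----------------------------------------------------

    def to_config(self) -> dict:
        return {
            "phases": list(self.phases),
            "situation_dims": {d: list(c) for d, c in self.situation_dims.items()},
            "attributes": {a: list(s) for a, s in self.attributes.items()},
            "groups": list(self.groups),
        }

    @classmethod
    def from_config(cls, config: Mapping) -> "EmaFrame":
        try:
            phases = config.get("phases", ["phase1"])
            dims = config["situation_dims"]
        except KeyError as e:
            raise ConfigurationError(f"missing configuration key: {e}") from None
        return cls(
            phases=phases,
            situation_dims=dims,
            attributes=config.get("attributes", {}),
            groups=config.get("groups", ["group"]),
        )


def build_frame(config: Mapping) -> EmaFrame:
    """Build an :class:`EmaFrame` from a structured study description."""
    return EmaFrame.from_config(config)


@dataclass(frozen=True)
class EmaRecord:
    """One validated EMA assessment.

    ``ratings`` maps attribute name to a 1-based ordinal index, or to
    ``None`` when the rating is missing.  A record with all ratings missing
    (situation-only) is valid.
    """

    participant_id: str
    group: str
    phase: str
    situation: tuple[str, ...]
    ratings: Mapping[str, int | None]

    @classmethod
    def validate(
        cls,
        frame: EmaFrame,
        participant_id: str,
        group: str,
        phase: str,
        situation: Mapping[str, str] | Sequence[str],
        ratings: Mapping[str, int | None],
    ) -> "EmaRecord":
        if group not in frame.groups:
            raise ValueError(f"unknown group {group!r}")
        if phase not in frame.phases:
            raise ValueError(f"unknown phase {phase!r}")
        if isinstance(situation, Mapping):
            sit = tuple(situation[d] for d in frame.situation_dims)
        else:
            sit = tuple(situation)
        frame.cell_index(sit)  # raises on unknown category
        clean: dict[str, int | None] = {}
        for a, scale in frame.attributes.items():
            v = ratings.get(a)
            if v is None:
                clean[a] = None
                continue
            v = int(v)
            if not 1 <= v <= len(scale):
                raise ValueError(
                    f"rating {v} outside 1..{len(scale)} for attribute {a!r}"
                )
            clean[a] = v
        return cls(str(participant_id), group, phase, sit, clean)


class EmaDataset:
    """Validated EMA records grouped by participant.

    Parameters
    ----------
    frame
        The study design every record must conform to.
    records
        Iterable of :class:`EmaRecord` (already validated) in any order;
        within-participant order is preserved.
    """

    def __init__(
        self,
        frame: EmaFrame,
        records: Iterable[EmaRecord],
        participant_groups: Mapping[str, str] | None = None,
    ):
        self.frame = frame
        by_pid: dict[str, list[EmaRecord]] = {}
        groups: dict[str, str] = {}
        # declared participants may have zero records (still part of the study)
        for pid, group in (participant_groups or {}).items():
            if group not in frame.groups:
                raise ValueError(f"unknown group {group!r} for participant {pid!r}")
            by_pid.setdefault(str(pid), [])
            groups[str(pid)] = group
        for rec in records:
            by_pid.setdefault(rec.participant_id, []).append(rec)
            prev = groups.setdefault(rec.participant_id, rec.group)
            if prev != rec.group:
                raise ValueError(
                    f"participant {rec.participant_id!r} assigned to two groups "
                    f"({prev!r}, {rec.group!r})"
                )
        self._records = by_pid
        self._groups = groups

    @property
    def participants(self) -> list[str]:
        return list(self._records)

    @property
    def n_participants(self) -> int:
        return len(self._records)

    def group_of(self, participant_id: str) -> str:
        return self._groups[participant_id]

    def records_of(self, participant_id: str) -> list[EmaRecord]:
        return list(self._records[participant_id])

    def record_counts(self) -> dict[str, int]:
        return {p: len(r) for p, r in self._records.items()}

    @property
    def n_records(self) -> int:
        return sum(len(r) for r in self._records.values())

    def participants_in_group(self, group: str) -> list[str]:
        return [p for p, g in self._groups.items() if g == group]

    def __iter__(self):
        for recs in self._records.values():
            yield from recs

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<EmaDataset: {self.n_participants} participants, "
            f"{self.n_records} records, K={self.frame.n_cells}>"
        )
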