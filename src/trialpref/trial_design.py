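"""Attribute schema and adaptive single-profile elicitation engine.

A hypothetical clinical study is described by 17 design attributes in five
categories (payment/support, administration/procedures, treatment-related,
location/time commitment, data collection/feedback).  Each attribute has two
or three levels, stored worst-to-best; the last level is the designated
"best" level used as the improvement target in the adaptive design.

The elicitation protocol is single-profile and adaptive: the initial task
shows every three-level attribute at its middle level and randomises
two-level attributes; the five follow-up tasks each modify exactly one
randomly drawn attribute, improving it (to the best level) when the initial
decision was to decline, or deteriorating it (to the worst level) when the
initial decision was to accept.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

CATEGORIES = frozenset(
    {
        "payment_support",
        "administration_procedures",
        "treatment_related",
        "location_time",
        "data_feedback",
    }
)

COUNTRIES = ("US", "Poland", "China")

_DEFAULT_SCHEMA_PATH = Path(__file__).parent / "data" / "default_schema.json"


class SchemaError(ValueError):
    """Raised when an attribute schema fails validation."""


@dataclass(frozen=True)
class AttributeDef:
    """One trial design feature with its ordered (worst -> best) levels."""

    name: str
    category: str
    levels: tuple[str, ...]
    best_index: int
    numeric_values: tuple[float, ...] | None = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not self.name or not self.name.isidentifier():
            raise SchemaError(f"attribute name {self.name!r} is not an identifier")
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"attribute {self.name!r}: unknown category {self.category!r}"
            )
        if not 2 <= len(self.levels) <= 3:
            raise SchemaError(
                f"attribute {self.name!r}: {len(self.levels)} levels (must be 2 or 3)"
            )
        if not 0 <= self.best_index < len(self.levels):
            raise SchemaError(f"attribute {self.name!r}: best_index out of range")
        if self.best_index != len(self.levels) - 1:
            raise SchemaError(
                f"attribute {self.name!r}: levels must be ordered worst->best "
                "(best_index must point at the last level)"
            )
        if self.numeric_values is not None and len(self.numeric_values) != len(
            self.levels
        ):
            raise SchemaError(
                f"attribute {self.name!r}: numeric_values length mismatch"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def worst_index(self) -> int:
        return 0

    @property
    def middle_index(self) -> int:
        if self.n_levels != 3:
            raise SchemaError(f"attribute {self.name!r} has no middle level")
        return 1


@dataclass(frozen=True)
class DesignSchema:
    """The full attribute space plus per-country payment localisation."""

    attributes: tuple[AttributeDef, ...]
    country: str = "US"
    currency_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate attribute names: {sorted(dupes)}")
        refs = [a.name for a in self.attributes if a.is_reference]
        if len(refs) != 1:
            raise SchemaError(
                f"exactly one attribute must be flagged as reference, got {refs}"
            )
        if self.country not in COUNTRIES:
            raise SchemaError(f"unknown country {self.country!r}")

    def __len__(self) -> int:
        return len(self.attributes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    @property
    def reference(self) -> str:
        return next(a.name for a in self.attributes if a.is_reference)

    def __getitem__(self, name: str) -> AttributeDef:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def non_reference_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes if not a.is_reference)

    def to_dict(self) -> dict:
        return {
            "country": self.country,
            "attributes": [
                {
                    "name": a.name,
                    "category": a.category,
                    "levels": list(a.levels),
                    "best_index": a.best_index,
                    **(
                        {"numeric_values": list(a.numeric_values)}
                        if a.numeric_values is not None
                        else {}
                    ),
                    **({"is_reference": True} if a.is_reference else {}),
                }
                for a in self.attributes
            ],
            "currency_map": {k: list(v) for k, v in self.currency_map.items()},
        }


@dataclass(frozen=True)
class StudyProfile:
    """A concrete level assignment: attribute name -> level index."""

    levels: Mapping[str, int]

    def validate(self, schema: DesignSchema) -> None:
        if set(self.levels) != set(schema.names):
            raise SchemaError("profile attributes do not match schema")
        for a in schema.attributes:
            if not 0 <= self.levels[a.name] < a.n_levels:
                raise SchemaError(f"profile level for {a.name!r} out of range")

    def replace(self, name: str, index: int) -> "StudyProfile":
        new = dict(self.levels)
        new[name] = index
        return StudyProfile(new)

    def hamming(self, other: "StudyProfile") -> int:
        return sum(self.levels[k] != other.levels[k] for k in self.levels)


@dataclass(frozen=True)
class ChoiceTask:
    """One survey page: the profile shown plus how it differs from task 0."""

    task_index: int
    profile: StudyProfile
    modified_attribute: str | None = None
    direction: str = "none"  # improve | deteriorate | none

    def __post_init__(self) -> None:
        if not 0 <= self.task_index <= 5:
            raise SchemaError("task_index must be in 0..5")
        if (self.modified_attribute is None) != (self.task_index == 0):
            raise SchemaError("modified_attribute is none iff task_index == 0")
        if self.task_index == 0 and self.direction != "none":
            raise SchemaError("initial task has direction 'none'")
        if self.task_index > 0 and self.direction not in ("improve", "deteriorate"):
            raise SchemaError("follow-up direction must be improve/deteriorate")


def _parse_attribute(entry: Mapping) -> AttributeDef:
    try:
        return AttributeDef(
            name=entry["name"],
            category=entry["category"],
            levels=tuple(entry["levels"]),
            best_index=int(entry["best_index"]),
            numeric_values=(
                tuple(entry["numeric_values"])
                if entry.get("numeric_values") is not None
                else None
            ),
            is_reference=bool(entry.get("is_reference", False)),
        )
    except KeyError as exc:  # pragma: no cover - exercised via load_schema tests
        raise SchemaError(
            f"attribute {entry.get('name', '<unnamed>')!r}: missing field {exc}"
        ) from None


def load_schema(config: str | Path | Mapping | None = None) -> DesignSchema:
    """Load an attribute schema.

    With ``config=None`` returns the shipped default 17-attribute schema.
    Otherwise ``config`` may be a mapping, or a path to a JSON/YAML file with
    keys ``attributes`` (list of attribute entries), ``country`` and
    ``currency_map``.

    Raises :class:`SchemaError` naming the offending attribute on any
    validation failure (bad level count, missing best_index, duplicates...).
    """
    if config is None:
        config = _DEFAULT_SCHEMA_PATH
    if isinstance(config, (str, Path)):
        path = Path(config)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    else:
        raw = config
    if not isinstance(raw, Mapping) or "attributes" not in raw:
        raise SchemaError("config must be a mapping with an 'attributes' list")
    attrs = tuple(_parse_attribute(e) for e in raw["attributes"])
    currency = {k: tuple(v) for k, v in raw.get("currency_map", {}).items()}
    return DesignSchema(
        attributes=attrs, country=raw.get("country", "US"), currency_map=currency
    )


def localize(schema: DesignSchema, country: str) -> DesignSchema:
    """Relabel payment levels in the local currency of ``country``.

    Payment amounts keep the same proportion of average salary in each
    country (US $0/$500/$2,000; Poland 0/450/1,800 zl; China ¥0/500/2,000);
    all other attributes are untouched.
    """
    if country not in COUNTRIES:
        raise SchemaError(f"unknown country {country!r}")
    if country not in schema.currency_map:
        raise SchemaError(f"no currency labels for {country!r} in schema")
    labels = schema.currency_map[country]
    new_attrs = []
    for a in schema.attributes:
        if a.name == "payment":
            if len(labels) != a.n_levels:
                raise SchemaError("currency label count mismatch for payment")
            a = AttributeDef(
                name=a.name,
                category=a.category,
                levels=tuple(labels),
                best_index=a.best_index,
                numeric_values=a.numeric_values,
                is_reference=a.is_reference,
            )
        new_attrs.append(a)
    return DesignSchema(
        attributes=tuple(new_attrs),
        country=country,
        currency_map=copy.deepcopy(dict(schema.currency_map)),
    )


def build_initial_profile(
    schema: DesignSchema, rng: np.random.Generator
) -> StudyProfile:
    """Construct the initial choice-task profile.

    Three-level attributes are fixed at their middle level; two-level
    attributes are randomised uniformly (the between-participant
    randomisation arm of the survey).  Deterministic given the generator
    state.
    """
    levels: dict[str, int] = {}
    for a in schema.attributes:
        if a.n_levels == 3:
            levels[a.name] = a.middle_index
        else:
            levels[a.name] = int(rng.integers(0, 2))
    return StudyProfile(levels)


def eligible_attributes(
    schema: DesignSchema, initial: StudyProfile, direction: str
) -> list[str]:
    """Attributes whose modification would visibly change the profile.

    An attribute already sitting at the target level (best for an
    improvement, worst for a deterioration) is excluded, since modifying it
    would produce no visible change to highlight.
    """
    out = []
    for a in schema.attributes:
        target = a.best_index if direction == "improve" else a.worst_index
        if initial.levels[a.name] != target:
            out.append(a.name)
    return out


def generate_followups(
    schema: DesignSchema,
    initial: StudyProfile,
    initial_decision: bool,
    rng: np.random.Generator,
) -> list[ChoiceTask]:
    """Generate the five adaptive follow-up tasks.

    If the initial decision was to decline (``initial_decision=False``) each
    follow-up improves one attribute to its best level; if it was to accept,
    each follow-up deteriorates one attribute to its worst level.  The five
    modified attributes are drawn uniformly without replacement from the
    eligible pool.
    """
    initial.validate(schema)
    direction = "deteriorate" if initial_decision else "improve"
    pool = eligible_attributes(schema, initial, direction)
    if len(pool) < 5:
        raise SchemaError(
            f"only {len(pool)} attributes eligible for direction {direction!r}"
        )
    chosen = [pool[i] for i in rng.choice(len(pool), size=5, replace=False)]
    tasks = []
    for t, name in enumerate(chosen, start=1):
        attr = schema[name]
        target = attr.best_index if direction == "improve" else attr.worst_index
        tasks.append(
            ChoiceTask(
                task_index=t,
                profile=initial.replace(name, target),
                modified_attribute=name,
                direction=direction,
            )
        )
    return tasks


def attribute_index(schema: DesignSchema) -> dict[str, int]:
    """Column index of each non-reference attribute in the encoded matrix."""
    return {name: i for i, name in enumerate(schema.non_reference_names())}


def encode_tasks(
    tasks: Iterable[ChoiceTask], schema: DesignSchema
) -> np.ndarray:
    """Indicator-code follow-up tasks for the switch model.

    One row per task; one column per non-reference attribute (16 for the
    default schema), with the transport-provision attribute as the omitted
    baseline.  A task modifying the reference attribute encodes to an
    all-zero row.
    """
    cols = attribute_index(schema)
    tasks = list(tasks)
    X = np.zeros((len(tasks), len(cols)))
    for i, task in enumerate(tasks):
        if task.modified_attribute is None:
            raise SchemaError("cannot encode an initial task (no modified attribute)")
        name = task.modified_attribute
        if name != schema.reference:
            X[i, cols[name]] = 1.0
    return X


def tasks_to_records(
    respondent_id: int,
    initial: ChoiceTask,
    followups: Sequence[ChoiceTask],
    decisions: Sequence[bool],
    schema: DesignSchema,
) -> list[dict]:
    """Flatten one respondent's six tasks to long-format rows."""
    all_tasks = [initial, *followups]
    if len(decisions) != len(all_tasks):
        raise ValueError("one decision required per task")
    rows = []
    for task, dec in zip(all_tasks, decisions):
        row = {
            "respondent_id": respondent_id,
            "task_index": task.task_index,
            "modified_attribute": task.modified_attribute or "",
            "direction": task.direction,
            "decision": int(dec),
        }
        for name in schema.names:
            row[f"level_{name}"] = task.profile.levels[name]
        rows.append(row)
    return rows
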