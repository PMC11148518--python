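"""Questionnaire definition: items, skip logic, attention filter, straightline window.

The interview is modeled as an ordered list of closed (categorical)
items.  Skip rules are predicates on earlier answers; an item whose
skip predicate fires is not applicable and must not be answered.  One
designated item is the attention filter (the respondent is instructed
to pick a specific category); nine designated adjacent items, none of
them subject to skips, form the straightlining scan window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import yaml


class SchemaError(ValueError):
    """Questionnaire/response schema violation."""


@dataclass(frozen=True)
class SkipRule:
    """Item is skipped (not applicable) when `item` was answered `equals`."""

    item: str
    equals: Any

    def fires(self, answers: Mapping[str, Any]) -> bool:
        return answers.get(self.item) == self.equals


@dataclass(frozen=True)
class Item:
    name: str
    answers: tuple = ()  # allowed categories; empty = free numeric/text
    required: bool = True
    skip: Optional[SkipRule] = None


@dataclass
class Questionnaire:
    items: list[Item]
    attention_item: str = ""
    attention_expected: Any = None
    straightline_window: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate item names")
        self._by_name = {it.name: it for it in self.items}
        for name in self.straightline_window:
            it = self._by_name.get(name)
            if it is None:
                raise SchemaError(f"straightline window item missing: {name!r}")
            if it.skip is not None:
                raise SchemaError(
                    f"straightline window item {name!r} is subject to a skip"
                )
        if self.attention_item and self.attention_item not in self._by_name:
            raise SchemaError(f"attention item missing: {self.attention_item!r}")

    def applicable_items(self, answers: Mapping[str, Any]) -> list[Item]:
        return [
            it
            for it in self.items
            if it.skip is None or not it.skip.fires(answers)
        ]

    def missing_required(self, answers: Mapping[str, Any]) -> list[str]:
        """Names of applicable required items without an answer."""
        return [
            it.name
            for it in self.applicable_items(answers)
            if it.required and answers.get(it.name) is None
        ]

    def is_complete(self, answers: Mapping[str, Any]) -> bool:
        return not self.missing_required(answers)


def default_questionnaire() -> Questionnaire:
    """Compact default interview: RDS essentials, demographics, a nine-item
    attitude battery (the straightline window), the attention filter, and
    three monitored binary indicators."""
    battery = [Item(f"q{i}", answers=(1, 2, 3, 4)) for i in range(1, 10)]
    items = [
        Item("degree"),  # personal network size (count)
        Item("region"),
        Item("province"),
        Item("age"),
        *battery,
        Item("attention", answers=("red", "green", "blue", "yellow")),
        Item("hiv_test_12m", answers=(0, 1)),
        Item("knows_status", answers=(0, 1)),
        Item("condom_last_sex", answers=(0, 1)),
        # example programmed skip: follow-up only shown after a recent test
        Item(
            "test_result_received",
            answers=(0, 1),
            skip=SkipRule(item="hiv_test_12m", equals=0),
        ),
    ]
    return Questionnaire(
        items=items,
        attention_item="attention",
        attention_expected="blue",
        straightline_window=[f"q{i}" for i in range(1, 10)],
    )


def load_questionnaire(path: str) -> Questionnaire:
    """Load a questionnaire definition from YAML or JSON."""
    with open(path, encoding="utf-8") as fh:
        raw = (
            json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        )
    items = []
    for spec in raw["items"]:
        skip = None
        if spec.get("skip"):
            skip = SkipRule(item=spec["skip"]["item"], equals=spec["skip"]["equals"])
        items.append(
            Item(
                name=spec["name"],
                answers=tuple(spec.get("answers", ())),
                required=bool(spec.get("required", True)),
                skip=skip,
            )
        )
    return Questionnaire(
        items=items,
        attention_item=raw.get("attention_item", ""),
        attention_expected=raw.get("attention_expected"),
        straightline_window=list(raw.get("straightline_window", [])),
    )
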