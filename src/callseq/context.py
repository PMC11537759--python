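"""Collapsing call-type sequences into broader contextual categories.

Call types are grouped by the behavioural context in which they are
typically produced (alarm, food, social contact, mobbing), and the same
Markov machinery is run over category tokens.  Adjacent identical
categories are deliberately NOT collapsed: two different mobbing calls in
a row become a Mobbing -> Mobbing self-transition, which is a real and
interpretable event at the category level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .annotation_io import CallSequence
from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class ContextScheme:
    """A total mapping from call-type labels to contextual categories."""

    mapping: Mapping[str, str]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in self.categories}
        if bad:
            raise ConfigurationError(
                f"mapped categories {sorted(bad)} missing from category list"
            )

    def category(self, call_type: str) -> str:
        try:
            return self.mapping[call_type]
        except KeyError:
            raise ValidationError(
                f"call type {call_type!r} has no contextual category in this scheme"
            ) from None

    @classmethod
    def from_file(cls, path: str | Path) -> "ContextScheme":
        """Load a scheme from a small YAML/JSON file.

        Expected structure: ``{"categories": [...], "mapping": {type: category}}``;
        a bare ``{type: category}`` mapping is also accepted, with
        categories inferred in sorted order.
        """
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"context scheme file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"cannot parse context scheme from {path}")
        if "mapping" in data:
            mapping = dict(data["mapping"])
            categories = tuple(data.get("categories") or sorted(set(mapping.values())))
        else:
            mapping = dict(data)
            categories = tuple(sorted(set(mapping.values())))
        return cls(mapping=mapping, categories=categories)


def default_marmoset_scheme() -> ContextScheme:
    """The standard common-marmoset context scheme.

    Alarm: whistle; Food: chirp; Contact: phee, trill, twitter;
    Mobbing: ek, tsk.
    """
    return ContextScheme(
        mapping={
            "whistle": "Alarm",
            "chirp": "Food",
            "phee": "Contact",
            "trill": "Contact",
            "twitter": "Contact",
            "ek": "Mobbing",
            "tsk": "Mobbing",
        },
        categories=("Alarm", "Contact", "Food", "Mobbing"),
    )


def map_sequences(
    sequences: Iterable[CallSequence], scheme: ContextScheme
) -> list[CallSequence]:
    """Token-for-token substitution of call types by their categories.

    Sequence boundaries and lengths are unchanged; adjacent identical
    categories are kept, so category self-transitions can appear.
    """
    return [
        CallSequence(
            tokens=tuple(scheme.category(t) for t in seq.tokens),
            individual=seq.individual,
            session=seq.session,
            context=seq.context,
        )
        for seq in sequences
    ]


def drop_sequences_containing(
    sequences: Sequence[CallSequence], labels: Iterable[str]
) -> list[CallSequence]:
    """Remove whole sequences containing any of the given tokens.

    Used e.g. to exclude alarm-category sequences from higher-order
    category analyses when the alarm call never occurs in long sequences.
    """
    drop = set(labels)
    return [s for s in sequences if not drop.intersection(s.tokens)]
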