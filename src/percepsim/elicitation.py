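"""Prompt construction and response parsing for the rater-facing protocol.

Similarity prompts consist of one sentence describing the dataset, one
sentence describing the rating task and its 0-1 scale, three fixed in-context
example pairs with their ratings, and the target pair with an empty
``Rating:`` field for the rater to fill in. Naming prompts present a
seed-shuffled list of 15 basic color terms and ask which best describes a hex
code. No network client exists here: any rater — human, language model, or
the synthetic respondents module — can consume the rendered text and return
free-text responses, which the parsers turn into numeric ratings or terms.

Malformed responses yield a typed :class:`ParseFailure` (never an exception)
and are excluded from aggregation with a reported count.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "SimilarityPromptSpec",
    "NamingPromptSpec",
    "ParseFailure",
    "build_similarity_prompt",
    "parse_rating",
    "build_naming_prompt",
    "parse_name",
    "flag_example_overlap",
]


@dataclass(frozen=True)
class ParseFailure:
    """Typed outcome for an unusable response; carries the raw text."""

    raw_text: str
    reason: str = "no parseable value"


@dataclass(frozen=True)
class SimilarityPromptSpec:
    """Template data for one similarity elicitation prompt.

    ``in_context_examples`` are exactly three (stimulus-text, stimulus-text,
    rating) triples, fixed across all target pairs of a dataset so the rater
    sees only a tiny fraction of the judged pairs.
    """

    dataset_sentence: str
    task_sentence: str
    in_context_examples: tuple[tuple[str, str, float], ...]
    target_pair: tuple[str, str]
    scale: tuple[float, float] = (0.0, 1.0)
    label_one: str = "Color one"
    label_two: str = "Color two"

    def __post_init__(self) -> None:
        if len(self.in_context_examples) != 3:
            raise ValueError("exactly 3 in-context examples are required")
        lo, hi = self.scale
        for _, _, r in self.in_context_examples:
            if not (lo <= r <= hi):
                raise ValueError(f"example rating {r} outside scale [{lo}, {hi}]")


def _pair_block(label_one: str, label_two: str, a: str, b: str, rating: float | None) -> str:
    tail = f" {rating:g}" if rating is not None else ""
    return f"{label_one}: {a}. {label_two}: {b}. Rating:{tail}"


def build_similarity_prompt(spec: SimilarityPromptSpec) -> str:
    """Render the similarity prompt; ends with an empty ``Rating:`` field.

    Stimulus texts are whatever the modality prescribes — hex codes for
    colors ("Color one: #FF0000. Color two: #A020F0. Rating:"), frequency
    values for pitch.
    """
    lines = [spec.dataset_sentence, spec.task_sentence]
    for a, b, r in spec.in_context_examples:
        lines.append(_pair_block(spec.label_one, spec.label_two, a, b, r))
    a, b = spec.target_pair
    lines.append(_pair_block(spec.label_one, spec.label_two, a, b, None))
    return "\n".join(lines)


_NUMBER_RE = re.compile(r"[-+]?(?:\d+\.\d*|\.\d+|\d+)")


def parse_rating(response_text: str, scale: tuple[float, float] = (0.0, 1.0)) -> float | ParseFailure:
    """Extract the first decimal number; succeed iff it lies within the scale."""
    m = _NUMBER_RE.search(response_text)
    if m is None:
        return ParseFailure(response_text, "no number found")
    value = float(m.group())
    lo, hi = scale
    if not (lo <= value <= hi):
        return ParseFailure(response_text, f"value {value} outside scale [{lo}, {hi}]")
    return value


@dataclass(frozen=True)
class NamingPromptSpec:
    """Template data for one forced-choice naming prompt."""

    term_list: tuple[str, ...]
    chip_text: str  # hex code of the presented color
    shuffle_seed: int = 0
    language: str = "english"

    def __post_init__(self) -> None:
        if len(self.term_list) != 15:
            raise ValueError("exactly 15 color terms are required")
        if self.language not in ("english", "russian"):
            raise ValueError("language must be 'english' or 'russian'")

    def shuffled_terms(self) -> tuple[str, ...]:
        terms = list(self.term_list)
        random.Random(self.shuffle_seed).shuffle(terms)
        return tuple(terms)


_NAMING_TEMPLATES = {
    "english": (
        "Here is a list of 15 basic color names: {terms}. "
        "Which of these names best describes the following color: {chip}? "
        "Respond only using the name."
    ),
    "russian": (
        "Вот список из 15 основных названий цветов: {terms}. "
        "Какое из этих названий лучше всего описывает следующий цвет: {chip}? "
        "Отвечайте, используя только название."
    ),
}


def build_naming_prompt(spec: NamingPromptSpec) -> str:
    """Render the naming prompt with the 15 terms in seed-shuffled order."""
    terms = ", ".join(spec.shuffled_terms())
    return _NAMING_TEMPLATES[spec.language].format(terms=terms, chip=spec.chip_text)


def parse_name(response_text: str, term_list: Sequence[str]) -> str | ParseFailure:
    """Match a free-text response to one of the offered terms.

    Tries a case-insensitive whitespace-trimmed exact match first, then the
    longest term occurring as a substring of the response.
    """
    cleaned = response_text.strip().casefold()
    for term in term_list:
        if cleaned == term.strip().casefold():
            return term
    matches = [t for t in term_list if t.casefold() in cleaned]
    if matches:
        return max(matches, key=len)
    return ParseFailure(response_text, "no matching term")


def flag_example_overlap(
    spec: SimilarityPromptSpec, target_pairs: Sequence[tuple[str, str]]
) -> list[tuple[str, str]]:
    """Target pairs that coincide with an in-context example pair.

    The three example pairs are fixed across a dataset; any matrix cell they
    would fill must be flagged so the pipeline can exclude or audit it.
    """
    examples = {frozenset((a, b)) for a, b, _ in spec.in_context_examples}
    return [p for p in target_pairs if frozenset(p) in examples]
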