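"""Synthetic respondents with known ground-truth perceptual geometry.

These generators stand in for the human participants and language-model
raters of the original elicitation protocol, so that every downstream
statistic can be validated against a known latent structure:

* a similarity rater that judges pairs as ``exp(-d/tau)`` of the Euclidean
  distance in a latent psychological space, plus clamped Gaussian noise —
  driven by a pitch helix (period 12 semitones, so octaves are extra-similar)
  or a hue circle;
* a confusion-count generator whose rows are multinomial draws biased toward
  similar stimuli;
* forced-choice naming respondents that pick color terms by softmax over
  distances to language-specific category prototypes. The Russian table
  splits blue into dark (синий) and light (голубой) prototypes and the
  violet region into фиолетовый and лиловый, mirroring the documented
  cross-linguistic contrast with English.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .naming import NamingResponse
from .simanalysis import ConfusionMatrix, RatingRecord
from .stimuli import StimulusSet, hue_angle_of_hex

__all__ = [
    "LatentSpace",
    "RatingScale",
    "SimilarityRespondent",
    "ConfusionModel",
    "NamingRespondent",
    "pitch_helix_space",
    "color_wheel_space",
    "simulate_similarity_ratings",
    "simulate_confusion",
    "simulate_naming",
    "munsell_coordinates",
    "ENGLISH_TERMS",
    "RUSSIAN_TERMS",
    "ENGLISH_PROTOTYPES",
    "RUSSIAN_PROTOTYPES",
    "naming_choice_probabilities",
]


# ---------------------------------------------------------------------------
# Latent spaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentSpace:
    """Euclidean 'psychological space': stimulus id -> point in R^k."""

    coordinates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        coords = {k: np.asarray(v, dtype=float) for k, v in self.coordinates.items()}
        dims = {v.shape for v in coords.values()}
        if len(dims) > 1:
            raise ValueError("all coordinates must share the same dimension")
        object.__setattr__(self, "coordinates", coords)

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.coordinates[a] - self.coordinates[b]))


#: Default helix rise per semitone. With radius 1 the latent distance at a
#: separation of s semitones is d(s)^2 = (rise·s)^2 + 2·radius^2·(1 - cos(2πs/12)),
#: so the octave (s = 12, chroma term zero) is a strict local minimum versus
#: s = 11 and 13 whenever rise < radius·sqrt(2(1 - cos(π/6)))/sqrt(23) ≈ 0.108·radius.
DEFAULT_RISE_PER_SEMITONE = 0.08


def pitch_helix_space(
    pitch_set: StimulusSet, radius: float = 1.0,
    rise_per_semitone: float = DEFAULT_RISE_PER_SEMITONE,
) -> LatentSpace:
    """Helical pitch representation: height tracks pitch, angle tracks pitch class.

    A tone at pitch p maps to (radius·cos(2πp/12), radius·sin(2πp/12),
    rise·p); tones an octave apart sit vertically aligned, giving them the
    enhanced similarity characteristic of octave equivalence.
    """
    if pitch_set.modality != "pitch":
        raise ValueError("pitch_helix_space requires a pitch set")
    coords = {}
    for tone in pitch_set:
        theta = 2.0 * math.pi * tone.midi / 12.0
        coords[tone.stimulus_id] = np.array(
            [radius * math.cos(theta), radius * math.sin(theta), rise_per_semitone * tone.midi]
        )
    return LatentSpace(coords)


def color_wheel_space(color_set: StimulusSet, radius: float = 1.0) -> LatentSpace:
    """Colors placed on a circle of the given radius at their hue angles."""
    coords = {}
    for c in color_set:
        angle = hue_angle_of_hex(c.hex_code)
        coords[c.stimulus_id] = np.array([radius * math.cos(angle), radius * math.sin(angle)])
    return LatentSpace(coords)


# ---------------------------------------------------------------------------
# Similarity rater
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatingScale:
    """Bounded response scale; ``n_levels`` set for discrete (Likert) scales."""

    min: float = 0.0
    max: float = 1.0
    n_levels: int | None = None  # None = continuous

    def __post_init__(self) -> None:
        if self.max <= self.min:
            raise ValueError("scale max must exceed min")
        if self.n_levels is not None and self.n_levels < 2:
            raise ValueError("discrete scales need at least 2 levels")


@dataclass(frozen=True)
class SimilarityRespondent:
    """Latent-geometry rater: rating = clamp(exp(-d/tau) + noise) on its scale."""

    space: LatentSpace
    tau: float = 1.0
    noise_sd: float = 0.05
    scale: RatingScale = field(default_factory=RatingScale)
    seed: int = 0
    rater_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def true_similarity(self, a: str, b: str) -> float:
        return math.exp(-self.space.distance(a, b) / self.tau)


def simulate_similarity_ratings(
    respondent: SimilarityRespondent,
    pairs: Sequence[tuple[str, str]],
    repetitions: int = 10,
) -> list[RatingRecord]:
    """Generate ``repetitions`` ratings per pair from the latent geometry.

    The unit-interval judgment exp(-d/tau) + N(0, noise_sd^2) is clamped to
    [0, 1], mapped affinely onto the respondent's scale, and — on discrete
    scales — rounded to the nearest level. Deterministic under the seed.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    for a, b in pairs:
        if a not in respondent.space.coordinates or b not in respondent.space.coordinates:
            raise KeyError(f"pair ({a!r}, {b!r}) not covered by the latent space")
    rng = np.random.default_rng(respondent.seed)
    scale = respondent.scale
    base = np.array([respondent.true_similarity(a, b) for a, b in pairs])
    records: list[RatingRecord] = []
    for rep in range(repetitions):
        noisy = base + rng.normal(0.0, respondent.noise_sd, size=base.size) \
            if respondent.noise_sd > 0 else base.copy()
        unit = np.clip(noisy, 0.0, 1.0)
        vals = scale.min + (scale.max - scale.min) * unit
        if scale.n_levels is not None:
            levels = np.linspace(scale.min, scale.max, scale.n_levels)
            vals = levels[np.abs(vals[:, None] - levels[None, :]).argmin(axis=1)]
        for (a, b), v in zip(pairs, vals):
            records.append(
                RatingRecord(rater_id=respondent.rater_id, stim_a=a, stim_b=b,
                             rating=float(v), repetition=rep)
            )
    return records


# ---------------------------------------------------------------------------
# Confusion generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionModel:
    """Similarity-based choice model for confusion counts.

    Row x of the count matrix is a multinomial draw of ``trials_per_row``
    trials with response probabilities proportional to
    ``base_similarity[x, ·] ** concentration``.
    """

    ids: tuple[str, ...]
    base_similarity: np.ndarray
    concentration: float = 1.0
    trials_per_row: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.base_similarity, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1] or s.shape[0] != len(self.ids):
            raise ValueError("base_similarity must be square and match ids")
        if not np.allclose(s, s.T):
            raise ValueError("base_similarity must be symmetric")
        if (s <= 0).any() or (s > 1).any():
            raise ValueError("base_similarity entries must lie in (0, 1]")
        if not np.allclose(np.diag(s), 1.0):
            raise ValueError("base_similarity diagonal must be exactly 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.trials_per_row < 1:
            raise ValueError("trials_per_row must be >= 1")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "base_similarity", s)


def simulate_confusion(model: ConfusionModel) -> ConfusionMatrix:
    """Draw a confusion-count matrix and normalise to probabilities.

    Counts receive add-one smoothing before row normalisation so the diagonal
    probabilities are strictly positive (the similarity conversion divides by
    p_xx p_yy). Raw counts are kept on the result; their rows sum to
    ``trials_per_row`` exactly.
    """
    rng = np.random.default_rng(model.seed)
    n = len(model.ids)
    weights = model.base_similarity ** model.concentration
    probs = weights / weights.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(model.trials_per_row, probs[i]) for i in range(n)])
    smoothed = counts + 1.0
    return ConfusionMatrix(
        ids=model.ids,
        probs=smoothed / smoothed.sum(axis=1, keepdims=True),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Naming respondents
# ---------------------------------------------------------------------------

#: Prototype tables as (hue_degrees, lightness in [0,1], chroma in [0,1]).
#: Chromatic prototypes sit on the hue cylinder; achromatic ones on its axis.
ENGLISH_PROTOTYPES: dict[str, tuple[float, float, float]] = {
    "red": (0.0, 0.50, 1.0),
    "orange": (30.0, 0.55, 1.0),
    "brown": (30.0, 0.20, 0.55),
    "yellow": (55.0, 0.65, 1.0),
    "green": (120.0, 0.50, 1.0),
    "turquoise": (175.0, 0.60, 1.0),
    "blue": (225.0, 0.50, 1.0),
    "indigo": (255.0, 0.30, 0.9),
    "violet": (270.0, 0.45, 1.0),
    "purple": (290.0, 0.40, 1.0),
    "pink": (330.0, 0.72, 0.85),
    "white": (0.0, 1.00, 0.0),
    "silver": (0.0, 0.75, 0.0),
    "grey": (0.0, 0.50, 0.0),
    "black": (0.0, 0.00, 0.0),
}

#: Russian table: same hue wheel, but the blue region carries two prototypes
#: split by lightness (синий dark vs голубой light), as does the violet
#: region (фиолетовый dark vs лиловый light).
RUSSIAN_PROTOTYPES: dict[str, tuple[float, float, float]] = {
    "красный": (0.0, 0.50, 1.0),        # red
    "оранжевый": (30.0, 0.55, 1.0),     # orange
    "коричневый": (30.0, 0.20, 0.55),   # brown
    "жёлтый": (55.0, 0.65, 1.0),        # yellow
    "зелёный": (120.0, 0.50, 1.0),      # green
    "бирюзовый": (175.0, 0.60, 1.0),    # turquoise
    "голубой": (225.0, 0.72, 1.0),      # light blue
    "синий": (225.0, 0.28, 1.0),        # dark blue
    "фиолетовый": (272.0, 0.30, 1.0),   # violet (dark)
    "лиловый": (282.0, 0.68, 0.95),     # lilac (light)
    "розовый": (330.0, 0.72, 0.85),     # pink
    "белый": (0.0, 1.00, 0.0),          # white
    "серебряный": (0.0, 0.75, 0.0),     # silver
    "серый": (0.0, 0.50, 0.0),          # grey
    "чёрный": (0.0, 0.00, 0.0),         # black
}

ENGLISH_TERMS: tuple[str, ...] = tuple(ENGLISH_PROTOTYPES)
RUSSIAN_TERMS: tuple[str, ...] = tuple(RUSSIAN_PROTOTYPES)

#: Weight of the lightness axis relative to the unit hue circle.
_LIGHTNESS_SCALE = 2.0


def _hlc_to_point(hue_deg: float, lightness: float, chroma: float) -> np.ndarray:
    theta = math.radians(hue_deg)
    return np.array(
        [chroma * math.cos(theta), chroma * math.sin(theta), _LIGHTNESS_SCALE * lightness]
    )


def munsell_coordinates(palette: StimulusSet) -> dict[str, np.ndarray]:
    """3-d cylindrical color coordinates of WCS chips: hue from the column,
    lightness from the row, unit chroma for chromatic chips."""
    if palette.modality != "munsell":
        raise ValueError("munsell_coordinates requires a munsell palette")
    coords = {}
    for chip in palette:
        lightness = 1.0 - chip.row / 9.0
        if chip.col == 0:
            coords[chip.chip_id] = _hlc_to_point(0.0, lightness, 0.0)
        else:
            hue = (chip.col - 1) / 40.0 * 360.0
            coords[chip.chip_id] = _hlc_to_point(hue, lightness, 1.0)
    return coords


@dataclass(frozen=True)
class NamingRespondent:
    """Forced-choice namer: P(term) = softmax over -d(chip, prototype)/temperature."""

    language: str = "english"
    temperature: float = 0.15
    seed: int = 0
    rater_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.language not in ("english", "russian"):
            raise ValueError("language must be 'english' or 'russian'")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def terms(self) -> tuple[str, ...]:
        return ENGLISH_TERMS if self.language == "english" else RUSSIAN_TERMS

    @property
    def prototypes(self) -> dict[str, np.ndarray]:
        table = ENGLISH_PROTOTYPES if self.language == "english" else RUSSIAN_PROTOTYPES
        return {t: _hlc_to_point(*hlc) for t, hlc in table.items()}


def naming_choice_probabilities(
    respondent: NamingRespondent, chip_point: np.ndarray
) -> np.ndarray:
    """Softmax choice probabilities over the respondent's 15 terms (sums to 1)."""
    protos = respondent.prototypes
    d = np.array([np.linalg.norm(chip_point - protos[t]) for t in respondent.terms])
    logits = -d / respondent.temperature
    p = np.exp(logits - logits.max())
    return p / p.sum()


def simulate_naming(
    respondent: NamingRespondent,
    palette: StimulusSet,
    responses_per_chip: int = 10,
) -> list[NamingResponse]:
    """Draw forced-choice naming responses for every chip of the palette.

    In the temperature -> 0 limit every chip deterministically receives its
    nearest prototype's term. Deterministic under the respondent's seed.
    """
    if responses_per_chip < 1:
        raise ValueError("responses_per_chip must be >= 1")
    coords = munsell_coordinates(palette)
    rng = np.random.default_rng(respondent.seed)
    terms = respondent.terms
    out: list[NamingResponse] = []
    for cid in palette.ids:
        p = naming_choice_probabilities(respondent, coords[cid])
        picks = rng.choice(len(terms), size=responses_per_chip, p=p)
        for k in picks:
            out.append(
                NamingResponse(chip_id=cid, term=terms[int(k)],
                               rater_id=respondent.rater_id, language=respondent.language)
            )
    return out
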