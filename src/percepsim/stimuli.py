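"""Stimulus-set construction for perceptual similarity and naming experiments.

Covers the four stimulus families used throughout the package:

* pitch ladders of harmonic complex tones, with the standard MIDI <-> frequency
  mapping ``p = 12·log2(f/440) + 69``;
* monochromatic color lists specified by wavelength (the classic 14-color set
  spanning 434–674 nm) with a piecewise visible-spectrum hex approximation;
* a symbolic 16-consonant inventory (two speakers);
* a World-Color-Survey-style palette of 330 Munsell chips (10 achromatic
  levels plus 40 hues x 8 lightness rows).

All generators are deterministic; the only stochastic operation is
:func:`jitter_pitch_set`, which is seeded.
"""

from __future__ import annotations

import colorsys
import json
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "PitchTone",
    "ColorStimulus",
    "ConsonantStimulus",
    "MunsellChip",
    "StimulusSet",
    "midi_from_frequency",
    "frequency_from_midi",
    "generate_pitch_set",
    "jitter_pitch_set",
    "wavelength_to_hex",
    "generate_color_set",
    "interpolate_color_set",
    "generate_consonant_set",
    "generate_munsell_palette",
    "hex_to_rgb",
    "rgb_to_hex",
    "hue_angle_of_hex",
    "EKMAN_WAVELENGTHS_NM",
    "CONSONANT_INVENTORY",
]

A4_HZ = 440.0
A4_MIDI = 69.0

#: The 14 monochromatic wavelengths (nm) of the classic color-similarity set,
#: spanning 434-674 nm from violet-blue to red.
EKMAN_WAVELENGTHS_NM: tuple[float, ...] = (
    434.0, 445.0, 465.0, 472.0, 490.0, 504.0, 537.0,
    555.0, 584.0, 600.0, 610.0, 628.0, 651.0, 674.0,
)

#: 16-consonant inventory (IPA), recorded by two speakers in the source study.
CONSONANT_INVENTORY: tuple[str, ...] = (
    "b", "p", "m", "n", "g", "k", "d", "t",
    "f", "v", "s", "z", "θ", "ð", "ʒ", "ʃ",
)

_HEX_RE = re.compile(r"^#[0-9A-F]{6}$")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PitchTone:
    """A harmonic complex tone on the semitone (MIDI) scale.

    ``midi`` and ``frequency_hz`` are kept mutually consistent via
    ``p = 12·log2(f/440) + 69``; the constructor enforces this to 1e-9.
    """

    stimulus_id: str
    midi: float
    frequency_hz: float

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if abs(midi_from_frequency(self.frequency_hz) - self.midi) >= 1e-9:
            raise ValueError(
                f"inconsistent tone {self.stimulus_id}: midi={self.midi}, "
                f"frequency_hz={self.frequency_hz}"
            )


@dataclass(frozen=True)
class ColorStimulus:
    """A color patch specified by an uppercase '#RRGGBB' hex code.

    ``wavelength_nm``, when present, identifies the monochromatic light the
    hex approximates and must lie in the visible band [380, 780] nm.
    """

    stimulus_id: str
    hex_code: str
    wavelength_nm: float | None = None
    term: str | None = None

    def __post_init__(self) -> None:
        if not _HEX_RE.match(self.hex_code):
            raise ValueError(f"malformed hex code {self.hex_code!r}")
        if self.wavelength_nm is not None and not (380.0 <= self.wavelength_nm <= 780.0):
            raise ValueError(f"wavelength {self.wavelength_nm} nm outside [380, 780]")


@dataclass(frozen=True)
class ConsonantStimulus:
    stimulus_id: str
    ipa_symbol: str
    speaker: str  # "male" | "female"

    def __post_init__(self) -> None:
        if self.ipa_symbol not in CONSONANT_INVENTORY:
            raise ValueError(f"unknown consonant {self.ipa_symbol!r}")
        if self.speaker not in ("male", "female"):
            raise ValueError(f"speaker must be 'male' or 'female', got {self.speaker!r}")


@dataclass(frozen=True)
class MunsellChip:
    """One chip of the WCS-style naming palette.

    ``row`` indexes lightness (0 lightest .. 9 darkest); ``col`` 0 is the
    achromatic column, 1-40 are hues.
    """

    chip_id: str
    row: int
    col: int
    hex_code: str

    def __post_init__(self) -> None:
        if not (0 <= self.row <= 9):
            raise ValueError("row must be in 0..9")
        if not (0 <= self.col <= 40):
            raise ValueError("col must be in 0..40")
        if not _HEX_RE.match(self.hex_code):
            raise ValueError(f"malformed hex code {self.hex_code!r}")


MODALITIES = ("pitch", "color", "consonant", "loudness", "taste", "timbre", "munsell")


@dataclass(frozen=True)
class StimulusSet:
    """An ordered collection of uniquely identified stimuli.

    The item order is the canonical row/column order of every matrix built
    over the set.
    """

    modality: str
    items: tuple = ()

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "items", tuple(self.items))
        ids = [getattr(it, "stimulus_id", None) or getattr(it, "chip_id") for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate stimulus ids")

    @property
    def size(self) -> int:
        return len(self.items)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(
            getattr(it, "stimulus_id", None) or getattr(it, "chip_id") for it in self.items
        )

    def __iter__(self) -> Iterator:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    # -- serialization (one JSON object per stimulus, line-delimited) -------

    def to_records(self) -> list[dict]:
        out = []
        for it in self.items:
            rec = {"modality": self.modality}
            rec.update(it.__dict__)
            out.append(rec)
        return out

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r, ensure_ascii=False) for r in self.to_records()) + "\n"


# ---------------------------------------------------------------------------
# Pitch
# ---------------------------------------------------------------------------

def midi_from_frequency(frequency_hz: float) -> float:
    """Semitone pitch number of a frequency: ``12·log2(f/440) + 69``."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return 12.0 * math.log2(frequency_hz / A4_HZ) + A4_MIDI


def frequency_from_midi(midi: float) -> float:
    """Frequency in Hz of a semitone pitch number (inverse of midi_from_frequency)."""
    return A4_HZ * 2.0 ** ((midi - A4_MIDI) / 12.0)


def generate_pitch_set(midi_lo: float, midi_hi: float, step_semitones: float = 1.0) -> StimulusSet:
    """Inclusive ladder of tones at ``midi_lo, midi_lo+step, ..., midi_hi``.

    The default two-octave experiment uses (60, 84, 1): 25 tones from C4
    (261.626 Hz) to C6 (1046.502 Hz).
    """
    if step_semitones <= 0:
        raise ValueError("step must be positive")
    if midi_lo > midi_hi:
        raise ValueError("midi_lo must not exceed midi_hi")
    n = int(math.floor((midi_hi - midi_lo) / step_semitones + 1e-12)) + 1
    tones = []
    for i in range(n):
        p = midi_lo + i * step_semitones
        tones.append(
            PitchTone(stimulus_id=f"tone_{i:02d}", midi=p, frequency_hz=frequency_from_midi(p))
        )
    return StimulusSet(modality="pitch", items=tones)


def jitter_pitch_set(
    pitch_set: StimulusSet, magnitude_semitones: float = 0.1, seed: int = 0
) -> StimulusSet:
    """Shift each tone's pitch by +/- ``magnitude_semitones``, signs i.i.d. uniform.

    Used as a control against lookup-table behaviour: jittered values no longer
    coincide with integer MIDI notes, but preserve the ladder geometry.
    """
    if pitch_set.modality != "pitch":
        raise ValueError("jitter_pitch_set requires a pitch set")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=pitch_set.size)
    tones = []
    for tone, sgn in zip(pitch_set.items, signs):
        p = tone.midi + sgn * magnitude_semitones
        tones.append(replace(tone, midi=p, frequency_hz=frequency_from_midi(p)))
    return StimulusSet(modality="pitch", items=tones)


# ---------------------------------------------------------------------------
# Colors
# ---------------------------------------------------------------------------

def _spectrum_rgb(wavelength_nm: float) -> tuple[float, float, float]:
    """Piecewise-linear visible-spectrum RGB (unit range), before gamma."""
    w = wavelength_nm
    if w < 440.0:
        r, g, b = -(w - 440.0) / (440.0 - 380.0), 0.0, 1.0
    elif w < 490.0:
        r, g, b = 0.0, (w - 440.0) / (490.0 - 440.0), 1.0
    elif w < 510.0:
        r, g, b = 0.0, 1.0, -(w - 510.0) / (510.0 - 490.0)
    elif w < 580.0:
        r, g, b = (w - 510.0) / (580.0 - 510.0), 1.0, 0.0
    elif w < 645.0:
        r, g, b = 1.0, -(w - 645.0) / (645.0 - 580.0), 0.0
    else:
        r, g, b = 1.0, 0.0, 0.0
    # Intensity falls off toward the band edges.
    if w < 420.0:
        s = 0.3 + 0.7 * (w - 380.0) / (420.0 - 380.0)
    elif w > 700.0:
        s = 0.3 + 0.7 * (780.0 - w) / (780.0 - 700.0)
    else:
        s = 1.0
    return r * s, g * s, b * s


_GAMMA = 0.8


def wavelength_to_hex(wavelength_nm: float) -> str:
    """Uppercase '#RRGGBB' approximation of a monochromatic light.

    Deterministic piecewise-linear spectrum model over 380-780 nm with gamma
    correction (gamma 0.8). Not calibrated colorimetry — adequate for hue
    ordering and prompt construction.
    """
    if not (380.0 <= wavelength_nm <= 780.0):
        raise ValueError(f"wavelength {wavelength_nm} nm outside the visible band [380, 780]")
    rgb = _spectrum_rgb(wavelength_nm)
    channels = tuple(int(round(255.0 * (c ** _GAMMA))) if c > 0 else 0 for c in rgb)
    return rgb_to_hex(channels)


def rgb_to_hex(rgb: Sequence[int]) -> str:
    r, g, b = (min(255, max(0, int(c))) for c in rgb)
    return f"#{r:02X}{g:02X}{b:02X}"


def hex_to_rgb(hex_code: str) -> tuple[int, int, int]:
    if not _HEX_RE.match(hex_code):
        raise ValueError(f"malformed hex code {hex_code!r}")
    return tuple(int(hex_code[i : i + 2], 16) for i in (1, 3, 5))


def hue_angle_of_hex(hex_code: str) -> float:
    """Hue angle in radians (HSV hue x 2π) of a hex color."""
    r, g, b = (c / 255.0 for c in hex_to_rgb(hex_code))
    h, s, v = colorsys.rgb_to_hsv(r, g, b)
    if s == 0.0:
        raise ValueError(f"achromatic color {hex_code} has no hue")
    return 2.0 * math.pi * h


def generate_color_set(wavelengths_nm: Iterable[float] = EKMAN_WAVELENGTHS_NM) -> StimulusSet:
    """Color set from a list of wavelengths, sorted ascending, hexes attached."""
    ws = sorted(float(w) for w in wavelengths_nm)
    items = [
        ColorStimulus(stimulus_id=f"color_{w:.1f}nm", wavelength_nm=w, hex_code=wavelength_to_hex(w))
        for w in ws
    ]
    return StimulusSet(modality="color", items=items)


def interpolate_color_set(base: StimulusSet, target_size: int) -> StimulusSet:
    """Extend a wavelength-sorted color set by inserting midpoint wavelengths.

    Midpoints are inserted into the widest remaining gap first (ties broken
    toward the shorter-wavelength gap) until ``target_size`` is reached; the
    base colors are preserved. Used to extend the 14-color set to 23 for
    better coverage of the hue circle.
    """
    if base.modality != "color":
        raise ValueError("interpolate_color_set requires a color set")
    if target_size < base.size:
        raise ValueError("target_size must be >= the base set size")
    ws = [c.wavelength_nm for c in base.items]
    if any(w is None for w in ws) or ws != sorted(ws):
        raise ValueError("base set must be wavelength-sorted with wavelengths present")
    ws = list(ws)
    while len(ws) < target_size:
        gaps = [ws[i + 1] - ws[i] for i in range(len(ws) - 1)]
        i = int(np.argmax(gaps))  # argmax takes the first (shortest-wavelength) tie
        ws.insert(i + 1, 0.5 * (ws[i] + ws[i + 1]))
    originals = {c.wavelength_nm: c for c in base.items}
    items = []
    for w in ws:
        if w in originals:
            items.append(originals[w])
        else:
            items.append(
                ColorStimulus(
                    stimulus_id=f"color_{w:.1f}nm", wavelength_nm=w, hex_code=wavelength_to_hex(w)
                )
            )
    return StimulusSet(modality="color", items=items)


# ---------------------------------------------------------------------------
# Consonants
# ---------------------------------------------------------------------------

def generate_consonant_set() -> StimulusSet:
    """The symbolic 16-consonant inventory, speakers alternating male/female."""
    items = [
        ConsonantStimulus(
            stimulus_id=f"cons_{i:02d}_{sym}",
            ipa_symbol=sym,
            speaker="male" if i % 2 == 0 else "female",
        )
        for i, sym in enumerate(CONSONANT_INVENTORY)
    ]
    return StimulusSet(modality="consonant", items=items)


# ---------------------------------------------------------------------------
# Munsell / WCS palette
# ---------------------------------------------------------------------------

_ROW_LETTERS = "ABCDEFGHIJ"


def _chip_hex(row: int, col: int) -> str:
    """Synthetic, perceptually ordered chip color: hue tracks the column,
    lightness tracks the row. Stand-in for calibrated Munsell renotation."""
    lightness = 1.0 - row / 9.0
    if col == 0:
        r = g = b = lightness
    else:
        hue = (col - 1) / 40.0
        r, g, b = colorsys.hls_to_rgb(hue, 0.15 + 0.7 * lightness, 0.9)
    return rgb_to_hex((round(255 * r), round(255 * g), round(255 * b)))


def generate_munsell_palette() -> StimulusSet:
    """The 330-chip WCS-style grid: 10 achromatic levels (column 0, rows A-J)
    plus 40 hue columns x 8 chromatic lightness rows (B-I).

    Chip ids follow the WCS convention of row letter + column number ("A0",
    "C17", ...). Hex codes are synthetic but ordered: only the grid layout and
    the perceptual ordering matter for the naming analyses.
    """
    chips = []
    for row in range(10):
        chips.append(MunsellChip(f"{_ROW_LETTERS[row]}0", row, 0, _chip_hex(row, 0)))
    for col in range(1, 41):
        for row in range(1, 9):
            chips.append(MunsellChip(f"{_ROW_LETTERS[row]}{col}", row, col, _chip_hex(row, col)))
    return StimulusSet(modality="munsell", items=chips)
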