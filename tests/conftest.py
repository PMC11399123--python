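"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

import percepsim as ps


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def brute_force_rand_counts(P: dict, Q: dict) -> tuple[int, int, int]:
    """O(n^2) pair counting: (total pairs, co-clustered in both, separated in both)."""
    items = sorted(P)
    a = b = c = 0
    for x, y in combinations(items, 2):
        a += 1
        same_p = P[x] == P[y]
        same_q = Q[x] == Q[y]
        if same_p and same_q:
            b += 1
        elif not same_p and not same_q:
            c += 1
    return a, b, c


def brute_force_confusion_similarity(probs: np.ndarray) -> np.ndarray:
    """Element-wise evaluation of s_xy = sqrt(p_xy p_yx / (p_xx p_yy))."""
    n = probs.shape[0]
    s = np.empty((n, n))
    for x in range(n):
        for y in range(n):
            s[x, y] = math.sqrt(probs[x, y] * probs[y, x] / (probs[x, x] * probs[y, y]))
    return s


def set_partitions(items: list):
    """Enumerate all set partitions (as label dicts) of the given items."""
    if not items:
        yield {}
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        labels = set(part.values())
        for lab in sorted(labels):
            yield {**part, first: lab}
        new_label = f"b{len(labels)}"
        yield {**part, first: new_label}


def helix_distance(separation: float, radius: float = 1.0, rise: float = 0.08) -> float:
    """Closed-form latent distance on the pitch helix at a given separation."""
    chroma = 2.0 * radius**2 * (1.0 - math.cos(2.0 * math.pi * separation / 12.0))
    return math.sqrt((rise * separation) ** 2 + chroma)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def pitch_ladder() -> ps.StimulusSet:
    return ps.generate_pitch_set(60, 84, 1.0)


@pytest.fixture(scope="session")
def helix(pitch_ladder) -> ps.LatentSpace:
    return ps.pitch_helix_space(pitch_ladder)


@pytest.fixture(scope="session")
def all_pitch_pairs(pitch_ladder) -> list[tuple[str, str]]:
    ids = list(pitch_ladder.ids)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


@pytest.fixture(scope="session")
def palette() -> ps.StimulusSet:
    return ps.generate_munsell_palette()


@pytest.fixture(scope="session")
def helix_ratings(helix, all_pitch_pairs):
    """10 repetitions per pair from the default helix respondent, seed 1."""
    respondent = ps.SimilarityRespondent(space=helix, seed=1)
    return ps.simulate_similarity_ratings(respondent, all_pitch_pairs, 10)
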