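"""Delimited-text readers and writers for ratings, matrices and naming data.

Dialect: comma-separated, UTF-8, "." decimal, mandatory header; floats are
written with 12 significant digits so write -> read -> write is byte-stable.
Russian terms are stored as UTF-8 without transliteration.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .naming import NamingMap, NamingResponse
from .simanalysis import ConfusionMatrix, RatingRecord, SimilarityMatrix

__all__ = [
    "read_ratings",
    "write_ratings",
    "read_matrix",
    "write_matrix",
    "read_naming",
    "write_naming",
    "write_naming_map",
]

_FLOAT_FMT = "%.12g"

RATING_COLUMNS = ["rater_id", "stim_a", "stim_b", "rating", "repetition"]
NAMING_COLUMNS = ["chip_id", "term", "rater_id", "language"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_ratings(
    path, scale: tuple[float, float] | None = None
) -> list[RatingRecord]:
    """Read long-format rating records; out-of-scale rows are excluded with a warning."""
    df = pd.read_csv(path, encoding="utf-8")
    _require_columns(df, RATING_COLUMNS, path)
    records = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        rating = float(row.rating)
        if scale is not None and not (scale[0] <= rating <= scale[1]):
            warnings.warn(
                f"{path}:{line}: rating {rating} outside scale {scale}; row excluded"
            )
            continue
        records.append(
            RatingRecord(
                rater_id=str(row.rater_id), stim_a=str(row.stim_a),
                stim_b=str(row.stim_b), rating=rating, repetition=int(row.repetition),
            )
        )
    return records


def write_ratings(records: Iterable[RatingRecord], path) -> None:
    df = pd.DataFrame(
        [(r.rater_id, r.stim_a, r.stim_b, r.rating, r.repetition) for r in records],
        columns=RATING_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8", lineterminator="\n")


def read_matrix(path, kind: str = "similarity") -> SimilarityMatrix | ConfusionMatrix:
    """Read a square matrix with an id header row and id first column."""
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    ids_row = tuple(str(c) for c in df.columns)
    ids_col = tuple(str(i) for i in df.index)
    if len(ids_row) != len(ids_col):
        raise ValueError(f"{path}: matrix is not square")
    if ids_row != ids_col:
        raise ValueError(f"{path}: row and column ids disagree")
    values = df.to_numpy(dtype=float)
    if kind == "similarity":
        return SimilarityMatrix(
            ids=ids_row, values=values,
            symmetric=bool(np.array_equal(values, values.T, equal_nan=True)),
        )
    if kind == "confusion":
        return ConfusionMatrix(ids=ids_row, probs=values)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(M: SimilarityMatrix | ConfusionMatrix, path) -> None:
    values = M.values if isinstance(M, SimilarityMatrix) else M.probs
    df = pd.DataFrame(values, index=list(M.ids), columns=list(M.ids))
    df.to_csv(path, float_format=_FLOAT_FMT, encoding="utf-8", lineterminator="\n")


def read_naming(path) -> list[NamingResponse]:
    df = pd.read_csv(path, encoding="utf-8")
    _require_columns(df, NAMING_COLUMNS, path)
    return [
        NamingResponse(
            chip_id=str(r.chip_id), term=str(r.term),
            rater_id=str(r.rater_id), language=str(r.language),
        )
        for r in df.itertuples(index=False)
    ]


def write_naming(responses: Iterable[NamingResponse], path) -> None:
    df = pd.DataFrame(
        [(r.chip_id, r.term, r.rater_id, r.language) for r in responses],
        columns=NAMING_COLUMNS,
    )
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def write_naming_map(naming_map: NamingMap, path) -> None:
    """Line-delimited JSON: one 'chip' record per chip, then one 'term'
    summary record per dominant term."""
    with open(path, "w", encoding="utf-8") as fh:
        for cid, cn in naming_map.chips.items():
            fh.write(json.dumps({
                "kind": "chip", "chip_id": cid, "dominant_term": cn.dominant_term,
                "agreement": round(cn.agreement, 12), "mark": cn.mark,
                "n_responses": cn.n_responses,
            }, ensure_ascii=False) + "\n")
        for term, ts in naming_map.terms.items():
            fh.write(json.dumps({
                "kind": "term", "term": term, "chip_count": ts.chip_count,
                "legend_color": ts.legend_hex,
            }, ensure_ascii=False) + "\n")
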