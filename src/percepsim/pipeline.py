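"""Run configuration, seeded reproducibility, logging, and the end-to-end pipeline.

A :class:`RunConfig` fixes every free parameter of a run (modality, sample
sizes, noise, bootstrap size, output paths) plus one root seed; per-stage
seeds are spawned deterministically from the root seed keyed by stage name,
so adding a stage never shifts the random streams of existing ones. A fixed
config yields bitwise-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import naming as nm
from . import respondents as rsp
from . import simanalysis as sa
from . import stimuli as st
from . import io as pio

__all__ = ["RunConfig", "StageRecord", "RunLog", "stage_seed", "run_pipeline"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, keyed by stage name."""
    return (int(root_seed) * 2654435761 + zlib.crc32(stage.encode("utf-8"))) % (2**31)


@dataclass
class RunConfig:
    """Complete, serialisable description of one pipeline run."""

    seed: int = 0
    modality: str = "pitch"  # "pitch" | "color" | "naming"
    out_dir: str = "percepsim_out"
    n_boot: int = 1000
    repetitions: int = 10
    scale_min: float = 0.0
    scale_max: float = 1.0
    noise_sd: float = 0.05
    tau: float = 1.0
    # pitch options
    midi_lo: int = 60
    midi_hi: int = 84
    step_semitones: float = 1.0
    helix_radius: float = 1.0
    rise_per_semitone: float = rsp.DEFAULT_RISE_PER_SEMITONE
    mds_dimensions: int = 3
    # color options
    n_colors: int = 14
    extend_colors_to: int = 0  # 0 = no interpolation
    # naming options
    responses_per_chip: int = 10
    naming_temperature: float = 0.15

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class StageRecord:
    stage: str
    params: dict[str, Any]
    outputs: dict[str, Any]
    warnings: tuple[str, ...] = ()
    timestamp: float = 0.0


@dataclass
class RunLog:
    records: list[StageRecord] = field(default_factory=list)

    def add(self, stage: str, params: dict, outputs: dict, warnings=()) -> None:
        self.records.append(
            StageRecord(stage=stage, params=params, outputs=outputs,
                        warnings=tuple(warnings), timestamp=time.time())
        )

    def summary(self) -> dict[str, dict]:
        return {r.stage: r.outputs for r in self.records}


def _pairs(ids) -> list[tuple[str, str]]:
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def run_pipeline(config: RunConfig) -> RunLog:
    """Execute the stages for the configured modality and write all outputs.

    pitch: ladder -> helix respondent -> ratings -> matrix -> smoothing ->
    interval profile & octave peak -> classical MDS -> distance-profile
    correlation with the generating helix -> bootstrap correlation vs the
    ground-truth similarity matrix.

    color: wavelength set (optionally interpolated) -> hue-circle respondent
    -> ratings -> matrix -> 2-d MDS -> distance-profile correlation.

    naming: English and Russian respondents over the 330-chip palette ->
    dominant maps -> cross-language ARI with bootstrap CI.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json() + "\n", encoding="utf-8")
    log = RunLog()
    scale = rsp.RatingScale(config.scale_min, config.scale_max)

    if config.modality in ("pitch", "color"):
        if config.modality == "pitch":
            stim = st.generate_pitch_set(config.midi_lo, config.midi_hi, config.step_semitones)
            space = rsp.pitch_helix_space(stim, config.helix_radius, config.rise_per_semitone)
        else:
            stim = st.generate_color_set(st.EKMAN_WAVELENGTHS_NM[: config.n_colors]
                                         if config.n_colors <= 14 else st.EKMAN_WAVELENGTHS_NM)
            if config.extend_colors_to:
                stim = st.interpolate_color_set(stim, config.extend_colors_to)
            space = rsp.color_wheel_space(stim)
        (out / "stimuli.jsonl").write_text(stim.to_jsonl(), encoding="utf-8")
        log.add("stimuli", {"modality": config.modality}, {"n_stimuli": stim.size})

        respondent = rsp.SimilarityRespondent(
            space=space, tau=config.tau, noise_sd=config.noise_sd, scale=scale,
            seed=stage_seed(config.seed, "similarity_ratings"),
        )
        pairs = _pairs(list(stim.ids))
        records = rsp.simulate_similarity_ratings(respondent, pairs, config.repetitions)
        pio.write_ratings(records, out / "ratings.csv")
        log.add("respondents", {"tau": config.tau, "noise_sd": config.noise_sd,
                                "repetitions": config.repetitions},
                {"n_records": len(records)})

        M = sa.assemble_matrix(records, stim.ids, scale=(scale.min, scale.max))
        Msym = sa.symmetrize(M)
        pio.write_matrix(Msym, out / "similarity_matrix.csv")

        truth = sa.SimilarityMatrix(
            ids=stim.ids,
            values=_truth_matrix(space, stim.ids, config.tau),
            symmetric=True,
        )
        corr = (
            sa.bootstrap_correlation(records, truth,
                                     n_boot=config.n_boot,
                                     seed=stage_seed(config.seed, "bootstrap_correlation"))
            if config.n_boot > 0
            else sa.correlate_upper_triangles(Msym, truth)
        )
        log.add("correlation_vs_truth", {"n_boot": config.n_boot},
                {"r": corr.r, "ci_low": corr.ci_low, "ci_high": corr.ci_high,
                 "n_pairs": corr.n_pairs})

        outputs: dict[str, Any] = {}
        if config.modality == "pitch":
            smoothed = sa.smooth_toeplitz(Msym)
            pio.write_matrix(smoothed, out / "similarity_matrix_smoothed.csv")
            profile = sa.interval_profile(Msym)
            peak = sa.octave_peak(profile)
            _write_profile(profile, out / "interval_profile.csv")
            outputs.update({"octave_peak": peak.separation, "peak_contrast": peak.contrast})
            mds_input = smoothed
        else:
            mds_input = Msym
        k = config.mds_dimensions if config.modality == "pitch" else 2
        emb = sa.classical_mds(mds_input, k)
        _write_embedding(emb, out / "mds_coordinates.csv")
        rho = sa.procrustes_distance_correlation(emb, space)
        outputs.update({"mds_k": k, "distance_profile_r": rho})
        log.add("analysis", {"k": k}, outputs)

    elif config.modality == "naming":
        palette = st.generate_munsell_palette()
        (out / "palette.jsonl").write_text(palette.to_jsonl(), encoding="utf-8")
        maps = {}
        all_responses = {}
        for language in ("english", "russian"):
            respondent = rsp.NamingRespondent(
                language=language, temperature=config.naming_temperature,
                seed=stage_seed(config.seed, f"naming_{language}"),
            )
            responses = rsp.simulate_naming(respondent, palette, config.responses_per_chip)
            pio.write_naming(responses, out / f"naming_{language}.csv")
            nmap = nm.dominant_map(responses, palette)
            pio.write_naming_map(nmap, out / f"naming_map_{language}.jsonl")
            maps[language] = nmap
            all_responses[language] = responses
            log.add(f"naming_{language}",
                    {"responses_per_chip": config.responses_per_chip},
                    {"n_terms_used": len(nmap.terms)})
        if config.n_boot > 0:
            comp, lo, hi = nm.bootstrap_ari(
                all_responses["english"], all_responses["russian"], palette,
                n_boot=config.n_boot, seed=stage_seed(config.seed, "bootstrap_ari"),
            )
        else:
            comp = nm.adjusted_rand_index(maps["english"], maps["russian"])
            lo = hi = float("nan")
        log.add("cross_language_ari", {"n_boot": config.n_boot},
                {"ari": comp.ari, "ri": comp.ri, "ci_low": lo, "ci_high": hi})
    else:
        raise ValueError(f"unknown modality {config.modality!r}")

    (out / "run_log.json").write_text(
        json.dumps(log.summary(), indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
    return log


def _truth_matrix(space, ids, tau):
    import numpy as np

    n = len(ids)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = float(np.exp(-space.distance(ids[i], ids[j]) / tau))
            m[i, j] = m[j, i] = s
    return m


def _write_profile(profile, path) -> None:
    import pandas as pd

    pd.DataFrame({
        "separation": profile.separations,
        "mean_similarity": profile.mean_similarity,
        "pair_count": profile.pair_counts,
    }).to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def _write_embedding(emb, path) -> None:
    import pandas as pd

    df = pd.DataFrame(emb.coordinates, index=list(emb.ids),
                      columns=[f"dim{i+1}" for i in range(emb.coordinates.shape[1])])
    df.index.name = "stimulus_id"
    df.to_csv(path, float_format="%.12g", lineterminator="\n")
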