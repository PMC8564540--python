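"""Recording eligibility, stitching, and clip standardization.

The protocol mirrors how a community archive is curated for playback:
keep grade-"A" files longer than 30 s whose type is song, call or
drumming (excluding wingbeat/flap/begging/alarm/night variants); cap at
50 files per species (random subset); if nothing long enough exists,
fall back to the shorter files that meet the quality/type rules and
stitch repeats of each until it exceeds 30 s. Every surviving file is
then cut to seconds [2.5, 27.5), downmixed to mono, resampled to
44.1 kHz and peak-normalized to -6 dBFS, yielding the fixed 25 s
standard clip that represents one singing individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .audio import (
    PEAK_MINUS_6_DB,
    STANDARD_CLIP_SAMPLES,
    STANDARD_RATE,
    AudioClip,
    StandardClip,
    read_wav,
)
from .errors import NoRecordingsError, ParameterError, SilentClipError

#: Vocalisation types accepted for soundscape construction.
ALLOWED_TYPE_TERMS = ("song", "call", "drumming")

#: Terms whose presence in the type string excludes a recording.
EXCLUDED_TYPE_TERMS = ("wingbeat", "flap", "begging", "alarm", "night")

#: Minimum source duration (seconds) for direct standardization.
MIN_SOURCE_DURATION_S = 30.0

_CUT_START_S = 2.5
_CUT_END_S = 27.5


def _type_eligible(vocal_type: str) -> bool:
    t = str(vocal_type).lower()
    if any(term in t for term in EXCLUDED_TYPE_TERMS):
        return False
    return any(term in t for term in ALLOWED_TYPE_TERMS)


def select_recordings(
    manifest: pd.DataFrame,
    species_code: str,
    region: str | None = None,
    max_files: int = 50,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, bool]:
    """Apply the eligibility rules for one species.

    Returns ``(rows, fallback)``. ``fallback`` is True when no file
    longer than 30 s survived and the shorter quality/type-compliant
    files are returned instead (they must be stitched before use).

    Raises
    ------
    NoRecordingsError
        If the species is absent from the manifest (or no file passes
        even the fallback rules); its sites must be dropped upstream.
    """
    if manifest.empty:
        raise ParameterError("manifest is empty")
    rows = manifest[manifest["species_code"] == species_code]
    if region is not None:
        rows = rows[rows["region"] == region]
    if rows.empty:
        raise NoRecordingsError(species_code)
    ok = rows[(rows["quality"] == "A") & rows["vocal_type"].map(_type_eligible)]
    eligible = ok[ok["duration_s"] > MIN_SOURCE_DURATION_S]
    fallback = False
    if eligible.empty:
        eligible = ok[ok["duration_s"] <= MIN_SOURCE_DURATION_S]
        fallback = True
        if eligible.empty:
            raise NoRecordingsError(species_code)
    if len(eligible) > max_files:
        rng = rng if rng is not None else np.random.default_rng()
        idx = rng.choice(len(eligible), size=max_files, replace=False)
        eligible = eligible.iloc[np.sort(idx)]
    return eligible.reset_index(drop=True), fallback


def stitch_to_min_duration(clips: list[AudioClip], min_s: float = 30.0) -> AudioClip:
    """Cyclically concatenate clips until the total exceeds ``min_s``.

    The clip sequence is repeated in order; the output duration is
    strictly greater than ``min_s`` and grows by whole clips only.
    """
    if not clips:
        raise ParameterError("cannot stitch an empty clip list")
    rate = clips[0].sample_rate_hz
    if any(c.sample_rate_hz != rate for c in clips):
        raise ParameterError("all clips must share one sample rate")
    if any(not c.is_mono for c in clips):
        raise ParameterError("stitching expects mono clips")
    if sum(c.n_samples for c in clips) == 0:
        raise ParameterError("total input duration must be positive")
    parts: list[np.ndarray] = []
    total = 0
    i = 0
    min_samples = min_s * rate
    while total <= min_samples:
        part = clips[i % len(clips)].samples
        parts.append(part)
        total += part.size
        i += 1
    return AudioClip(samples=np.concatenate(parts), sample_rate_hz=rate)


def standardize_clip(clip: AudioClip, file_id: str = "") -> StandardClip:
    """Cut, downmix, resample and normalize a clip to the standard form.

    Keeps seconds [2.5, 27.5) of the source (so the source must last at
    least 27.5 s), averages channels to mono, resamples to 44.1 kHz with
    a polyphase FIR anti-aliasing filter, and rescales the peak to
    -6 dBFS (linear 0.50119).
    """
    sr = clip.sample_rate_hz
    if clip.duration_s < _CUT_END_S - 1e-9:
        raise ParameterError(
            f"clip lasts {clip.duration_s:.2f} s; standardization needs >= {_CUT_END_S} s "
            "(stitch shorter files first)"
        )
    x = clip.samples
    if x.ndim == 2:
        x = x.mean(axis=1)
    x = x[int(_CUT_START_S * sr) : int(_CUT_END_S * sr)]
    if sr != STANDARD_RATE:
        frac = Fraction(STANDARD_RATE, sr).limit_denominator(10000)
        x = resample_poly(x, frac.numerator, frac.denominator)
    if x.size < STANDARD_CLIP_SAMPLES:
        x = np.pad(x, (0, STANDARD_CLIP_SAMPLES - x.size))
    else:
        x = x[:STANDARD_CLIP_SAMPLES]
    peak = np.max(np.abs(x))
    if peak == 0.0:
        raise SilentClipError("cannot normalize a silent clip")
    x = x * (PEAK_MINUS_6_DB / peak)
    return StandardClip(samples=x, sample_rate_hz=STANDARD_RATE, file_id=file_id)


@dataclass
class ClipLibrary:
    """Standardized clips grouped by species, ready for insertion."""

    clips: dict[str, list[StandardClip]] = field(default_factory=dict)

    @property
    def species(self) -> set[str]:
        return set(self.clips)

    def add(self, species_code: str, clip: StandardClip) -> None:
        self.clips.setdefault(species_code, []).append(clip)

    def get(self, species_code: str) -> list[StandardClip]:
        try:
            return self.clips[species_code]
        except KeyError:
            raise NoRecordingsError(species_code) from None

    def n_clips(self, species_code: str | None = None) -> int:
        if species_code is not None:
            return len(self.clips.get(species_code, []))
        return sum(len(v) for v in self.clips.values())


def build_clip_library(
    manifest: pd.DataFrame,
    species: list[str] | None = None,
    region: str | None = None,
    max_files: int = 50,
    seed: int = 0,
    base_dir: str | Path | None = None,
) -> tuple[ClipLibrary, list[str]]:
    """Select, load and standardize clips for a set of species.

    Fallback (short) files are each stitched from repeats of themselves
    before standardization. Returns the library and the list of species
    for which no usable recording existed (their sites are dropped by
    the inclusion filters).
    """
    wanted = species if species is not None else sorted(manifest["species_code"].unique())
    lib = ClipLibrary()
    missing: list[str] = []
    for sp in wanted:
        rng = np.random.default_rng(_subset_seed(seed, sp))
        try:
            rows, fallback = select_recordings(manifest, sp, region=region, max_files=max_files, rng=rng)
        except NoRecordingsError:
            missing.append(sp)
            continue
        for _, row in rows.iterrows():
            path = Path(row["path"])
            if base_dir is not None and not path.is_absolute():
                path = Path(base_dir) / path
            raw = read_wav(path)
            if fallback:
                raw = stitch_to_min_duration([raw], min_s=MIN_SOURCE_DURATION_S)
            try:
                lib.add(sp, standardize_clip(raw, file_id=str(row["file_id"])))
            except SilentClipError:
                continue
        if lib.n_clips(sp) == 0:
            missing.append(sp)
    return lib, missing


def _subset_seed(seed: int, species_code: str) -> int:
    from ._seeds import child_seed

    return child_seed(seed, "select", species_code)
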