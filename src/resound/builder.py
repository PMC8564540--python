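"""Soundscape construction: random-time, random-gain clip insertion.

A soundscape is built on an initially empty (all-zero) canvas, 5 min by
default. For every counted individual of every species in a site-year
community, one of that species' standardized clips is chosen uniformly,
given a random playback gain (emulating the bird's distance to the
surveyor) and added at a uniformly random start time. Mixing is a plain
floating-point sum with no clipping or limiting, so the canvas is an
exact linear superposition of its insertions; indices are computed on
the floating-point canvas directly, and any rescaling happens only on
WAV export.

Per (site, year, iteration) random substreams make the whole panel
bit-reproducible from one master seed and safe to rebuild partially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg.blas import daxpy

from ._seeds import child_rng
from .audio import AudioClip, write_wav
from .errors import NoRecordingsError, ParameterError
from .indices import AcousticIndices, IndexConfig, compute_all_indices
from .standardize import ClipLibrary


@dataclass(frozen=True)
class UniformGain:
    """Uniform playback amplitude on [lo, hi]."""

    lo: float = 0.05
    hi: float = 1.0

    def validate(self) -> None:
        if not (0.0 < self.lo <= self.hi <= 1.0):
            raise ParameterError("uniform gain needs 0 < lo <= hi <= 1")

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))


@dataclass(frozen=True)
class HalfNormalGain:
    """|N(0, scale)| clipped to [floor, cap]: mass concentrated near quiet.

    Emulates a larger share of distant vocalisations than the uniform
    default.
    """

    scale: float = 0.4
    floor: float = 0.01
    cap: float = 1.0

    def validate(self) -> None:
        if self.scale <= 0 or not (0.0 < self.floor <= self.cap <= 1.0):
            raise ParameterError("half-normal gain needs scale > 0 and 0 < floor <= cap <= 1")

    def draw(self, rng: np.random.Generator) -> float:
        return float(np.clip(abs(rng.normal(0.0, self.scale)), self.floor, self.cap))


GainDist = UniformGain | HalfNormalGain


def draw_gain(gain_dist: GainDist, rng: np.random.Generator) -> float:
    """One playback gain in (0, 1] from the given distribution."""
    if not isinstance(gain_dist, (UniformGain, HalfNormalGain)):
        raise ParameterError(f"unknown gain distribution {gain_dist!r}")
    gain_dist.validate()
    return gain_dist.draw(rng)


@dataclass(frozen=True)
class SoundscapeParams:
    """Construction-rule parameters (the paper-protocol defaults)."""

    canvas_s: float = 300.0
    clip_s: float = 25.0
    gain: GainDist = field(default_factory=UniformGain)
    sample_rate_hz: int = 44100
    n_iter: int = 5

    def validate(self) -> None:
        if self.canvas_s < self.clip_s:
            raise ParameterError("canvas_s must be >= clip_s")
        if self.n_iter < 1:
            raise ParameterError("n_iter must be >= 1")
        if self.sample_rate_hz < 8000:
            raise ParameterError("sample_rate_hz must be >= 8000")
        draw_gain(self.gain, np.random.default_rng(0))  # validates the dist


@dataclass(frozen=True)
class SiteYearCommunity:
    """Counts of individuals per species at one site in one year."""

    site_id: str
    year: int
    composition: dict[str, int]

    def validate(self) -> None:
        if any(c < 1 for c in self.composition.values()):
            raise ParameterError("all counts must be >= 1")

    @property
    def total_individuals(self) -> int:
        return sum(self.composition.values())


@dataclass(frozen=True)
class InsertionEvent:
    species_code: str
    file_id: str
    start_s: float
    gain: float


@dataclass
class Soundscape:
    """The composite canvas plus full insertion provenance."""

    clip: AudioClip
    events: list[InsertionEvent]
    site_id: str = ""
    year: int = 0
    iteration: int = 0


def build_soundscape(
    community: SiteYearCommunity,
    library: ClipLibrary,
    params: SoundscapeParams,
    rng: np.random.Generator,
) -> Soundscape:
    """Mix one soundscape for a site-year community.

    For each individual (species in composition order, individuals in
    count order) the generator draws, in this order: a clip index, a
    start time uniform on [0, canvas_s - clip_s], and a gain. The clip
    scaled by the gain is summed into the canvas.
    """
    params.validate()
    community.validate()
    sr = params.sample_rate_hz
    n_canvas = int(round(params.canvas_s * sr))
    canvas = np.zeros(n_canvas)
    events: list[InsertionEvent] = []
    if not community.composition:
        warnings.warn(
            f"empty community at {community.site_id}/{community.year}: silent soundscape",
            stacklevel=2,
        )
        return Soundscape(AudioClip(canvas, sr), events, community.site_id, community.year)
    for species, count in community.composition.items():
        clips = library.get(species)  # raises NoRecordingsError if absent
        for _ in range(count):
            idx = int(rng.integers(len(clips)))
            clip = clips[idx]
            if clip.n_samples > n_canvas:
                raise ParameterError("clip longer than canvas")
            max_start = params.canvas_s - clip.n_samples / sr
            start_s = float(rng.uniform(0.0, max_start))
            gain = draw_gain(params.gain, rng)
            i0 = min(int(round(start_s * sr)), n_canvas - clip.n_samples)
            # fused in-place y += a*x on the canvas slice
            daxpy(clip.samples, canvas[i0 : i0 + clip.n_samples], a=gain)
            events.append(InsertionEvent(species, clip.file_id, start_s, gain))
    return Soundscape(AudioClip(canvas, sr), events, community.site_id, community.year)


def resynthesize_from_provenance(
    soundscape: Soundscape, library: ClipLibrary, params: SoundscapeParams
) -> AudioClip:
    """Rebuild the canvas purely from recorded events (mixing is linear)."""
    sr = params.sample_rate_hz
    n_canvas = int(round(params.canvas_s * sr))
    canvas = np.zeros(n_canvas)
    for ev in soundscape.events:
        clip = next(c for c in library.get(ev.species_code) if c.file_id == ev.file_id)
        i0 = min(int(round(ev.start_s * sr)), n_canvas - clip.n_samples)
        daxpy(clip.samples, canvas[i0 : i0 + clip.n_samples], a=ev.gain)
    return AudioClip(canvas, sr)


def communities_from_counts(counts: pd.DataFrame) -> list[SiteYearCommunity]:
    """Group a count table into per-site-year communities."""
    out = []
    for (site, year), grp in counts.groupby(["site_id", "year"], sort=True):
        comp = dict(zip(grp["species_code"], grp["count"].astype(int)))
        out.append(SiteYearCommunity(site_id=str(site), year=int(year), composition=comp))
    return out


def build_index_panel(
    counts: pd.DataFrame,
    library: ClipLibrary,
    params: SoundscapeParams,
    index_config: IndexConfig | None = None,
    master_seed: int = 0,
    index_fn=None,
    export_dir=None,
) -> pd.DataFrame:
    """Per-site-year acoustic indices averaged over construction iterations.

    Builds ``params.n_iter`` independent soundscapes for every site-year
    community (each on its own seed substream), computes all four
    indices on each, and stores the arithmetic mean per index. Site
    metadata (coordinates, stratum, route) is carried through for the
    trend stage. ``index_fn`` may replace the default index computation;
    ``export_dir`` saves the final iteration of each site-year as WAV.
    """
    if index_fn is None:
        cfg = index_config or IndexConfig()
        index_fn = lambda clip: compute_all_indices(clip, cfg)  # noqa: E731
    meta_cols = [c for c in ("latitude", "longitude", "stratum", "route") if c in counts.columns]
    meta = counts.groupby("site_id", sort=True)[meta_cols].first() if meta_cols else None
    rows = []
    for community in communities_from_counts(counts):
        sums = {"adi": 0.0, "aei": 0.0, "bi": 0.0, "h": 0.0}
        last = None
        for it in range(params.n_iter):
            rng = child_rng(master_seed, "soundscape", community.site_id, community.year, it)
            scape = build_soundscape(community, library, params, rng)
            scape.iteration = it
            idx = index_fn(scape.clip)
            if isinstance(idx, AcousticIndices):
                if idx.degenerate and community.total_individuals > 0:
                    raise FloatingPointError(
                        f"degenerate indices from a non-silent soundscape at "
                        f"{community.site_id}/{community.year}"
                    )
                vals = idx.as_dict()
            else:
                vals = dict(idx)
            for k in sums:
                if not np.isfinite(vals[k]):
                    raise FloatingPointError(
                        f"non-finite {k} at {community.site_id}/{community.year}"
                    )
                sums[k] += vals[k]
            last = scape
        if export_dir is not None and last is not None:
            out = last.clip.samples
            peak = np.max(np.abs(out)) if out.size else 0.0
            if peak > 1.0:  # export-only rescale; indices always use the raw sum
                out = out / peak
            write_wav(
                f"{export_dir}/{community.site_id}_{community.year}.wav",
                AudioClip(out, last.clip.sample_rate_hz),
            )
        row = {
            "site_id": community.site_id,
            "year": community.year,
            **{k: v / params.n_iter for k, v in sums.items()},
            "n_iter": params.n_iter,
            "seed": master_seed,
        }
        if meta is not None and community.site_id in meta.index:
            row.update(meta.loc[community.site_id].to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
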