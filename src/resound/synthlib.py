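"""Synthetic recording library and synthetic count datasets.

This module emulates the two external data sources the pipeline is built
around: a community sound archive (per-species recordings with
xeno-canto-style metadata) and long-running breeding-bird count schemes
(site-year-species count tables with coordinates and strata).

Species recordings are syllable trains of linear frequency sweeps with a
small number of harmonics at -6 dB per harmonic, interspersed with
silence, over a low uniform noise floor plus occasional soft background
chirps at random frequencies (field recordings always carry other
species and ambient sound in the background). Distinct carrier frequencies
across species give each species its own slice of spectrum, so that the
band-occupancy indices respond to community composition. Per-file jitter
(carrier +/-3 %, syllable length +/-10 %) stands in for
between-individual variation in song structure.

Count datasets follow per-site log-linear trends in species richness and
per-species abundance, with site-specific rates drawn around the design
rates and zero-truncated Poisson noise on realized counts (count tables
only list detected species, so every listed count is >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import child_rng, child_seed
from .audio import AudioClip, write_wav
from .errors import ParameterError

COUNT_COLUMNS = [
    "site_id",
    "year",
    "species_code",
    "count",
    "latitude",
    "longitude",
    "stratum",
    "route",
]

MANIFEST_COLUMNS = [
    "file_id",
    "species_code",
    "duration_s",
    "quality",
    "vocal_type",
    "region",
    "path",
]

_VOCAL_TYPE_WEIGHTS = {
    "song": 0.60,
    "call": 0.25,
    "drumming": 0.05,
    "alarm": 0.05,
    "night": 0.05,
}


@dataclass(frozen=True)
class SongSpec:
    """Parameters of one species' synthetic vocalisation.

    ``duty_cycle`` is the fraction of a recording occupied by syllables;
    ``noise_floor`` the peak linear amplitude of the background noise.
    """

    species_code: str
    f0: float
    bandwidth: float = 500.0
    n_harmonics: int = 1
    syllable_dur: float = 0.15
    gap_dur: float = 0.0  # derived from duty_cycle when 0
    duty_cycle: float = 0.4
    noise_floor: float = 0.002
    #: soft random background chirps (other species, ambient sound) per
    #: second; field recordings are never acoustically clean
    background_rate: float = 1.2
    background_level: float = 0.06
    #: optional broadband attack transient at each syllable onset,
    #: relative to the syllable amplitude (off by default)
    attack_level: float = 0.0

    def validate(self) -> None:
        if self.f0 <= 0:
            raise ParameterError("f0 must be positive")
        if self.bandwidth < 0 or self.syllable_dur <= 0:
            raise ParameterError("bandwidth must be >= 0 and syllable_dur > 0")
        if not (0.0 < self.duty_cycle <= 1.0):
            raise ParameterError("duty_cycle must be in (0, 1]")
        if not (0.0 <= self.noise_floor <= 0.05):
            raise ParameterError("noise_floor must be in [0, 0.05]")
        if self.n_harmonics < 0:
            raise ParameterError("n_harmonics must be >= 0")
        if self.f0 + self.bandwidth + self.n_harmonics * self.f0 >= 22050.0:
            raise ParameterError("spectral content must stay below the 22.05 kHz Nyquist")
        if self.background_rate < 0 or not (0.0 <= self.background_level < 0.3):
            raise ParameterError("background_rate >= 0 and background_level in [0, 0.3) required")
        if not (0.0 <= self.attack_level <= 1.0):
            raise ParameterError("attack_level must be in [0, 1]")


@dataclass(frozen=True)
class CountDesign:
    """Design of a synthetic multi-site count dataset.

    Trends are multiplicative per-year rates (1.0 = stationary,
    0.98 = 2 %/yr decline); ``site_trend_sd`` is the standard deviation
    of per-site log-rates around the design log-rate.
    """

    n_sites: int = 100
    years: tuple[int, int] = (2000, 2009)
    base_richness: int = 12
    base_abundance: float = 3.0
    richness_trend: float = 1.0
    abundance_trend: float = 1.0
    site_trend_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ParameterError("n_sites must be >= 1")
        if self.years[1] - self.years[0] + 1 < 3:
            raise ParameterError("need at least 3 years for downstream inclusion rules")
        if self.base_richness < 1 or self.base_abundance <= 0:
            raise ParameterError("base_richness >= 1 and base_abundance > 0 required")
        if self.richness_trend <= 0 or self.abundance_trend <= 0:
            raise ParameterError("trend rates must be > 0")
        if self.site_trend_sd < 0:
            raise ParameterError("site_trend_sd must be >= 0")


def synthesize_species_recording(
    spec: SongSpec,
    duration_s: float,
    sample_rate_hz: int = 44100,
    seed: int = 0,
) -> AudioClip:
    """Render one synthetic recording of a species.

    The output is a periodic syllable train (random phase offset and
    per-syllable amplitude jitter, deterministic given ``seed``): each
    syllable is a linear sweep from ``f0`` to ``f0 + bandwidth`` with
    ``n_harmonics`` overtones at -6 dB per harmonic, under a Hann
    envelope. Syllable spacing is ``syllable_dur / duty_cycle``, so the
    fraction of samples inside syllables approximates the duty cycle.
    """
    spec.validate()
    if duration_s < 1:
        raise ParameterError("duration_s must be >= 1")
    if sample_rate_hz < 8000:
        raise ParameterError("sample_rate_hz must be >= 8000")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    x = _colored_noise(rng, n, sample_rate_hz, spec.noise_floor)

    period = spec.syllable_dur / spec.duty_cycle
    ns = int(round(spec.syllable_dur * sample_rate_hz))
    ns = min(ns, n)
    tt = np.arange(ns) / sample_rate_hz
    sweep_rate = spec.bandwidth / spec.syllable_dur
    phase = 2.0 * np.pi * (spec.f0 * tt + 0.5 * sweep_rate * tt * tt)
    nyquist = sample_rate_hz / 2.0
    proto = np.zeros(ns)
    for k in range(1, spec.n_harmonics + 2):  # fundamental + n_harmonics overtones
        if k * (spec.f0 + spec.bandwidth) >= nyquist:
            break
        proto += 10.0 ** (-6.0 * (k - 1) / 20.0) * np.sin(k * phase)
    proto *= np.hanning(ns)
    peak = np.max(np.abs(proto))
    if peak > 0:
        proto /= peak

    offset = rng.uniform(0.0, max(period - spec.syllable_dur, 1e-6))
    t0 = offset
    while t0 + spec.syllable_dur <= duration_s + 1e-12:
        i0 = int(round(t0 * sample_rate_hz))
        seg = min(ns, n - i0)
        if seg <= 0:
            break
        amp = 0.7 * rng.uniform(0.75, 1.0)
        x[i0 : i0 + seg] += amp * proto[:seg]
        if spec.attack_level > 0:
            # broadband onset transient shared by all species' spectra
            na = min(seg, max(int(round(0.25 * ns)), 8))
            burst = rng.normal(0.0, 1.0, na)
            x[i0 : i0 + na] += amp * spec.attack_level * 0.33 * np.hanning(na) * burst
        t0 += period

    # soft background chirps at random frequencies: the inevitable other
    # species / ambient sounds of a field recording
    n_bg = rng.poisson(spec.background_rate * duration_s)
    for _ in range(n_bg):
        bg_dur = float(rng.uniform(0.08, 0.35))
        nb = max(int(round(bg_dur * sample_rate_hz)), 8)
        t_bg = float(rng.uniform(0.0, max(duration_s - bg_dur, 1e-6)))
        f_bg = float(rng.uniform(600.0, min(9500.0, 0.45 * sample_rate_hz)))
        amp = spec.background_level * float(rng.uniform(0.5, 1.5))
        i0 = int(round(t_bg * sample_rate_hz))
        seg = min(nb, n - i0)
        if seg <= 0:
            continue
        tb = np.arange(seg) / sample_rate_hz
        x[i0 : i0 + seg] += amp * np.hanning(seg) * np.sin(2.0 * np.pi * f_bg * tb)

    peak = np.max(np.abs(x))
    if peak > 1.0:
        x /= peak
    return AudioClip(samples=x, sample_rate_hz=sample_rate_hz)


def draw_species_specs(n_species: int, rng: np.random.Generator) -> list[SongSpec]:
    """One :class:`SongSpec` per species, with distinct carriers.

    Carriers are an evenly spaced ladder over 1.6-8.8 kHz (shuffled), so
    any two species occupy different parts of the band-occupancy range.
    """
    if n_species < 1:
        raise ParameterError("n_species must be >= 1")
    carriers = np.linspace(1500.0, 6500.0, n_species) if n_species > 1 else np.array([3000.0])
    carriers = rng.permutation(carriers)
    specs = []
    for i, f0 in enumerate(carriers):
        # broad sweeps + harmonics: songbird energy spans several kHz and
        # overlaps heavily between species
        bw = rng.uniform(500.0, 2000.0)
        n_h = int(rng.integers(1, 4))
        while n_h > 0 and (f0 + bw + n_h * f0) >= 21500.0:
            n_h -= 1
        specs.append(
            SongSpec(
                species_code=f"SP{i + 1:03d}",
                f0=float(f0),
                bandwidth=float(bw),
                n_harmonics=n_h,
                syllable_dur=float(rng.uniform(0.08, 0.30)),
                # wide behavioral spread: species range from sparse callers
                # to near-continuous singers, as real communities do
                duty_cycle=float(rng.uniform(0.15, 0.90)),
                noise_floor=float(rng.uniform(0.005, 0.035)),
                background_rate=float(rng.uniform(0.3, 2.0)),
                background_level=float(rng.uniform(0.02, 0.10)),
            )
        )
    return specs


def build_recording_library(
    n_species: int,
    files_per_species: int,
    duration_range: tuple[float, float] = (31.0, 40.0),
    sample_rate_hz: int = 44100,
    out_dir: str | Path = "library",
    seed: int = 0,
    quality_downgrade_frac: float = 0.1,
    vocal_type_weights: dict[str, float] | None = None,
    region: str = "region-1",
) -> pd.DataFrame:
    """Render a full recording library to WAV and return its manifest.

    Each file is a jittered copy of its species' spec (carrier +/-3 %,
    syllable duration +/-10 %) with its own duration drawn from
    ``duration_range``. A ``quality_downgrade_frac`` fraction of files
    get a random quality grade in B-E instead of the default "A";
    vocalisation types are drawn with ``vocal_type_weights``.
    """
    if files_per_species < 1:
        raise ParameterError("files_per_species must be >= 1")
    if duration_range[0] < 1 or duration_range[0] > duration_range[1]:
        raise ParameterError("invalid duration_range")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create library directory {out_dir}: {exc}") from exc

    weights = vocal_type_weights or _VOCAL_TYPE_WEIGHTS
    types = list(weights)
    probs = np.array([weights[t] for t in types], dtype=float)
    probs /= probs.sum()

    specs = draw_species_specs(n_species, child_rng(seed, "species-specs"))
    rows = []
    for sp in specs:
        for j in range(files_per_species):
            rng = child_rng(seed, "file", sp.species_code, j)
            jittered = replace(
                sp,
                f0=sp.f0 * (1.0 + rng.uniform(-0.03, 0.03)),
                syllable_dur=sp.syllable_dur * (1.0 + rng.uniform(-0.10, 0.10)),
            )
            dur = float(rng.uniform(*duration_range))
            clip = synthesize_species_recording(
                jittered,
                dur,
                sample_rate_hz,
                seed=child_seed(seed, "render", sp.species_code, j),
            )
            file_id = f"{sp.species_code}_{j:03d}"
            path = out_dir / sp.species_code / f"{file_id}.wav"
            write_wav(path, clip)
            quality = "A"
            if rng.uniform() < quality_downgrade_frac:
                quality = str(rng.choice(["B", "C", "D", "E"]))
            vocal_type = str(rng.choice(types, p=probs))
            rows.append(
                {
                    "file_id": file_id,
                    "species_code": sp.species_code,
                    "duration_s": clip.duration_s,
                    "quality": quality,
                    "vocal_type": vocal_type,
                    "region": region,
                    "path": str(path),
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _colored_noise(
    rng: np.random.Generator, n: int, sample_rate_hz: int, peak: float, alpha: float = 1.8
) -> np.ndarray:
    """Sloped (1/f^alpha amplitude) ambient noise, peak-normalized.

    Field recordings carry colored background noise (wind, air, handling
    rumble) whose level falls smoothly with frequency; the smooth slope
    means every frequency band holds some content near any amplitude
    threshold, as in real spectra.
    """
    if peak <= 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    shape = (np.maximum(f, 150.0) / 1000.0) ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    m = np.max(np.abs(x))
    x = x * (peak / m) if m > 0 else x
    # faint wideband microphone self-noise, far below the ambient slope
    # (sits at the edge of the 16-bit dynamic range in a lone recording)
    x += (peak * 1.5e-3) * rng.standard_normal(n)
    return x


def _zero_truncated_poisson(rng: np.random.Generator, mu: float) -> int:
    """Poisson(mu) conditioned on being positive."""
    for _ in range(1000):
        k = int(rng.poisson(mu))
        if k > 0:
            return k
    return 1  # mu astronomically small; the species is present, so count 1


def simulate_count_dataset(design: CountDesign, species_pool: list[str]) -> pd.DataFrame:
    """Simulate a site x year x species count table.

    Sites sit on a regular lat/lon grid split into four quadrant strata.
    Each site gets its own species ordering (a permutation of the pool)
    and its own log-linear richness and abundance rates; in a year with
    realized richness r the first r species of the ordering are present,
    so declining richness drops species in a stable order. Realized
    counts are zero-truncated Poisson draws about the latent means.
    """
    design.validate()
    if len(species_pool) < design.base_richness:
        raise ParameterError(
            f"species pool ({len(species_pool)}) smaller than base_richness "
            f"({design.base_richness})"
        )
    y0, y1 = design.years
    years = range(y0, y1 + 1)
    n_cols = int(np.ceil(np.sqrt(design.n_sites)))
    n_rows = int(np.ceil(design.n_sites / n_cols))
    rows = []
    for s in range(design.n_sites):
        site_id = f"site{s + 1:04d}"
        gr, gc = divmod(s, n_cols)
        lat = 35.0 + (25.0 * gr / max(n_rows - 1, 1))
        lon = -10.0 + (40.0 * gc / max(n_cols - 1, 1))
        stratum = f"ST{1 + 2 * int(gr >= n_rows / 2) + int(gc >= n_cols / 2)}"
        rng = child_rng(design.seed, "counts", site_id)
        order = rng.permutation(np.asarray(species_pool, dtype=object))
        r_rate = float(np.exp(np.log(design.richness_trend) + rng.normal(0.0, design.site_trend_sd)))
        a_rate = float(np.exp(np.log(design.abundance_trend) + rng.normal(0.0, design.site_trend_sd)))
        for t, year in enumerate(years):
            latent_r = design.base_richness * r_rate**t
            r = int(min(len(order), max(1, round(latent_r))))
            mu = design.base_abundance * a_rate**t
            for code in order[:r]:
                rows.append(
                    {
                        "site_id": site_id,
                        "year": int(year),
                        "species_code": str(code),
                        "count": _zero_truncated_poisson(rng, mu),
                        "latitude": lat,
                        "longitude": lon,
                        "stratum": stratum,
                        "route": "",
                    }
                )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)
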