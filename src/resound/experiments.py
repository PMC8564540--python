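"""Simulated-community experiments and their regression summaries.

Three experiment drivers:

* a single-species abundance sweep (1-10, 20, 30, 40, 50 conspecific
  individuals per soundscape),
* a richness x abundance grid (communities of r species, each at a
  individuals, species drawn at random from the pool), and
* a construction-rule sensitivity experiment: communities of ten
  species declining from 10 to 5 individuals each over six years, built
  under four alternative construction rules (5/3/10-minute canvases
  with uniform gains, and a 5-minute canvas with half-normal gains).

Regression summaries are ordinary least squares on per-cell iteration
means: mean index ~ log(individuals) [+ log(species) + interaction],
with the interaction dropped and the model refitted when its p-value
is at or above 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._seeds import child_rng
from .builder import HalfNormalGain, SiteYearCommunity, SoundscapeParams, build_soundscape
from .errors import FitError, ParameterError
from .indices import IndexConfig, compute_all_indices
from .standardize import ClipLibrary

DEFAULT_SWEEP_ABUNDANCES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20, 30, 40, 50)
DEFAULT_RICHNESS_LEVELS = (2, 3, 4, 5, 10, 20, 50)
DEFAULT_GRID_ABUNDANCES = tuple(range(1, 11))


@dataclass
class SimFit:
    """An OLS summary: per-term estimate/SE/t/p plus the retention flag."""

    terms: pd.DataFrame
    interaction_retained: bool
    response: str

    def estimate(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "p"])


def _score(clip, cfg: IndexConfig):
    return compute_all_indices(clip, cfg).as_dict()


def run_single_species_sweep(
    library: ClipLibrary,
    abundances: tuple[int, ...] = DEFAULT_SWEEP_ABUNDANCES,
    n_iter: int = 1000,
    params: SoundscapeParams | None = None,
    index_config: IndexConfig | None = None,
    seed: int = 0,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Indices of soundscapes holding n conspecific individuals.

    One soundscape per species x abundance x iteration, with clip
    choice, insertion time and gain re-randomized every iteration.
    """
    params = params or SoundscapeParams()
    cfg = index_config or IndexConfig()
    pool = species if species is not None else sorted(library.species)
    if not pool:
        raise ParameterError("empty species pool")
    rows = []
    for sp in pool:
        if library.n_clips(sp) == 0:
            import warnings

            warnings.warn(f"species {sp} has no clips; skipped", stacklevel=2)
            continue
        for a in abundances:
            for it in range(n_iter):
                rng = child_rng(seed, "sweep", sp, a, it)
                community = SiteYearCommunity("sweep", 0, {sp: int(a)})
                scape = build_soundscape(community, library, params, rng)
                rows.append(
                    {"species": sp, "abundance": int(a), "iteration": it, **_score(scape.clip, cfg)}
                )
    return pd.DataFrame(rows)


def run_richness_abundance_grid(
    library: ClipLibrary,
    richness_levels: tuple[int, ...] = DEFAULT_RICHNESS_LEVELS,
    abundance_levels: tuple[int, ...] = DEFAULT_GRID_ABUNDANCES,
    n_iter: int = 100,
    params: SoundscapeParams | None = None,
    index_config: IndexConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Indices over a species-richness x per-species-abundance grid.

    Each iteration draws its own random species subset (without
    replacement) from the library pool; provenance (the species drawn)
    is retained in the ``species_drawn`` column.
    """
    params = params or SoundscapeParams()
    cfg = index_config or IndexConfig()
    pool = sorted(library.species)
    if not richness_levels or not abundance_levels:
        raise ParameterError("richness and abundance level sets must be non-empty")
    if max(richness_levels) > len(pool):
        raise ParameterError(
            f"max richness {max(richness_levels)} exceeds pool size {len(pool)}"
        )
    rows = []
    for r in richness_levels:
        for a in abundance_levels:
            for it in range(n_iter):
                rng = child_rng(seed, "grid", r, a, it)
                drawn = [str(s) for s in rng.choice(pool, size=int(r), replace=False)]
                community = SiteYearCommunity("grid", 0, {sp: int(a) for sp in drawn})
                scape = build_soundscape(community, library, params, rng)
                rows.append(
                    {
                        "richness": int(r),
                        "abundance": int(a),
                        "iteration": it,
                        "species_drawn": ";".join(drawn),
                        **_score(scape.clip, cfg),
                    }
                )
    return pd.DataFrame(rows)


def fit_simulation_model(
    table: pd.DataFrame,
    response: str,
    include_species: bool = False,
    alpha: float = 0.05,
) -> SimFit:
    """OLS of per-cell mean index on log abundance (and log richness).

    Cells are (species, abundance) for sweep output and (richness,
    abundance) for grid output; the response is the cell mean across
    iterations. With ``include_species`` the model carries
    ``log_individuals + log_species + interaction`` and the interaction
    is dropped (model refitted) when its p-value is >= ``alpha``.
    """
    if response not in table.columns:
        raise ParameterError(f"response {response!r} not in table")
    if include_species:
        if table["richness"].nunique() < 2 or table["abundance"].nunique() < 2:
            raise ParameterError("need >= 2 distinct richness and abundance levels")
        cells = table.groupby(["richness", "abundance"], as_index=False)[response].mean()
        logi = np.log(cells["abundance"].to_numpy(float))
        logs = np.log(cells["richness"].to_numpy(float))
        names = ["intercept", "log_individuals", "log_species", "interaction"]
        X = np.column_stack([np.ones_like(logi), logi, logs, logi * logs])
    else:
        if table["abundance"].nunique() < 2:
            raise ParameterError("need >= 2 distinct abundance levels")
        keys = ["species", "abundance"] if "species" in table.columns else ["abundance"]
        cells = table.groupby(keys, as_index=False)[response].mean()
        logi = np.log(cells["abundance"].to_numpy(float))
        names = ["intercept", "log_individuals"]
        X = np.column_stack([np.ones_like(logi), logi])
    y = cells[response].to_numpy(float)

    def _ols(Xm, nm):
        if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
            raise FitError("design matrix is rank deficient")
        fit = sm.OLS(y, Xm).fit()
        return pd.DataFrame(
            {
                "term": nm,
                "estimate": fit.params,
                "se": fit.bse,
                "t": fit.tvalues,
                "p": fit.pvalues,
            }
        ).reset_index(drop=True)

    terms = _ols(X, names)
    retained = True
    if include_species:
        p_int = float(terms.loc[terms["term"] == "interaction", "p"].iloc[0])
        if not (p_int < alpha):
            retained = False
            terms = _ols(X[:, :3], names[:3])
    return SimFit(terms=terms, interaction_retained=retained and include_species, response=response)


def default_sensitivity_variants() -> dict[str, SoundscapeParams]:
    """The four construction-rule variants of the sensitivity experiment."""
    base = SoundscapeParams()
    return {
        "canvas300_uniform": base,
        "canvas180_uniform": replace(base, canvas_s=180.0),
        "canvas600_uniform": replace(base, canvas_s=600.0),
        "canvas300_halfnormal": replace(base, gain=HalfNormalGain()),
    }


def run_construction_sensitivity(
    library: ClipLibrary,
    n_communities: int = 1000,
    community_size: int = 10,
    abundance_path: tuple[int, ...] = (10, 9, 8, 7, 6, 5),
    variants: dict[str, SoundscapeParams] | None = None,
    index_config: IndexConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Index trajectories of declining communities under each variant.

    Every community is ``community_size`` species drawn at random once
    and shared across all variants; per year y its members all have
    abundance ``abundance_path[y]``.
    """
    variants = variants or default_sensitivity_variants()
    cfg = index_config or IndexConfig()
    pool = sorted(library.species)
    if community_size > len(pool):
        raise ParameterError("community_size exceeds pool size")
    rows = []
    for c in range(n_communities):
        draw_rng = child_rng(seed, "sens-community", c)
        drawn = [str(s) for s in draw_rng.choice(pool, size=community_size, replace=False)]
        for vname, vparams in variants.items():
            for y, a in enumerate(abundance_path, start=1):
                rng = child_rng(seed, "sens", c, vname, y)
                community = SiteYearCommunity(f"community{c}", y, {sp: int(a) for sp in drawn})
                scape = build_soundscape(community, library, vparams, rng)
                rows.append(
                    {
                        "community": c,
                        "variant": vname,
                        "year": y,
                        "abundance": int(a),
                        "species_drawn": ";".join(drawn),
                        **_score(scape.clip, cfg),
                    }
                )
    return pd.DataFrame(rows)
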