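"""Forward-time demographic-genetic model of two temporally offset demes.

A strict biennial plant forms two demes at one site: the cohort flowering in
odd years (d1) and the cohort flowering in even years (d2). Individuals that
delay flowering from age 2 to age 3 act as *temporal migrants*, moving genes
between the demes. The model tracks, for each deme and generation,

    N_T = N_R + N_M - N_E

where N_R are recruits produced by the deme's previous generation, N_M are
immigrants (the other deme's emigrants of the preceding year) and N_E are
emigrants leaving towards the other deme. Deme d1 reproduces in years
y = 2t - 1 and deme d2 in years z = 2t. Growth is multiplicative with a
stochastic rate lambda ~ Normal(lambda_mean, lambda_sd) truncated at zero.
Each individual carries unlinked diallelic loci; offspring genotypes are
binomial draws from the parental generation's allele frequencies (panmixia,
selfing allowed). Emigration moves concrete individuals: round(m * N_R)
rows sampled uniformly from the newly recruited cohort, delivered to the
other deme at its next reproductive year. A migration event happens at a
given deme-year with probability p_event, drawn independently per deme-year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genotypes import GroupedGenotypes

logger = logging.getLogger(__name__)

DemeId = Literal["d1", "d2"]
DEMES: tuple[DemeId, DemeId] = ("d1", "d2")


# --------------------------------------------------------------------- config
@dataclass
class SimulationConfig:
    """Parameters of a single two-deme simulation.

    ``p0`` may be a float (every locus starts at that frequency), the string
    ``"uniform"`` (independent U(0,1) draw per locus) or a length-``n_loci``
    array of per-locus initial frequencies. Loci start at Hardy-Weinberg
    proportions.
    """

    n_generations: int = 100
    n0: int = 1000
    n_loci: int = 100
    p0: float | str | Sequence[float] = 0.5
    lambda_mean: float = 1.0
    lambda_sd: float = 0.01
    m12: float = 0.0
    m21: float = 0.0
    p_event: float = 0.0
    coupled_events: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.lambda_sd < 0:
            raise ValueError("lambda_sd must be >= 0")
        for name in ("m12", "m21", "p_event"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if isinstance(self.p0, str):
            if self.p0 != "uniform":
                raise ValueError("p0 string option must be 'uniform'")
        elif np.ndim(self.p0) == 0:
            if not 0.0 <= float(self.p0) <= 1.0:
                raise ValueError("p0 must be in [0, 1]")
        else:
            arr = np.asarray(self.p0, dtype=float)
            if arr.shape != (self.n_loci,):
                raise ValueError("p0 array must have length n_loci")
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("p0 values must be in [0, 1]")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from a YAML (or JSON) file whose keys mirror the
        field names."""
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def initial_frequencies(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.p0, str):
            return rng.uniform(0.0, 1.0, size=self.n_loci)
        if np.ndim(self.p0) == 0:
            return np.full(self.n_loci, float(self.p0))
        return np.asarray(self.p0, dtype=float).copy()


# --------------------------------------------------------------------- states
@dataclass
class DemeState:
    """Snapshot of one deme after its reproductive year of generation ``t``."""

    deme_id: DemeId
    generation: int
    year: int
    N_T: int
    N_R: int
    N_M: int
    N_E: int
    genotypes: np.ndarray  # (N_T, n_loci) copies of allele A, values {0,1,2}
    allele_freqs: np.ndarray  # per-locus frequency of allele A
    extinct: bool
    recolonized: bool = False

    def check(self) -> None:
        assert self.N_T == self.N_R + self.N_M - self.N_E >= 0
        assert self.genotypes.shape[0] == self.N_T
        assert self.extinct == (self.N_T == 0)


@dataclass
class EmigrantCohort:
    """Individuals that left their natal deme, buffered until they reproduce
    in the other deme one year later (at age 3)."""

    source_deme: DemeId
    birth_year: int
    genotypes: np.ndarray  # (N_E, n_loci)

    @property
    def size(self) -> int:
        return self.genotypes.shape[0]


@dataclass
class PopulationTrajectory:
    """Per-deme time series plus the final genotype matrices."""

    series: pd.DataFrame  # columns: deme, generation, year, N_T, N_R, N_M, N_E, extinct, recolonized, H_S
    final_genotypes: dict[DemeId, np.ndarray] = field(default_factory=dict)

    def deme_series(self, deme: DemeId) -> pd.DataFrame:
        return self.series[self.series["deme"] == deme].reset_index(drop=True)

    def sizes(self, deme: DemeId) -> np.ndarray:
        return self.deme_series(deme)["N_T"].to_numpy()

    def to_csv(self, path) -> None:
        self.series.to_csv(path, index=False)

    def to_grouped_genotypes(self) -> GroupedGenotypes:
        """Final genotypes of both demes as a labelled genotype table
        (diallelic codes 1 = allele A, 2 = allele a)."""
        return GroupedGenotypes.from_dosage(
            {d: self.final_genotypes[d] for d in DEMES if d in self.final_genotypes}
        )


# ----------------------------------------------------------------- primitives
def reproductive_year(t: int, deme: DemeId) -> int:
    """Calendar year of generation ``t``: 2t-1 for d1, 2t for d2."""
    if t < 1:
        raise ValueError("generation index must be >= 1")
    return 2 * t - 1 if deme == "d1" else 2 * t


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def recruit_count(N_prev: int, lam: float) -> int:
    """Recruits produced by a deme of size ``N_prev`` growing at rate ``lam``,
    rounded to the nearest integer (half away from zero), floored at 0."""
    if N_prev < 0 or lam < 0:
        raise ValueError("N_prev and lam must be non-negative")
    return max(0, _round_half_away(lam * N_prev))


def emigrant_count(N_R: int, m: float, event: bool) -> int:
    """Emigrants leaving a cohort of ``N_R`` recruits at migration rate ``m``,
    zero when no migration event occurred."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("migration rate must be in [0, 1]")
    if not event:
        return 0
    return min(N_R, max(0, _round_half_away(m * N_R)))


def sample_offspring_genotypes(
    freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` panmictic offspring: entry (i, l) ~ Binomial(2, freqs[l])."""
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty((0, freqs.size), dtype=np.int8)
    return rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.int8)


def draw_emigrants(
    cohort: np.ndarray, N_E: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split a recruit cohort into (emigrants, residents) by uniform sampling
    of ``N_E`` rows without replacement."""
    n = cohort.shape[0]
    if N_E < 0:
        raise ValueError("N_E must be >= 0")
    if N_E > n:
        logger.warning("emigrant count %d exceeds cohort size %d; clipping", N_E, n)
        N_E = n
    if N_E == 0:
        return cohort[:0], cohort
    idx = rng.choice(n, size=N_E, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return cohort[mask], cohort[~mask]


def allele_frequencies(genotypes: np.ndarray, n_loci: int) -> np.ndarray:
    if genotypes.shape[0] == 0:
        return np.full(n_loci, np.nan)
    return genotypes.sum(axis=0, dtype=np.float64) / (2.0 * genotypes.shape[0])


def gene_diversity(genotypes: np.ndarray) -> float:
    """Nei's unbiased gene diversity H_S, averaged over diallelic loci."""
    n = genotypes.shape[0]
    if n == 0:
        return np.nan
    p = genotypes.sum(axis=0, dtype=np.float64) / (2.0 * n)
    h = 1.0 - p**2 - (1.0 - p) ** 2
    if n > 0 and 2 * n > 1:
        h = h * (2 * n) / (2 * n - 1)
    return float(h.mean())


# ------------------------------------------------------------ generation step
def init_deme(
    config: SimulationConfig,
    deme: DemeId,
    rng: np.random.Generator,
    freqs: np.ndarray | None = None,
) -> DemeState:
    """Found a deme with ``n0`` individuals at Hardy-Weinberg proportions.

    ``freqs`` overrides the config's initial frequencies; both demes of one
    simulation share a single ancestral frequency vector.
    """
    p = config.initial_frequencies(rng) if freqs is None else freqs
    genotypes = sample_offspring_genotypes(p, config.n0, rng)
    return DemeState(
        deme_id=deme,
        generation=0,
        year=reproductive_year(1, deme) - 2,
        N_T=config.n0,
        N_R=config.n0,
        N_M=0,
        N_E=0,
        genotypes=genotypes,
        allele_freqs=allele_frequencies(genotypes, config.n_loci),
        extinct=config.n0 == 0,
    )


def advance_generation(
    state: DemeState,
    incoming: EmigrantCohort | None,
    config: SimulationConfig,
    rng: np.random.Generator,
    event: bool | None = None,
) -> tuple[DemeState, EmigrantCohort]:
    """Advance one deme through its next reproductive year.

    Draws lambda, recruits offspring from the previous generation's allele
    frequencies, removes the emigrant cohort (a Bernoulli(p_event) draw per
    deme-year decides whether migration happens at all) and appends the
    incoming cohort from the other deme. Returns the new state together with
    the (possibly empty) outgoing cohort.

    The RNG consumption is fixed: one normal draw for lambda and one uniform
    for the migration event happen every call, so trajectories with equal
    seeds stay aligned across parameter settings that imply no migration.
    """
    t = state.generation + 1
    year = reproductive_year(t, state.deme_id)
    m = config.m12 if state.deme_id == "d1" else config.m21

    lam = max(0.0, rng.normal(config.lambda_mean, config.lambda_sd))
    if event is None:
        event = bool(rng.random() < config.p_event)

    N_R = recruit_count(state.N_T, lam) if state.N_T > 0 else 0
    if state.N_T > 0:
        recruits = sample_offspring_genotypes(state.allele_freqs, N_R, rng)
    else:
        recruits = np.empty((0, config.n_loci), dtype=np.int8)

    N_E = emigrant_count(N_R, m, event)
    emig, residents = draw_emigrants(recruits, N_E, rng)

    if incoming is not None and incoming.size > 0:
        immigrants = incoming.genotypes
    else:
        immigrants = np.empty((0, config.n_loci), dtype=np.int8)
    N_M = immigrants.shape[0]

    genotypes = (
        np.concatenate([residents, immigrants], axis=0) if N_M else residents
    )
    N_T = N_R + N_M - N_E
    new = DemeState(
        deme_id=state.deme_id,
        generation=t,
        year=year,
        N_T=N_T,
        N_R=N_R,
        N_M=N_M,
        N_E=N_E,
        genotypes=genotypes,
        allele_freqs=allele_frequencies(genotypes, config.n_loci),
        extinct=N_T == 0,
        recolonized=state.extinct and N_T > 0,
    )
    new.check()
    outgoing = EmigrantCohort(state.deme_id, year, emig)
    return new, outgoing


def run_simulation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> PopulationTrajectory:
    """Run both demes for ``config.n_generations`` generations.

    Within generation ``t``, d1 reproduces in year 2t-1 (receiving d2's
    emigrants of year 2t-2) and d2 reproduces in year 2t (receiving d1's
    emigrants of year 2t-1). No emigrant cohorts exist before year 1, so each
    deme's first generation has N_M = 0. Fully reproducible from the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_init = config.initial_frequencies(rng)
    states: dict[DemeId, DemeState] = {
        d: init_deme(config, d, rng, freqs=p_init) for d in DEMES
    }
    pending: dict[DemeId, EmigrantCohort | None] = {"d1": None, "d2": None}
    rows: list[dict] = []
    for _ in range(config.n_generations):
        # with coupled_events one Bernoulli(p_event) draw per generation
        # governs both demes' years; otherwise each deme-year draws its own
        shared = (
            bool(rng.random() < config.p_event) if config.coupled_events else None
        )
        for deme in DEMES:  # d1 (odd year) then d2 (even year)
            state, outgoing = advance_generation(
                states[deme], pending[deme], config, rng, event=shared
            )
            pending[deme] = None
            other: DemeId = "d2" if deme == "d1" else "d1"
            pending[other] = outgoing if outgoing.size else None
            states[deme] = state
            rows.append(
                {
                    "deme": deme,
                    "generation": state.generation,
                    "year": state.year,
                    "N_T": state.N_T,
                    "N_R": state.N_R,
                    "N_M": state.N_M,
                    "N_E": state.N_E,
                    "extinct": state.extinct,
                    "recolonized": state.recolonized,
                    "H_S": gene_diversity(state.genotypes),
                }
            )
    series = pd.DataFrame(rows).sort_values(["deme", "generation"], kind="stable")
    series = series.reset_index(drop=True)
    return PopulationTrajectory(
        series=series,
        final_genotypes={d: states[d].genotypes.copy() for d in DEMES},
    )
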