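"""Census-conditioned Wright-Fisher forward simulation of allele frequencies.

Neutral per-SNP binomial drift: each generation t the allele frequency is
resampled as Binomial(2N_t, p_{t-1}) / 2N_t, with N_t the (diploid) census
size of that generation. SNPs are unlinked and no new mutation enters over
the handful of generations simulated, so the model reduces to independent
binomial chains. The first generation is the founding bottleneck (2N₁
founder gametes drawn at the source frequency).

An optional per-SNP selection coefficient applies the deterministic
diploid multiplicative-fitness update (genotype fitnesses 1 : e^{s/2} :
e^{s}) to the expected frequency before each binomial draw, which grows the
log-odds of the favoured allele by exactly s/2 per generation; this is the
model the standardized selection coefficient of :mod:`afvec.selcoef`
inverts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "CensusTrajectory",
    "SimulationBatch",
    "sample_founder_frequencies",
    "selection_update",
    "simulate_population",
    "generations_from_census",
]


@dataclass(frozen=True)
class CensusTrajectory:
    """Per-generation diploid census sizes N₁…N_τ for one population.

    N₁ is the founding-generation size (the bottleneck); τ, the number of
    generations between founding and sampling, is the length of ``sizes``.
    """

    population: str
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) < 1:
            raise ValueError("need at least one generation")
        if any(n < 1 for n in self.sizes):
            raise ValueError("census sizes must be >= 1")

    @property
    def tau(self) -> int:
        return len(self.sizes)


@dataclass
class SimulationBatch:
    """Replicate final allele frequencies from one population's simulation.

    ``final`` has shape (replicates, n_snps): the frequency of each SNP at
    generation τ in each replicate, all started from ``founding``.
    """

    population: str
    founding: np.ndarray
    final: np.ndarray
    census: CensusTrajectory
    seed: int | None = None

    @property
    def replicates(self) -> int:
        return self.final.shape[0]

    @property
    def n_snps(self) -> int:
        return self.final.shape[1]


def sample_founder_frequencies(n_snps: int, source_freqs=None, ne: int | None = None,
                               rng: np.random.Generator | None = None,
                               maf_min: float | None = None) -> np.ndarray:
    """Founding minor-allele frequencies for a simulated population.

    If ``source_freqs`` (observed polarized frequencies, or an
    AlleleFrequencyTable) is given those are used directly — the source
    sample is taken as representative of the founding frequencies. Otherwise
    frequencies are drawn from the neutral folded site-frequency spectrum,
    density ∝ 1/p + 1/(1−p), truncated to [1/(2·ne), 0.5] (optionally to
    [maf_min, 0.5] to emulate a MAF-filtered SNP panel) and folded to the
    minor allele. The antiderivative of the density is logit(p), so draws
    reduce to p = expit((1−u)·logit(lower)) for uniform u.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if source_freqs is not None:
        f = getattr(source_freqs, "source_freq", source_freqs)
        f = np.asarray(f, dtype=np.float64)
        if f.size == 0:
            raise ValueError("empty source frequency table")
        return f[:n_snps] if len(f) >= n_snps else np.resize(f, n_snps)
    if ne is None or ne < 2:
        raise ValueError("ne >= 2 required when no source frequencies are given")
    rng = np.random.default_rng(rng)
    lower = max(1.0 / (2 * ne), maf_min if maf_min is not None else 0.0)
    u = rng.random(n_snps)
    return expit((1.0 - u) * logit(lower))


def selection_update(p: np.ndarray, s) -> np.ndarray:
    """Deterministic diploid multiplicative-selection update on frequency p.

    Genotype fitnesses 1 : e^{s/2} : e^{s} for 0/1/2 copies of the focal
    allele give a marginal allele-fitness ratio of exactly e^{s/2}, so the
    log-odds of the focal allele increase by s/2 per generation. Fixation
    states (p = 0 or 1) are left untouched.
    """
    p = np.asarray(p, dtype=np.float64)
    w = np.exp(np.asarray(s, dtype=np.float64) / 2.0)
    num = p * w
    return num / (num + (1.0 - p))


def simulate_population(founding: np.ndarray, census: CensusTrajectory,
                        replicates: int = 200,
                        rng: np.random.Generator | int | None = None,
                        s=None) -> SimulationBatch:
    """Forward-simulate every SNP ``replicates`` times through the census.

    Pure binomial Wright-Fisher drift by default; with ``s`` (scalar or
    per-SNP array of selection coefficients on the focal allele) the
    deterministic selection update is applied to the expected frequency
    before each binomial draw. Frequencies 0 and 1 are absorbing under
    neutrality.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(rng)
    p = np.broadcast_to(np.asarray(founding, dtype=np.float64),
                        (replicates, len(np.atleast_1d(founding)))).copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("founding frequencies must lie in [0, 1]")
    for n_t in census.sizes:
        if s is not None:
            p = selection_update(p, s)
        p = rng.binomial(2 * n_t, p) / (2.0 * n_t)
    return SimulationBatch(population=census.population,
                           founding=np.atleast_1d(np.asarray(founding, dtype=np.float64)),
                           final=p, census=census)


def generations_from_census(census: pd.DataFrame, population: str,
                            generation_months: float = 7.9,
                            month_col: str = "month",
                            size_col: str = "census") -> CensusTrajectory:
    """Collapse a dated census series into per-generation effective sizes.

    ``census`` holds point census counts with a fractional ``month`` since
    introduction. Generation g spans ((g−1)·L, g·L] months with L the
    generation length; the size for g is the harmonic mean of the census
    points falling in that interval (harmonic, because drift variance
    accumulates as 1/N, so low-census episodes dominate). Empty intervals
    inherit the previous generation's size; counts are rounded to ≥ 1.
    """
    if generation_months <= 0:
        raise ValueError("generation_months must be positive")
    sub = census.sort_values(month_col)
    months = sub[month_col].to_numpy(dtype=float)
    sizes = sub[size_col].to_numpy(dtype=float)
    if len(sizes) == 0 or np.any(sizes <= 0):
        raise ValueError("census series must be non-empty with positive counts")
    n_gen = int(np.ceil(months.max() / generation_months))
    out: list[int] = []
    for g in range(1, n_gen + 1):
        lo, hi = (g - 1) * generation_months, g * generation_months
        mask = (months > lo) & (months <= hi) if g > 1 else (months >= 0) & (months <= hi)
        vals = sizes[mask]
        if len(vals):
            hm = len(vals) / np.sum(1.0 / vals)
            out.append(max(1, int(round(hm))))
        else:
            out.append(out[-1] if out else max(1, int(round(sizes[0]))))
    return CensusTrajectory(population=population, sizes=tuple(out))
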